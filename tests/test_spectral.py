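"""Spectral features: battery conformance, brute-force transform oracles,
scaling laws and population-level physiology checks."""

import numpy as np
import pytest

from ecgbeats.spectral import (
    _centered_correlation,
    _frames,
    _sym2_kernel,
    cwt_features,
    extract_spectrald,
    extract_spectralr,
    fft_band_sums,
    stft_stats,
    wvd_features,
)
from ecgbeats.registry import registry_names
from ecgbeats.synthetic import BeatClass, generate_beat

FS = 2000.0


class TestFftBands:
    def test_zero_segment(self):
        assert np.all(fft_band_sums(np.zeros(100), FS) == 0)

    def test_pure_tone_lands_in_its_band(self):
        t = np.arange(200) / FS
        sums = fft_band_sums(np.sin(2 * np.pi * 50 * t), FS)
        assert sums[1] / sums.sum() > 0.95
        assert np.all(sums >= 0)


class TestStft:
    def test_zero_segment(self):
        assert stft_stats(np.zeros(100), FS) == (0.0, 0.0, 0.0)

    def test_linear_scaling(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=150)
        a = np.array(stft_stats(x, FS))
        b = np.array(stft_stats(3.0 * x, FS))
        assert b == pytest.approx(3.0 * a, rel=1e-12)

    def test_matches_direct_dft_oracle(self):
        """Spectrogram statistics equal a per-frame direct-DFT double sum."""
        t = np.arange(180) / FS
        x = np.sin(2 * np.pi * 80 * t) + 0.5 * np.sin(2 * np.pi * 300 * t)
        mean, med, mx = stft_stats(x, FS)
        win = np.hamming(32)
        cells = []
        for start in range(0, 180 - 32 + 1, 8):
            frame = x[start:start + 32] * win
            for k in range(1, 65):  # non-DC rows of a 128-point DFT
                c = sum(frame[n] * np.exp(-2j * np.pi * k * n / 128) for n in range(32))
                cells.append(abs(c))
        cells = np.array(cells)
        assert mx == pytest.approx(cells.max(), rel=1e-6)
        assert mean == pytest.approx(cells.mean(), rel=1e-6)
        assert med == pytest.approx(np.median(cells), rel=1e-6)

    def test_short_segment_single_padded_frame(self):
        x = np.ones(10)
        assert _frames(x, 32, 8).shape == (1, 32)


class TestCwt:
    def test_zero_segment(self):
        assert cwt_features(np.zeros(64), FS) == (0.0, 0.0, 0.0, 0.0)

    def test_self_correlation_at_matching_scale(self):
        """A segment that *is* the scale-8 sym2 wavelet correlates >= 0.99
        with the scale-8 kernel at its best placement."""
        k8 = _sym2_kernel(8)
        seg = np.zeros(120)
        seg[10:10 + len(k8)] = k8
        corr = _centered_correlation(seg, k8) / (np.linalg.norm(seg) * np.linalg.norm(k8))
        assert corr.max() >= 0.99

    def test_correlations_bounded(self, beats_by_class):
        for beat in beats_by_class.values():
            f = beat.fiducials
            seg = beat.waveform[0, f.qrs_onset:f.j_point]
            _, _, bp, bs = cwt_features(seg, FS)
            assert -1.0 <= bp <= 1.0 and -1.0 <= bs <= 1.0

    def test_matches_bruteforce_grid_oracle(self):
        """corr features equal an exhaustive python double loop over all
        (scale, placement) pairs."""
        rng = np.random.default_rng(3)
        seg = rng.normal(size=60)
        scales = (1, 2, 5, 9, 17, 32)
        _, _, bp, bs = cwt_features(seg, FS, scales=scales)
        norm_x = np.linalg.norm(seg)
        r = np.zeros((len(scales), len(seg)))
        for i, a in enumerate(scales):
            kern = _sym2_kernel(a)
            K = len(kern)
            nk = np.linalg.norm(kern)
            for p in range(len(seg)):
                acc = 0.0
                for m in range(K):
                    idx = p - (K - 1) // 2 + m
                    if 0 <= idx < len(seg):
                        acc += seg[idx] * kern[m]
                r[i, p] = acc / (norm_x * nk)
        assert bp == pytest.approx(r.max(axis=1).mean(), rel=1e-6)
        assert bs == pytest.approx(r.max(axis=0).mean(), rel=1e-6)


class TestWvd:
    def test_zero_segment(self):
        mx, mean = wvd_features(np.zeros(64), FS)
        assert mx == 0.0 and mean == 0.0

    def test_tone_concentrates_at_its_frequency(self):
        from scipy.signal import hilbert
        t = np.arange(128) / FS
        x = np.sin(2 * np.pi * 100 * t)
        z = hilbert(x)
        n = len(z)
        M = 2 * n
        # direct double-sum at the central time sample
        tc = n // 2
        h = min(tc, n - 1 - tc)
        best_k, best_v = 0, -1.0
        for k in range(M // 2):
            acc = 0.0 + 0.0j
            for m in range(-h, h + 1):
                acc += z[tc + m] * np.conj(z[tc - m]) * np.exp(-2j * np.pi * k * m / M)
            if abs(acc) > best_v:
                best_k, best_v = k, abs(acc)
        f_peak = best_k * FS / (2 * M)
        assert abs(f_peak - 100.0) <= FS / (2 * M) + 1e-9

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        a = np.array(wvd_features(x, FS))
        b = np.array(wvd_features(2.0 * x, FS))
        assert b == pytest.approx(4.0 * a, rel=1e-9)

    def test_matches_direct_double_sum_oracle(self):
        from scipy.signal import hilbert
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        mx, mean = wvd_features(x, FS)
        z = hilbert(x)
        n = len(z)
        M = 2 * n
        vals = []
        for k in range(M):
            f = k * FS / (2 * M)
            if f > 500.0:
                continue
            for tc in range(n):
                h = min(tc, n - 1 - tc)
                acc = 0.0 + 0.0j
                for m in range(-h, h + 1):
                    acc += z[tc + m] * np.conj(z[tc - m]) * np.exp(-2j * np.pi * k * m / M)
                vals.append(abs(acc))
        vals = np.array(vals)
        assert mx == pytest.approx(vals.max(), rel=1e-6)
        assert mean == pytest.approx(vals.mean(), rel=1e-6)


class TestExtractors:
    def test_spectrald_registry_conformance(self, beats_by_class):
        expected = registry_names("SpectralD")
        for beat in beats_by_class.values():
            fv = extract_spectrald(beat)
            assert list(fv.values) == expected
            assert all(v >= 0 for k, v in fv.values.items() if "corr" not in k)

    def test_spectralr_registry_conformance(self, beats_by_class):
        expected = registry_names("SpectralR")
        fv = extract_spectralr(beats_by_class[BeatClass.NOR])
        assert list(fv.values) == expected
        assert len(fv.values) == 72

    def test_identical_leads_identical_features(self, nor_beat):
        w = np.vstack([nor_beat.waveform[0], nor_beat.waveform[0]])
        fv = extract_spectrald(w, nor_beat.fiducials, FS)
        for name, v in fv.values.items():
            if name.endswith("_i"):
                assert fv.values[name[:-2] + "_ii"] == v

    def test_translation_invariance_spectralr(self, nor_beat):
        pad = 300
        w = np.zeros((2, 560 + 2 * pad))
        w[:, pad:pad + 560] = nor_beat.waveform
        a = extract_spectralr(w, pad + 60, FS)
        w2 = np.zeros_like(w)
        w2[:, pad + 7:pad + 567] = nor_beat.waveform
        b = extract_spectralr(w2, pad + 67, FS)
        for k in a.values:
            assert b.values[k] == pytest.approx(a.values[k], rel=1e-9, abs=1e-12)

    def test_vpb_has_more_low_band_power_than_nor(self, noiseless_config):
        """Wide ventricular complexes concentrate power below 35 Hz."""
        low = {}
        for lab in (BeatClass.NOR, BeatClass.VPB):
            vals = []
            for i in range(30):
                b = generate_beat(lab, noiseless_config, i)
                vals.append(extract_spectrald(b).values["d_fft_0_35_i"])
            low[lab] = np.mean(vals)
        assert low[BeatClass.VPB] > low[BeatClass.NOR]

    def test_s50_low_band_exceeds_s20_on_ischemic_beats(self, noiseless_config):
        """The 100 ms window includes ST content the 40 ms one does not."""
        for i in range(20):
            b = generate_beat(BeatClass.ISE, noiseless_config, i)
            fv = extract_spectralr(b)
            assert fv.values["s50_fft_0_35_i"] >= fv.values["s20_fft_0_35_i"]
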