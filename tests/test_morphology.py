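"""Morphological features: registry conformance, analytic area oracles,
equivariances and parameter recovery."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecgbeats.morphology import area_under, extract_morphd, extract_morphr, loop_features
from ecgbeats.registry import RATIO_SENTINEL, registry, registry_names
from ecgbeats.synthetic import BeatClass, Fiducials, generate_beat

FS = 2000.0


class TestRegistry:
    def test_family_sizes(self):
        reg = registry()
        counts = {}
        for e in reg:
            counts[e.family] = counts.get(e.family, 0) + 1
        assert counts == {"MorphD": 71, "MorphR": 44, "SpectralD": 24, "SpectralR": 72}

    def test_names_unique_and_tagged(self):
        reg = registry()
        names = [e.name for e in reg]
        assert len(set(names)) == len(names)
        assert all(e.lead in ("i", "ii", "both") for e in reg)


class TestAreaUnder:
    def test_constant_segment_closed_form(self):
        # 1 mV for 100 ms -> 0.1 mV.s
        samples = np.ones(int(0.100 * FS) + 1)
        assert area_under(samples, FS, "signed") == pytest.approx(0.1, rel=1e-12)

    @given(arrays(np.float64, st.integers(2, 200),
                  elements=st.floats(-5, 5, allow_nan=False)))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_decomposition_identity(self, v):
        s = area_under(v, FS, "signed")
        p = area_under(v, FS, "positive")
        n = area_under(v, FS, "negative")
        a = area_under(v, FS, "absolute")
        assert p >= -1e-15 and n <= 1e-15
        assert s == pytest.approx(p + n, abs=1e-12)
        assert a == pytest.approx(p - n, abs=1e-12)

    def test_matches_oversampled_riemann_oracle(self, beats_by_class):
        """Rectified parts agree with a 10x-oversampled Riemann sum of the
        linear interpolant within 1 %."""
        for beat in beats_by_class.values():
            v = beat.waveform[0]
            fine = np.interp(np.arange(len(v) * 10 - 9) / 10.0, np.arange(len(v)), v)
            dt = 1.0 / (10.0 * FS)
            oracle_pos = np.sum(np.clip((fine[:-1] + fine[1:]) / 2, 0, None)) * dt
            oracle_abs = np.sum(np.abs((fine[:-1] + fine[1:]) / 2)) * dt
            assert area_under(v, FS, "positive") == pytest.approx(oracle_pos, rel=0.01)
            assert area_under(v, FS, "absolute") == pytest.approx(oracle_abs, rel=0.01)


class TestLoopFeatures:
    @pytest.mark.parametrize("x,y,expected", [
        ([0, 1, 0], [0, 0, 0], (1.0, 0.0)),
        ([0, 0], [0, 2], (2.0, 90.0)),
        ([0, 0, 0], [0, 0, 0], (0.0, 0.0)),
    ])
    def test_trivial_geometry(self, x, y, expected):
        assert loop_features(np.array(x, float), np.array(y, float)) == pytest.approx(expected)

    def test_nor_angle_matches_lead_ratio(self, noiseless_config):
        """Without amplitude jitter the QRS-loop angle is the arctangent of
        the configured lead II / lead I R amplitude ratio."""
        beat = generate_beat(BeatClass.NOR, noiseless_config, 0)
        fd = extract_morphd(beat)
        r1, r2 = noiseless_config.classes[BeatClass.NOR].r_amp
        assert fd.values["qrsloop_angle_deg"] == pytest.approx(
            np.degrees(np.arctan2(r2, r1)), abs=1.0)


class TestMorphD:
    def test_exact_registry_conformance(self, beats_by_class):
        expected = registry_names("MorphD")
        for beat in beats_by_class.values():
            fv = extract_morphd(beat)
            assert list(fv.values) == expected

    def test_zero_waveform(self):
        fid = Fiducials(20, 60, 80, 400)
        fv = extract_morphd(np.zeros((2, 560)), fid, FS)
        for name, v in fv.values.items():
            if "ratio" in name:
                assert v == RATIO_SENTINEL
            elif name.endswith(("_ms", "_deg")) and not name.startswith("auc"):
                continue
            else:
                assert v == 0.0

    def test_qrs_duration_recovers_ground_truth(self, noiseless_config):
        for i in range(50):
            b = generate_beat(BeatClass.ISM, noiseless_config, i)
            fv = extract_morphd(b)
            assert abs(fv.values["qrs_d_ms"] - b.params["qrs_dur_drawn_ms"]) <= 1000.0 / FS

    def test_rectangular_pulse_area_closed_form(self):
        """A 1.5 mV rectangle of 40 ms inside the QRS contributes h*w to
        the positive QRS area."""
        w = np.zeros((2, 560))
        w[:, 100:181] = 1.5  # 80 samples = 40 ms
        fid = Fiducials(80, 140, 200, 520)
        fv = extract_morphd(w, fid, FS)
        assert fv.values["auc_qrs_pos_i"] == pytest.approx(1.5 * 0.040, rel=2e-2)

    def test_amplitude_equivariance(self, beats_by_class):
        beat = beats_by_class[BeatClass.ISE]
        f1 = extract_morphd(beat)
        scaled = replace(beat, waveform=beat.waveform * 2.5)
        f2 = extract_morphd(scaled)
        for e in registry():
            if e.family != "MorphD":
                continue
            a, b = f1.values[e.name], f2.values[e.name]
            if e.units in ("mV", "mV.s"):
                assert b == pytest.approx(2.5 * a, rel=1e-9, abs=1e-12)
            else:  # ms, deg, dimensionless ratios
                assert b == pytest.approx(a, rel=1e-9, abs=1e-9)

    def test_out_of_window_fiducials_rejected(self):
        with pytest.raises(ValueError):
            extract_morphd(np.zeros((2, 560)), Fiducials(20, 60, 80, 600), FS)

    def test_st20_parameter_recovery(self, noiseless_config):
        """Regressing measured ST20 on the configured severe-ischemic ST
        level over noiseless beats recovers slope 1 within 2 %."""
        levels = np.linspace(-0.4, 0.4, 41)
        measured = []
        for i, level in enumerate(levels):
            ise = replace(noiseless_config.classes[BeatClass.ISE],
                          st_level=(float(level), float(level)))
            cfg = replace(noiseless_config,
                          classes={**noiseless_config.classes, BeatClass.ISE: ise})
            b = generate_beat(BeatClass.ISE, cfg, i)
            measured.append(extract_morphd(b).values["st20_i"])
        slope = np.polyfit(levels, measured, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)


class TestMorphR:
    def test_exact_registry_conformance(self, beats_by_class):
        expected = registry_names("MorphR")
        for beat in beats_by_class.values():
            fv = extract_morphr(beat)
            assert list(fv.values) == expected

    def test_zero_waveform(self):
        fv = extract_morphr(np.zeros((2, 560)), 60, FS)
        for name, v in fv.values.items():
            if "pos_" in name and name.startswith("r_m"):
                continue  # positions of ties are 0-referenced anyway
            assert v == 0.0

    def test_translation_invariance(self, beats_by_class):
        """Embedding the beat deeper into a longer trace and moving r_index
        along leaves every feature unchanged (windows unclipped)."""
        beat = beats_by_class[BeatClass.NOR]
        pad = 400
        w = np.zeros((2, 560 + 2 * pad))
        w[:, pad:pad + 560] = beat.waveform
        a = extract_morphr(w, pad + 60, FS)
        w2 = np.zeros_like(w)
        w2[:, pad + 5:pad + 565] = beat.waveform
        b = extract_morphr(w2, pad + 65, FS)
        for k in a.values:
            assert b.values[k] == pytest.approx(a.values[k], rel=1e-9, abs=1e-12)

    def test_triangle_area_closed_form(self):
        """A unit triangle of half-width 20 ms centred on R integrates to
        its analytic area over the 40 ms window."""
        w = np.zeros((2, 560))
        half = int(0.020 * FS)  # 40 samples
        tri = 1.0 - np.abs(np.arange(-half, half + 1)) / half
        w[:, 60 - half:60 + half + 1] = tri
        fv = extract_morphr(w, 60, FS)
        assert fv.values["auc_r40_i"] == pytest.approx(0.020, rel=1e-6)
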