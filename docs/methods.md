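# Methods

## The beat model

Each synthetic beat is a two-lead 280 ms window sampled at `fs` (default
2000 Hz; 560 samples), with the R peak fixed at round(0.030·fs) so the
window spans R−30 ms to R+250 ms. Per lead, the waveform is a sum of
Gaussian-shaped bumps for the Q, R, S and T deflections plus an
ST-plateau offset. The bumps are Gaussians truncated at 3σ and rescaled
to reach zero continuously at the truncation point, so every deflection
has strictly compact support. This is what makes the generator's
fiducials *exact*: the QRS onset and J point delimit the union of the
Q/R/S supports, the T end is the edge of the T support, and 20 ms after
the J point the waveform equals the ST level exactly (the T support is
constrained to start at least 25 ms after J, and the plateau reaches its
full level within 10 ms). Noise is added only after the fiducials are
fixed.

Geometry per beat: QRS duration `d` and QT are drawn from per-class
normal distributions truncated symmetrically at ±3 SD (±2.5 SD for the
VPB QRS, keeping every ventricular complex at least 2.5× the normal
width); QRS onset = R − r_frac·d with a class-specific r_frac (0.5 for
narrow beats, 0.3 for VPBs so wide complexes stay inside the window);
J = onset + d; T end = onset + QT. All indices are integers, so
fiducial-derived durations match the drawn parameters to within one
sample.

### Class parameterization

Non-ischemic beats use the stabilization-period statistics
RR = 344 ± 46 ms, QRS = 24 ± 4 ms, QT = 175 ± 22 ms. The pathological
classes follow the qualitative electrophysiology of progressive global
ischemia: ISM (5th minute) gets mild QRS prolongation (28 ± 5 ms) and a
small ST shift (≈0.1 mV, opposite signs in the two leads, as ischemic
currents project differently onto orthogonal leads); ISE (10th minute)
gets marked widening (40 ± 6 ms), a large ST shift (≈0.3 mV), QT
shortening and T inversion; VPBs are wide (70 ± 4 ms) biphasic RS
complexes with a dominant S wave, discordant T, and premature timing
(default 0.7 of the preceding interval in continuous records). Lead II
amplitudes default to 1.2× lead I so the two-lead loop features are
non-degenerate; the noiseless QRS-loop angle is then
atan2(1.2, 1) ≈ 50°.

### Intra-class variability: heart modes

Real multi-animal datasets are strongly multimodal within a class:
different hearts show ST depression *or* elevation, different amplitude
scales and occasionally opposite dominant VPB polarity. The generator
emulates this with four discrete per-class "modes" (as if each beat came
from one of four experiments), drawn uniformly per beat, which scale the
overall amplitude (0.75–1.3×), the ST level (including sign flips for the
ischemic classes), the T wave, and flip VPB polarity in half the modes.
On top of the modes, each beat gets per-lead log-normal amplitude jitter
(σ = 0.12–0.18) and Gaussian ST-level jitter. This structure is what
makes the benchmark behave like real data: class-conditional
distributions are non-Gaussian and multimodal, so instance-based
learners (k-NN) outperform linear discriminants, while everything
remains pairwise distinguishable in rank distribution for enough
features to survive the all-pairs filter.

What the generator does **not** emulate: P waves (never delineated in
this pipeline, so PQ-dependent features are deliberately absent),
respiration-coupled morphology drift, electrode motion artefacts,
polymorphic VPB trains, and continuous ischemia progression (classes are
stationary distributions, not a time course). Passing tests therefore
demonstrate correctness of the pipeline mechanics and the *qualitative*
reproduction of the study design, not clinical performance on real
recordings.

### Seeding

One root seed; each beat of a dataset uses a substream keyed by
(class, index) via `numpy` `SeedSequence` spawn keys, so beat k of class
c is identical whatever else is generated; the dataset order is shuffled
by a separate dedicated substream.

## Preprocessing

Baseline removal follows the zero-phase Lynn construction: the baseline
estimate is two cascaded odd-length moving averages, each spanning
0.4/cutoff seconds (0.8 s at the 0.5 Hz default), applied with symmetric
reflection; the triangular composite impulse response is symmetric about
zero lag, hence exactly zero phase, and the estimate subtracted from the
signal leaves DC at zero and attenuates a 0.2 Hz wander sinusoid by
>90 % in amplitude-squared terms. The −3 dB point sits slightly above
the nominal cutoff (≈0.57 Hz at the default); the filter is specified by
its span, the classical comb/moving-average parameterization.

QRS detection sums the absolute bior1.5 stationary-wavelet detail
coefficients of both leads over the levels whose dyadic bands intersect
10–60 Hz (levels 5 and 6 at 2 kHz). The threshold is
max(0.35 × 98th percentile of the envelope per 2 s block,
0.10 × global 99th percentile) — both terms scale with the signal, so
detection is invariant to positive amplitude scaling. Candidates closer
than the 150 ms refractory period are pruned (larger envelope wins); a
candidate arriving within 260 ms of a detection with less than half its
envelope is rejected as a T wave; surviving candidates are refined to
the extremum of the summed absolute leads within ±25 ms. Defaults were
chosen for the rabbit rhythm (RR ≈ 344 ms, minimum RR 150 ms).

## Features

All per-lead amplitudes in `MorphD` are measured against the pre-QRS
isoline (median of the window's first 10 ms). Areas are computed exactly
on the piecewise-linear interpolant: each inter-sample segment
contributes its trapezoid, segments crossing zero are split analytically,
so signed = positive + negative and absolute = positive − negative hold
to machine precision. Positive-to-negative area ratios with vanishing
denominator return a capped sentinel (10⁶); relative areas with a
vanishing reference return 0 for 0/0 and a sign-preserving sentinel
otherwise. Ratio-family features stay finite for every input and
standardization absorbs the scale.

The registry (`ecgbeats.registry`) is the single source of truth for
names, order, subgroup and units: MorphD = 7 both-lead + 32 per lead
(7 voltage, 12 areas, 10 relative, 3 ratios); MorphR = 22 per lead
(6 extremum features with positions relative to the R peak, 9 general
areas, 7 absolute areas). R-centred ⟨R−t, R+t⟩ windows that overrun the
segment edge are clipped to it (at the default geometry the 100 ms
half-width always clips 70 ms of the pre-R side — a property of the
30 ms pre-window, identical for every beat).

Spectral battery per lead and segment: FFT band powers are one-sided
|X|² sums on a fixed 4096-point zero-padded grid (≈0.49 Hz resolution),
so resolution does not depend on segment length. The spectrogram uses a
32-sample Hamming window, 75 % overlap and a 128-point FFT — even a
40 ms (80-sample) segment yields ≥7 frames — statistics are taken over
the *magnitude* cells with the DC row excluded. The CWT uses the sym2
wavelet sampled from its refinement cascade at integer scales 1–32
(support truncated below 1e-8); the correlation features build the
normalized-correlation matrix r[a, p] between the segment and the
scale-a kernel centred at sample p (bounded to [−1, 1] by
Cauchy-Schwarz): one feature averages over scales the best correlation
across placements, the other averages over placements the best
correlation across scales. The Wigner-Ville distribution is computed
from the analytic signal (suppressing negative-frequency cross-terms)
via the instantaneous autocorrelation r_n[m] = z[n+m]·z*[n−m]; bin k of
the 2N-point DFT over the lag maps to frequency k·fs/(4N), and the
max/mean are taken over magnitude cells at 0–500 Hz. Degenerate inputs
(all-zero segments) return zeros, including the correlation features.

## Selection

Shapiro-Wilk p-values per feature and class are reported but do not gate
anything — they document why the non-parametric path is used.
Kruskal-Wallis uses mid-ranks with tie correction and the χ²(k−1)
approximation. The post-hoc procedure is the Tukey-Kramer multiple
comparison of group mean ranks: q = |R̄ᵢ−R̄ⱼ| / √(S(1/nᵢ+1/nⱼ)/2), with
S = N(N+1)/12 tie-corrected, referred to the studentized range with
infinite degrees of freedom; unequal group sizes are allowed. A feature
is retained iff all six pairwise p-values fall below α = 0.05; no
correction across features is applied (each feature is judged on its
own). The pipeline runs selection globally per family; subgroups are
formed afterwards by intersecting the retained set with the registry
subgroups.

## Benchmark

Folds are stratified (the 172-member VPB class must appear in every
fold) and shuffled under the run seed. Standardization statistics come
from the training fold only; zero-variance training features map to 0 in
both matrices and are flagged. Model notes: the quadratic discriminant
carries a 1e-3 covariance ridge because relative-area features are
near-collinear within folds; the kernel naive Bayes uses per-feature,
per-class Gaussian KDEs with Silverman bandwidths (floored at 1e-3 on
z-scored features); SVMs use C = 1, gamma = 1/(n_features·Var) and an
explicit one-vs-all wrapper with maximum-decision-value voting; k-NN is
Euclidean on the standardized features. No hyperparameter search is
performed anywhere — the grid compares fixed, conventional settings.

## Problem sizes

Default experiments use the 832-beat class mix (220/220/220/172).
Detector evaluations use 500-beat continuous records; calibration checks
use 1000 beats; the null-distribution simulations use 2000 (omnibus) and
1000 (post-hoc) replicates; benchmark replicate studies use 10 seeds.

## Known limitations

The three-lead artefact-exclusion step of laboratory practice has no
counterpart here (the artifact is two-lead by design); automatic
delineation of QRS onset/J/T end is out of scope (ground-truth fiducials
stand in); the Wigner-Ville implementation is the discrete pseudo-WVD
without time smoothing, so closely spaced in-band components produce
cross-terms; absolute classification accuracies depend on the chosen
generator variability and should be read as properties of the synthetic
conditions, not of any animal dataset.
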