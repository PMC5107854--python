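# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `respstab`, and what the synthetic validation does
and does not demonstrate.

## Trace model and I/O

A respiration trace is a uniformly sampled displacement series x(t) in
the tracker's distance units (assumed cm throughout), typically the
anterior–posterior chest-surface position at 25 Hz (the default assumed
rate for headerless files; configurable).  Amplitude units are carried
as metadata and never rescaled implicitly: every cutoff in the
classifier is "in trace units".  CSV files with a mildly non-uniform
time column are accepted if the worst deviation is below 10% of the
median step (the grid is snapped to the median step); anything worse
must be resampled explicitly (linear interpolation), because silently
regridding pathological data would bias the velocity estimates.

## Cycle decomposition

Cycles are anchored trough-to-trough: end-of-exhale is the mechanically
stable resting phase of breathing, so the trough sequence defines both
the period series P_i and the baseline series e_i used for MEE
(mean of e_i), MUD (max), MDD (min) and the drift index MUD−MDD.
Troughs are local minima with prominence ≥ 20% of the global
peak-to-peak range and ≥ 1.0 s separation — values chosen to suppress
cardiac and sensor ripple at physiological breathing rates
(0.1–0.5 Hz); both are configurable.  One peak (the cycle maximum) is
taken between consecutive troughs, so extrema strictly alternate, and
the cycle amplitude is that maximum minus the leading trough value.

A consequence worth knowing: on waveforms with a flat end-of-exhale
plateau, the *timing* of the trough within the plateau is noise-limited
(any sample on the plateau is equally deep to within the noise), so
per-cycle period estimates carry up to a few hundred milliseconds of
jitter on noisy traces even though amplitudes and baseline statistics
are essentially unaffected.

Outlier cycles are screened by resampling every cycle to a common
length, correlating it against the point-wise *median* cycle (robust to
the outliers being screened), and discarding cycles with Pearson
r < 0.6, worst first.  The discard budget is a cap: at most
⌊0.05·N⌋ cycles, but at least one whenever any cycle fails; if more
fail than may be discarded a warning flags the trace as globally
irregular rather than silently censoring it.

## Poincaré section

The phase-space portrait uses central-difference velocity (one-sided at
the ends) with optional moving-average pre-smoothing of x; the pipeline
default is a 5-sample window (0.2 s at 25 Hz), which attenuates sensor
noise amplified by differentiation while leaving the breathing waveform
(period ≈ 4 s) intact.

Section points are recorded as the first discrete sample at-or-after
each plane crossing, deliberately without sub-sample interpolation:
interpolating onto the plane would collapse one coordinate's variation
by construction, whereas the discrete-sample convention keeps dispersion
in both x and v.  Crossing detection uses a Schmitt trigger with a
hysteresis band of 20% of the section coordinate's half-range: after a
crossing the detector re-arms only once the trajectory retreats beyond
the band, so noise wiggling around the plane level (e.g. v ≈ 0 on the
end-of-exhale plateau) cannot generate spurious section points.  SDs
are population (ddof = 0) by default.

Two plane placements are provided, and the choice matters:

* **turnaround** (default): the plane lies at the midrange of the
  *velocity* coordinate (≈ 0 for quasi-symmetric breathing) and
  downward crossings — the end-of-inhale turnarounds, one per cycle —
  are recorded.  The x-coordinates of the section points are then the
  per-cycle end-of-inhale positions, so SD_x responds directly to
  amplitude jitter and baseline drift while remaining insensitive to
  period jitter; SD_v collects the residual velocity spread at the
  turnaround.  This placement reproduces the clinically observed
  behaviour of the dispersion indices (amplitude-irregular and drifting
  patterns scatter strongly in x; period-irregular-only patterns do
  not) and feeds the classifier.
* **midrange**: the classical one-sided section, with the plane on the
  displacement coordinate halfway between the global maximum and
  minimum of respiration and upward (exhale→inhale) crossings recorded.
  Because the recorded sample lies within one sampling step of the
  plane, x is pinned to the plane level (SD_x ≤ v_max/fs) and amplitude
  variation expresses itself in SD_v instead — with the side effect
  that period jitter also enters SD_v through v ∝ A/T.  The mode is
  retained for comparison and diagnostics.

The plane level is computed from the retained trace (samples of
discarded cycles are excluded from both the level and the crossings).

## Fourier spectrum and period regularity

The trace is detrended (linear by default, so baseline drift does not
leak into the respiratory band — drift is measured separately by
MUD−MDD), transformed under a rectangular window, and scaled to a
one-sided amplitude spectrum (interior bins 2/N, DC and Nyquist 1/N):
a sinusoid of amplitude a occupying an integer number of cycles appears
as a single bin of height a.  The rectangular window is a deliberate
fixed convention — A₁ cutoffs are only comparable under a fixed
normalization, and at 20-minute records the frequency resolution
(≈ 0.8 mHz) makes leakage unimportant.  The fundamental f₀ is the
tallest local maximum in the physiological band (0.05–1.0 Hz default)
and A₁ is its height.  Note that A₁ values, and therefore the 0.117
classification cutoff, are meaningful only under this normalization and
the trace's amplitude units.

Period regularity is a two-part rule operationalizing a visual
criterion ("one dominant fundamental peak; bell-shaped spectrum
centered on it"):

1. *Peak dominance*: A₁ must exceed the mean height of the 3 tallest
   other significant in-band local maxima (those ≥ 1% of A₁, outside
   ±2 bins of f₀) at least 2-fold.  Averaging over *all* local maxima
   would be dominated by the sheer count of negligible noise wiggles —
   making the statistic depend on record length and noise floor rather
   than spectral shape — so the comparison is against the tallest
   competitors, which is also what the eye compares the fundamental
   against.
2. *Concentration*: the fraction of in-band spectral energy within
   ±0.05 Hz of f₀ must reach 0.8.

Both thresholds (and the half-width) are configurable calibration
constants; the defaults separate the regular-period archetypes from the
irregular-period ones with wide margins (measured on the generator:
concentration ≥ 0.93 for regular-period cohorts vs ≤ 0.75 for
irregular-period ones; dominance ratio ≥ 3 vs ≤ 1.5).

## Largest Lyapunov exponent

Rosenstein-style divergence-curve estimator, chosen over Wolf-style
trajectory following for robustness on short, noisy physiological
records:

* Delay τ: first lag at which the autocorrelation of x falls below 1/e
  (fallback: quarter of the dominant period).  Dimension m: smallest
  m ≤ 8 with false-nearest-neighbour fraction < 5% (Kennel criteria,
  distance ratio 15, size criterion 2σ; fallback m = 3).  FNN
  statistics are computed on a subsample of at most 4000 points.
* Each embedded point is paired with its nearest *distinct* neighbour
  (distance > 0) outside a Theiler window of one mean breathing period,
  excluding trivially correlated same-cycle neighbours.  Requiring a
  distinct neighbour matters for strictly periodic traces, which
  revisit themselves exactly: the informative neighbour is the nearest
  distinct state, which produces a flat divergence curve and the
  regular-breathing limit λ₁ → 0.
* The pair set is fixed up front — reference points are restricted so
  every pair supports the full expansion horizon.  Dropping pairs as
  they run off the end would change the curve's composition across
  steps and can cancel a genuine contraction trend (survivorship bias);
  a constant pair set measures the same ensemble at every step.  Pairs
  whose separation underflows to exactly zero at some step are skipped
  at that step (their log-distance is undefined).
* λ₁ is the least-squares slope of the mean log-distance over the first
  mean period of expansion steps, divided by the sampling interval
  (units s⁻¹).  The fit region is configurable; the first period is
  where the linear scaling region of quasi-periodic signals lies,
  before fold-back.
* Nearest neighbours are found by exact chunked brute force (the
  largest routine input here is ~30 000 embedded points, well within
  one core's reach); an accelerated search may replace it only if
  exactly equivalent.

Sign semantics, and what is testable: a positive exponent means nearby
breathing states diverge (stochastic cycle-to-cycle variation reads as
divergence); zero is the strictly periodic limit; negative means the
trace carries a *deterministic contracting transient* — e.g. an
initially scattered amplitude envelope that settles toward a steady
orbit — and faster settling gives a more negative exponent.  Purely
stochastic perturbations can never yield a negative slope under this
estimator class: neighbours are selected at minimal initial separation,
so random differences only regress upward.  The validation suite
therefore exercises the negative branch with decaying-envelope and
exponentially damped traces (for x = e^{−λt}·sin ωt every pair
contracts at rate λ and the estimator recovers −λ), and treats
absolute exponents of clinical recordings as algorithm- and
normalization-dependent quantities: only the sign and the limits are
portable claims.

## Synthetic archetypes

Each generated cycle is z_i(t) = b_i + A_i·sin²ⁿ(πt/T_i), a Lujan-type
profile (default n = 2) whose 2n-th-order zero at the cycle boundaries
gives the flat end-of-exhale plateau of real breathing, with the smooth
end-of-inhale maximum mid-cycle.  Orienting the plateau at the *trough*
keeps the baseline walk b_i an end-of-exhale property — exactly what
MEE/MUD/MDD measure — and makes cycle concatenation continuous.
A_i and T_i are truncated-normal draws (truncation at 0.1·μ_A and
0.2·μ_T prevents non-physical negatives); b_i is a reflected random
walk confined to [0, drift_span], updated once per cycle (drift is a
baseline property, not within-cycle noise), with step SD defaulting to
drift_span/8 so a 20-minute walk explores most of its range (measured
MUD−MDD for a 0.8 cm span: 0.64–0.79 cm noise-free across seeds);
white sensor noise is added last.  All randomness derives from one
`numpy.random.default_rng(seed)` stream, so traces are bit-reproducible
across platforms.

Archetype presets (base μ_A = 0.8 cm, μ_T = 4 s, noise 0.01 cm,
20 min at 25 Hz): "regular" means 2% coefficient of variation;
amplitude-irregular groups (C, D) use σ_A = 0.30·μ_A; period-irregular
groups (B, D) use σ_T = 0.25·μ_T; drift adds a 0.8 cm span.  The CV
values define the archetypes; the absolute scale and noise level are
package calibration constants chosen once so the archetypes land on the
intended sides of the published cutoffs with wide margins (e.g. group-A
SD_x ≈ 0.02 vs cutoff 0.11 vs group-C ≈ 0.24+; group-B A₁ ≈ 0.08 vs
cutoff 0.117 vs group-A ≈ 0.30).  The canonical validation cohort uses
drift-free A and B and drifting C and D, mirroring the clinically
observed prevalence (drift accompanies amplitude irregularity far more
often than not).  Note that under the turnaround section baseline drift
itself spreads SD_x, so a drifting-but-amplitude-regular trace can
cross the amplitude cutoff: drift and amplitude regularity are not
fully separable in a single dispersion index.

What the generator does *not* emulate: cardiac superposition,
inhale/exhale hysteresis, breathing-type switching, apnea, and
non-stationary changes in mean period.  Passing the recovery tests
therefore shows the pipeline separates the four archetype mechanisms at
realistic amplitudes and noise levels; it does not certify performance
on clinical recordings, whose cutoffs depend on device units and should
be re-derived per site with the ROC tooling.

## Classification, ROC and ANOVA conventions

Amplitude regularity uses SD_x alone by default (the strongest single
index; configurable to SD_v or to require both); SD_v is always
reported.  A₁'s direction is explicit: *higher* fundamental peaks mean
*more regular* periods, so irregular means A₁ < cutoff.  Boundary
values classify as regular (inclusive comparisons), an arbitrary but
fixed tie rule.  Exactly one group is assigned to any finite index
vector.

ROC: AUC by the Mann–Whitney rank identity with ties counted ½; the
reported cutoff maximizes Youden's J and is placed at the midpoint
between adjacent distinct scores; orientation is auto-detected (scores
are flipped when AUC < 0.5 and the flip is recorded).  ANOVA: classical
one-way F; Scheffé pairwise criterion at α = 0.05 with homogeneous
subsets reported in increasing order of mean in the compact
"A, B < C, D" notation.  Cohort reports flag per-trace failures as
rows rather than aborting, and skip the (slow) LLE by default.

## Problem sizes used in validation

The validation suite uses full 20-minute traces at 25 Hz (30 000
samples) for the headline Lyapunov limit and for the 50-per-group
archetype recovery, 400–600 s traces for invariance checks, and
shorter (≈2000-sample) traces for the cross-implementation LLE
comparisons, where the independent plain-loop reference implementation
is quadratic in trace length.  Null calibration of the ANOVA stage uses
200 seeded simulations of four 20-sample groups.
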