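"""Synthetic respiration generator with ground-truth labels.

Traces are built by concatenating breathing cycles with a Lujan-family
profile,

    z_i(t) = b_i + A_i * sin**(2n)(pi * t / T_i),   0 <= t < T_i,

whose flat plateau (the 2n-th order zero of sin**(2n) at the cycle
boundaries) models the end-of-exhale rest position, while the smooth
maximum mid-cycle is end-of-inhale.  Per-cycle amplitudes A_i and periods
T_i are truncated-normal draws; the end-of-exhale baseline b_i follows a
reflected random walk confined to [0, drift_span], updated once per cycle,
so baseline drift is a property of the end-of-exhale positions exactly as
the MUD/MDD statistics assume.  White sensor noise is added last.

Four archetype presets mirror the clinically observed pattern taxonomy:

======  ==================  ===============  =========================
Group   amplitude           period           description
======  ==================  ===============  =========================
A       regular (2% CV)     regular (2% CV)  both regular
B       regular             irregular (25%)  period irregular
C       irregular (30%)     regular          amplitude irregular
D       irregular           irregular        both irregular
======  ==================  ===============  =========================

Each preset may additionally carry baseline drift (``drift=True`` adds a
0.8 cm bounded drift excursion); the all-regular archetype A is by
definition drift-free.  The sigma ratios are the archetype definitions;
the absolute scale (``mu_A``), noise level and drift span are package
calibration constants chosen so the archetypes fall on the intended sides
of the published classification cutoffs (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError
from .trace_io import RespTrace, uniform_time_grid

#: Calibrated archetype constants (see module docstring and docs/methods.md).
BASE_MU_A = 0.8      # cm, mean cycle amplitude
BASE_MU_T = 4.0      # s, mean cycle period
BASE_NOISE_SD = 0.01  # cm, additive white sensor noise
DRIFT_SPAN = 0.8     # cm, total baseline excursion when drift is present
REGULAR_CV = 0.02    # sigma/mu for "regular" amplitude or period
IRREGULAR_AMP_CV = 0.30   # sigma_A/mu_A for amplitude-irregular groups
IRREGULAR_PER_CV = 0.25   # sigma_T/mu_T for period-irregular groups

GROUPS = ("A", "B", "C", "D")


@dataclass
class SynthParams:
    """Generator parameters; defaults are the Group-A-like regular regime.

    drift_step_sd defaults to drift_span/8: over a 20-min recording
    (~300 cycles) the reflected walk then explores most of its range, so
    the realized MUD-MDD is close to (but bounded by) drift_span.
    """

    mu_A: float = BASE_MU_A          # cm, mean cycle amplitude
    sigma_A: float = 0.0             # cm, per-cycle amplitude SD
    mu_T: float = BASE_MU_T          # s, mean cycle period
    sigma_T: float = 0.0             # s, per-cycle period SD
    drift_span: float = 0.0          # cm, bound of the baseline random walk
    drift_step_sd: float | None = None  # cm per cycle; None -> drift_span/10
    noise_sd: float = BASE_NOISE_SD  # cm, additive white noise SD
    shape_n: int = 2                 # cycle profile exponent: sin**(2n)
    duration: float = 1200.0         # s
    fs: float = 25.0                 # Hz
    seed: int = 0
    label: str | None = None         # archetype label when built by preset()
    drift: bool = False              # drift flag when built by preset()

    def __post_init__(self) -> None:
        if self.mu_A <= 0 or self.mu_T <= 0:
            raise InputError("mu_A and mu_T must be positive")
        if min(self.sigma_A, self.sigma_T, self.drift_span,
               self.noise_sd) < 0:
            raise InputError("sigma_A, sigma_T, drift_span, noise_sd "
                             "must be non-negative")
        if self.shape_n < 1 or int(self.shape_n) != self.shape_n:
            raise InputError("shape_n must be an integer >= 1")
        if self.fs <= 0:
            raise InputError("fs must be positive")


@dataclass
class GroundTruth:
    """Realized per-cycle quantities and the generating archetype."""

    group_label: str | None
    drift_flag: bool
    amplitudes: np.ndarray   # drawn A_i, cm
    periods: np.ndarray      # drawn T_i, s
    baselines: np.ndarray    # end-of-exhale baseline b_i, cm
    starts: np.ndarray = field(default=None)  # cycle start times, s


def _truncated_normal(rng: np.random.Generator, mu: float, sigma: float,
                      lower: float) -> float:
    """Normal(mu, sigma) draw rejected below ``lower`` (exact truncation)."""
    if sigma == 0.0:
        return mu
    for _ in range(1000):
        value = rng.normal(mu, sigma)
        if value >= lower:
            return float(value)
    # Pathological sigma/lower combination: fall back to the bound.
    return float(lower)


def generate_trace(params: SynthParams) -> tuple[RespTrace, GroundTruth]:
    """Generate one synthetic respiration trace.

    Deterministic for a fixed seed: the cycle draws, the baseline walk and
    the noise all come from one ``numpy.random.default_rng(seed)`` stream.

    Raises
    ------
    InputError
        If ``duration < 3 * mu_T`` (too few cycles to analyze).
    """
    p = params
    if p.duration < 3 * p.mu_T:
        raise InputError(
            f"duration {p.duration} s is shorter than 3 cycles "
            f"(3*mu_T = {3 * p.mu_T} s)")
    rng = np.random.default_rng(p.seed)
    step_sd = (p.drift_span / 8.0 if p.drift_step_sd is None
               else p.drift_step_sd)

    # Draw cycles until they cover the recording.
    amplitudes, periods, baselines, starts = [], [], [], []
    if p.drift_span > 0:
        b = float(rng.uniform(0.0, p.drift_span))
    else:
        b = 0.0
    s = 0.0
    while s < p.duration:
        A = _truncated_normal(rng, p.mu_A, p.sigma_A, 0.1 * p.mu_A)
        T = _truncated_normal(rng, p.mu_T, p.sigma_T, 0.2 * p.mu_T)
        amplitudes.append(A)
        periods.append(T)
        baselines.append(b)
        starts.append(s)
        s += T
        if p.drift_span > 0 and step_sd > 0:
            b += rng.normal(0.0, step_sd)
            # Reflect into [0, drift_span].
            while b < 0.0 or b > p.drift_span:
                if b < 0.0:
                    b = -b
                if b > p.drift_span:
                    b = 2.0 * p.drift_span - b

    n = int(round(p.duration * p.fs))
    t = uniform_time_grid(0.0, n, p.fs)
    x = np.empty(n, dtype=float)
    exponent = 2 * int(p.shape_n)
    for A, T, b0, s0 in zip(amplitudes, periods, baselines, starts):
        k0 = int(np.ceil(s0 * p.fs - 1e-9))
        k1 = min(n, int(np.ceil((s0 + T) * p.fs - 1e-9)))
        if k0 >= n:
            break
        tau = t[k0:k1] - s0
        x[k0:k1] = b0 + A * np.sin(np.pi * tau / T) ** exponent
    if p.noise_sd > 0:
        x += rng.normal(0.0, p.noise_sd, size=n)

    trace = RespTrace(t=t, x=x, fs=p.fs,
                      meta={"source": "respstab.synth", "units": "cm",
                            "seed": p.seed, "label": p.label})
    truth = GroundTruth(group_label=p.label, drift_flag=p.drift_span > 0,
                        amplitudes=np.array(amplitudes),
                        periods=np.array(periods),
                        baselines=np.array(baselines),
                        starts=np.array(starts))
    return trace, truth


def preset(group: str, drift: bool = False, **overrides) -> SynthParams:
    """Parameter set for one of the four archetype groups.

    ``drift=True`` adds a bounded baseline excursion of ``DRIFT_SPAN`` cm;
    it is forbidden for Group A (the all-regular archetype is drift-free
    by definition).  Keyword overrides replace any SynthParams field.
    """
    if group not in GROUPS:
        raise InputError(f"unknown group {group!r}; expected one of {GROUPS}")
    if group == "A" and drift:
        raise InputError("Group A is the drift-free archetype; "
                         "drift=True is not allowed")
    amp_cv = IRREGULAR_AMP_CV if group in ("C", "D") else REGULAR_CV
    per_cv = IRREGULAR_PER_CV if group in ("B", "D") else REGULAR_CV
    params = SynthParams(
        sigma_A=amp_cv * BASE_MU_A,
        sigma_T=per_cv * BASE_MU_T,
        drift_span=DRIFT_SPAN if drift else 0.0,
        label=group,
        drift=drift,
    )
    if overrides:
        params = replace(params, **overrides)
    return params
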