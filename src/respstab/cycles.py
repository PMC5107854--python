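"""Breathing-cycle segmentation, outlier-cycle rejection, and baseline
drift statistics.

A time–amplitude respiration curve decomposes into per-cycle
subcomponents: amplitude A (end-of-inhale peak minus the leading
end-of-exhale trough), period P (trough-to-trough duration), and the
end-of-exhale baseline whose mean (MEE), maximal upward drift position
(MUD) and maximal downward drift position (MDD) summarize baseline
stability; MUD−MDD is the drift index.

Cycles are anchored trough-to-trough because end-of-exhale is the stable
resting phase of breathing.  A small fraction of cycles that do not
correlate with the majority pattern (coughs, swallows, tracker glitches)
may be discarded — at most 5% of cycles by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import AnalysisError
from .trace_io import RespTrace

#: Extremum prominence threshold as a fraction of the global
#: peak-to-peak range; suppresses cardiac/sensor ripples.
PROMINENCE_FRAC = 0.20

#: Minimum separation between detected troughs (s); physiological
#: breathing sits at 0.1–0.5 Hz, so 1 s excludes intra-cycle wiggles.
MIN_SEPARATION_S = 1.0

#: Common length cycles are resampled to before template correlation.
TEMPLATE_LEN = 101


@dataclass
class CycleSet:
    """Per-cycle decomposition of a trace.

    Cycle ``i`` spans samples ``trough_indices[i] .. trough_indices[i+1]``
    and contains ``peak_indices[i]``.  ``discarded`` holds cycle indices
    rejected by :func:`reject_outlier_cycles`.
    """

    trough_indices: np.ndarray
    peak_indices: np.ndarray
    amplitudes: np.ndarray   # cm, per-cycle peak - leading trough (A)
    periods: np.ndarray      # s, trough-to-trough (P)
    discarded: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int))

    @property
    def n_cycles(self) -> int:
        return len(self.amplitudes)

    @property
    def retained(self) -> np.ndarray:
        """Indices of cycles kept for analysis."""
        mask = np.ones(self.n_cycles, dtype=bool)
        mask[self.discarded] = False
        return np.nonzero(mask)[0]

    @property
    def retained_trough_indices(self) -> np.ndarray:
        """Sample indices of troughs bounding at least one retained cycle."""
        keep = self.retained
        idx = np.union1d(self.trough_indices[keep],
                         self.trough_indices[keep + 1])
        return idx.astype(int)

    def mean_period(self) -> float:
        """Mean trough-to-trough period of retained cycles (s)."""
        return float(np.mean(self.periods[self.retained]))


@dataclass
class DriftStats:
    """End-of-exhale baseline statistics (all in trace units)."""

    MEE: float       # mean end-of-exhale position
    MUD: float       # maximal upward drift position
    MDD: float       # maximal downward drift position
    mud_mdd: float   # MUD - MDD, the baseline-drift index


def segment_cycles(trace: RespTrace,
                   prominence_frac: float = PROMINENCE_FRAC,
                   min_separation_s: float = MIN_SEPARATION_S) -> CycleSet:
    """Locate end-of-exhale troughs and end-of-inhale peaks.

    Troughs are local minima with prominence at least ``prominence_frac``
    of the global peak-to-peak range and pairwise separation at least
    ``min_separation_s``.  Exactly one peak (the maximum sample) is taken
    between each pair of consecutive troughs, so troughs and peaks
    strictly alternate.  The amplitude of cycle ``i`` is the maximum of
    the cycle minus the value at its leading trough.

    Raises
    ------
    AnalysisError
        For a constant trace ("no oscillation detected") or fewer than
        two detected troughs.
    """
    x = trace.x
    ptp = float(np.max(x) - np.min(x))
    if ptp == 0.0:
        raise AnalysisError("no oscillation detected: trace is constant")
    distance = max(1, int(round(min_separation_s * trace.fs)))
    troughs, _ = find_peaks(-x, prominence=prominence_frac * ptp,
                            distance=distance)
    if len(troughs) < 2:
        raise AnalysisError(
            f"only {len(troughs)} trough(s) detected; need at least 2 "
            f"breathing cycles")
    peaks = np.empty(len(troughs) - 1, dtype=int)
    amplitudes = np.empty(len(troughs) - 1)
    for i in range(len(troughs) - 1):
        lo, hi = troughs[i], troughs[i + 1]
        peaks[i] = lo + int(np.argmax(x[lo:hi + 1]))
        amplitudes[i] = x[peaks[i]] - x[lo]
    periods = np.diff(trace.t[troughs])
    return CycleSet(trough_indices=troughs, peak_indices=peaks,
                    amplitudes=amplitudes, periods=periods)


def _cycle_templates(cycles: CycleSet, trace: RespTrace) -> np.ndarray:
    """Length-normalize every cycle to TEMPLATE_LEN samples."""
    grid = np.linspace(0.0, 1.0, TEMPLATE_LEN)
    out = np.empty((cycles.n_cycles, TEMPLATE_LEN))
    for i in range(cycles.n_cycles):
        lo = cycles.trough_indices[i]
        hi = cycles.trough_indices[i + 1]
        seg = trace.x[lo:hi + 1]
        out[i] = np.interp(grid, np.linspace(0.0, 1.0, len(seg)), seg)
    return out


def reject_outlier_cycles(cycles: CycleSet, trace: RespTrace,
                          max_fraction: float = 0.05,
                          r_min: float = 0.6) -> CycleSet:
    """Discard cycles uncorrelated with the majority breathing pattern.

    Every cycle is resampled to a common length and Pearson-correlated
    against the point-wise *median* cycle (robust to the very outliers
    being screened).  Cycles with r < ``r_min`` are discarded worst-first,
    up to a cap of ``floor(max_fraction * N)`` cycles but at least one
    whenever any cycle fails.  If more cycles fail than may be discarded,
    a warning is emitted and the worst offenders are removed.
    """
    if cycles.n_cycles < 3:
        raise AnalysisError("need at least 3 cycles for outlier screening")
    templates = _cycle_templates(cycles, trace)
    median_cycle = np.median(templates, axis=0)
    med_c = median_cycle - median_cycle.mean()
    med_norm = np.sqrt(np.sum(med_c ** 2))
    r = np.empty(cycles.n_cycles)
    for i, row in enumerate(templates):
        row_c = row - row.mean()
        denom = med_norm * np.sqrt(np.sum(row_c ** 2))
        r[i] = np.sum(row_c * med_c) / denom if denom > 0 else -1.0
    failing = np.nonzero(r < r_min)[0]
    if len(failing) == 0:
        return CycleSet(cycles.trough_indices, cycles.peak_indices,
                        cycles.amplitudes, cycles.periods,
                        discarded=np.array([], dtype=int))
    cap = max(1, int(np.floor(max_fraction * cycles.n_cycles)))
    if len(failing) > cap:
        warnings.warn(
            f"{len(failing)} cycles fall below r_min={r_min} but only "
            f"{cap} (max_fraction={max_fraction}) may be discarded; the "
            f"trace may be globally irregular", stacklevel=2)
    order = failing[np.argsort(r[failing])]     # worst first
    discarded = np.sort(order[:cap])
    return CycleSet(cycles.trough_indices, cycles.peak_indices,
                    cycles.amplitudes, cycles.periods, discarded=discarded)


def drift_stats(cycles: CycleSet, trace: RespTrace) -> DriftStats:
    """MEE / MUD / MDD and the drift index MUD−MDD.

    Computed on the end-of-exhale (trough) positions of retained cycles:
    ``MEE = mean(e_i)``, ``MUD = max(e_i)``, ``MDD = min(e_i)``.
    """
    if len(cycles.retained) < 2:
        raise AnalysisError("need at least 2 retained cycles for "
                            "drift statistics")
    e = trace.x[cycles.retained_trough_indices]
    mee, mud, mdd = float(np.mean(e)), float(np.max(e)), float(np.min(e))
    return DriftStats(MEE=mee, MUD=mud, MDD=mdd, mud_mdd=mud - mdd)
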