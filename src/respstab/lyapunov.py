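"""Largest Lyapunov exponent (LLE) by the divergence-curve method.

The trace is delay-embedded, each embedded point is paired with its
nearest neighbour outside a Theiler window (a minimum temporal separation
of one mean breathing period, excluding trivially correlated same-cycle
neighbours), and the mean log-distance of the pairs is followed as both
trajectories evolve.  The least-squares slope of this divergence curve
over the first mean period of expansion steps, expressed per second, is
the LLE estimate λ₁:

* λ₁ > 0 — initially close trajectories separate (chaotic/irregular
  dynamics);
* λ₁ ≈ 0 — purely regular (periodic) respiration;
* λ₁ < 0 — trajectories converge, i.e. the breathing pattern regularizes
  toward a stable orbit; more negative values mean faster regularization.

This mean-log-divergence construction (Rosenstein-style) is robust for
short, noisy physiological records.  Embedding parameters are chosen by
standard practice: the delay is the first lag where the autocorrelation
of x drops below 1/e, and the dimension is the smallest m ≤ 8 whose
false-nearest-neighbour fraction falls below 5%.

Exact duplicate points (distance 0) are never accepted as nearest
neighbours: a strictly periodic trace sampled commensurately revisits
itself exactly, and the informative neighbour is the nearest *distinct*
state, which yields a flat divergence curve and λ₁ → 0, the regular-
respiration limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, InputError
from .trace_io import RespTrace

MAX_EMBED_DIM = 8
FNN_THRESHOLD = 0.05
FNN_RTOL = 15.0       # Kennel distance-ratio criterion
FNN_ATOL = 2.0        # Kennel absolute-size criterion (vs signal SD)
FNN_SAMPLE_CAP = 4000  # FNN statistics are computed on at most this many pts


@dataclass
class LLEResult:
    """Divergence curve and fitted largest Lyapunov exponent."""

    tau: int                 # embedding delay, samples
    m: int                   # embedding dimension
    divergence: np.ndarray   # mean log-divergence per expansion step
    fit_range: tuple         # (first, last) step used for the slope fit
    lle: float               # slope of the fit, 1/s
    n_pairs: int             # neighbour pairs entering the curve


def _autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    a = x - np.mean(x)
    denom = float(np.dot(a, a))
    if denom == 0.0:
        raise InputError("autocorrelation undefined for a constant trace")
    full = np.correlate(a, a, mode="full")[len(a) - 1:]
    return full[:max_lag + 1] / denom


def _embed(x: np.ndarray, tau: int, m: int) -> np.ndarray:
    n = len(x) - (m - 1) * tau
    if n < 2:
        raise InputError("trace too short for the requested embedding")
    return np.column_stack([x[k * tau:k * tau + n] for k in range(m)])


def _nearest_distinct(points: np.ndarray, sub: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest neighbour with distance > 0 for each row (brute force)."""
    ref = points if sub is None else points[sub]
    n, nref = len(points), len(ref)
    scale = float(np.mean(np.sum(points ** 2, axis=1))) or 1.0
    zero_tol = 1e-14 * scale
    sq = np.sum(points ** 2, axis=1)
    sq_ref = np.sum(ref ** 2, axis=1)
    nn_idx = np.empty(nref, dtype=int)
    nn_d2 = np.empty(nref)
    chunk = max(1, int(2e7 // n))
    for lo in range(0, nref, chunk):
        hi = min(nref, lo + chunk)
        d2 = sq_ref[lo:hi, None] + sq[None, :] - 2.0 * ref[lo:hi] @ points.T
        rows = np.arange(lo, hi) if sub is None else sub[lo:hi]
        d2[np.arange(hi - lo), rows] = np.inf
        d2[d2 <= zero_tol] = np.inf
        nn_idx[lo:hi] = np.argmin(d2, axis=1)
        nn_d2[lo:hi] = d2[np.arange(hi - lo), nn_idx[lo:hi]]
    return nn_idx, np.sqrt(np.maximum(nn_d2, 0.0))


def choose_embedding(trace: RespTrace,
                     max_m: int = MAX_EMBED_DIM,
                     fnn_threshold: float = FNN_THRESHOLD
                     ) -> tuple[int, int]:
    """Select (tau, m) for delay embedding.

    tau: first lag where the autocorrelation of x drops below 1/e
    (fallback: a quarter of the dominant period if no such lag exists in
    the first half of the record).  m: smallest dimension ≤ ``max_m``
    whose false-nearest-neighbour fraction is below ``fnn_threshold``
    (fallback: 3).
    """
    x = np.asarray(trace.x, dtype=float)
    if len(x) < 1000:
        raise InputError(f"trace too short for LLE analysis "
                         f"({len(x)} samples; need >= 1000)")
    max_lag = len(x) // 2
    r = _autocorrelation(x, max_lag)
    below = np.nonzero(r < 1.0 / np.e)[0]
    below = below[below > 0]
    if len(below):
        tau = int(below[0])
    else:
        # Fallback: quarter of the dominant period from the spectrum.
        spec = np.abs(np.fft.rfft(x - x.mean()))
        spec[0] = 0.0
        f0_bin = int(np.argmax(spec))
        tau = max(1, int(round(len(x) / f0_bin / 4))) if f0_bin else 1

    # False-nearest-neighbour fraction on a capped subsample.
    stride = max(1, len(x) // FNN_SAMPLE_CAP)
    sigma = float(np.std(x))
    m_sel = None
    for m in range(2, max_m + 1):
        emb = _embed(x, tau, m + 1)   # need the (m+1)-th coordinate
        pts_m = emb[:, :m]
        sub = np.arange(0, len(pts_m), stride)
        nn_idx, nn_d = _nearest_distinct(pts_m, sub=sub)
        extra = np.abs(emb[sub, m] - emb[nn_idx, m])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = extra / nn_d
        d_m1 = np.sqrt(nn_d ** 2 + extra ** 2)
        false = (ratio > FNN_RTOL) | (d_m1 / sigma > FNN_ATOL)
        ok = np.isfinite(ratio)
        if ok.sum() == 0:
            continue
        if float(np.mean(false[ok])) < fnn_threshold:
            m_sel = m
            break
    if m_sel is None:
        m_sel = 3
    return tau, m_sel


def lle_estimate(trace: RespTrace, tau: int, m: int, theiler: int,
                 max_steps: int | None = None,
                 fit_range: tuple[int, int] | None = None) -> LLEResult:
    """Largest Lyapunov exponent from the mean log-divergence curve.

    Parameters
    ----------
    trace : RespTrace
    tau, m : int
        Embedding delay (samples) and dimension.
    theiler : int
        Theiler window in samples; nearest-neighbour candidates within
        this temporal distance are excluded.  Use at least one mean
        breathing period.
    max_steps : int, optional
        Expansion horizon in samples (default: ``theiler``, one period).
    fit_range : (int, int), optional
        First/last expansion step of the least-squares fit (default:
        ``(0, max_steps)`` — the first mean period of expansion).

    Notes
    -----
    The pair set is fixed up front: reference points are restricted so
    that every pair supports the full expansion horizon, keeping the
    composition of the divergence curve constant across steps (no
    survivorship tilt of the slope).

    Raises
    ------
    AnalysisError
        If no valid neighbour pair exists.
    """
    if tau < 1 or m < 2:
        raise InputError("need tau >= 1 and m >= 2")
    x = np.asarray(trace.x, dtype=float)
    emb = _embed(x, tau, m)
    n_emb = len(emb)
    if max_steps is None:
        max_steps = int(theiler)
    max_steps = int(max_steps)
    n_ref = n_emb - max_steps
    if n_ref < 100:
        raise InputError("embedded trajectory too short for the requested "
                         "expansion horizon (need >= 100 reference points)")

    pts = emb[:n_ref]
    sq = np.sum(pts ** 2, axis=1)
    scale = float(np.mean(sq)) or 1.0
    zero_tol = 1e-14 * scale
    theiler = int(theiler)
    nn = np.full(n_ref, -1, dtype=int)
    nn_ok = np.zeros(n_ref, dtype=bool)
    chunk = max(1, int(2e7 // n_ref))
    for lo in range(0, n_ref, chunk):
        hi = min(n_ref, lo + chunk)
        d2 = sq[lo:hi, None] + sq[None, :] - 2.0 * pts[lo:hi] @ pts.T
        rows = np.arange(lo, hi)
        # Theiler band and exact duplicates are invalid candidates.
        cols = np.arange(n_ref)
        band = np.abs(cols[None, :] - rows[:, None]) <= theiler
        d2[band] = np.inf
        d2[d2 <= zero_tol] = np.inf
        idx = np.argmin(d2, axis=1)
        good = np.isfinite(d2[np.arange(hi - lo), idx])
        nn[lo:hi] = idx
        nn_ok[lo:hi] = good
    refs = np.nonzero(nn_ok)[0]
    if len(refs) == 0:
        raise AnalysisError("no valid neighbour pairs for LLE estimation")
    nbrs = nn[refs]

    steps = np.arange(max_steps + 1)
    divergence = np.empty(len(steps))
    for i in steps:
        d = np.linalg.norm(emb[refs + i] - emb[nbrs + i], axis=1)
        # Pairs whose separation underflows to exactly zero at this step
        # (bit-identical states) have no finite log-distance; skip them.
        d = d[d > 0.0]
        divergence[i] = (float(np.mean(np.log(d))) if len(d)
                         else np.nan)

    if fit_range is None:
        fit_range = (0, max_steps)
    lo_s, hi_s = int(fit_range[0]), int(fit_range[1])
    if hi_s <= lo_s or hi_s > max_steps:
        raise InputError(f"invalid fit_range {fit_range}")
    sel = steps[lo_s:hi_s + 1]
    curve = divergence[lo_s:hi_s + 1]
    ok = np.isfinite(curve)
    if ok.sum() < 2:
        raise AnalysisError("divergence curve degenerate over the fit range")
    slope = float(np.polyfit(sel[ok], curve[ok], 1)[0])
    lle = slope * trace.fs   # per step -> per second
    return LLEResult(tau=int(tau), m=int(m), divergence=divergence,
                     fit_range=(lo_s, hi_s), lle=lle, n_pairs=len(refs))
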