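"""Phase-space portrait and modified Poincaré section.

The phase-space portrait plots velocity v(t) against displacement x(t);
periodic breathing traces closed loops, and the spread of the loops
encodes amplitude and baseline irregularity.

The Poincaré section intersects the trajectory with a transverse plane
and records one discrete sample per crossing — deliberately *without*
sub-sample interpolation, so both coordinates retain variation.  The
dispersion of the crossing points along the displacement axis (SD_x) and
the velocity axis (SD_v) quantifies amplitude irregularity.

Two section placements are provided:

* ``mode="turnaround"`` (default) — the plane sits at the midrange of the
  *velocity* coordinate (≈ 0 for quasi-symmetric breathing); downward
  crossings are the end-of-inhale turnarounds, one per cycle.  The x
  coordinates of the section points are then the per-cycle end-of-inhale
  positions, so SD_x responds directly to amplitude jitter and baseline
  drift while remaining insensitive to period jitter.  This placement
  reproduces the clinically observed ordering of SD_x / SD_v across
  regular and irregular breathing patterns and is the one used by the
  classifier.
* ``mode="midrange"`` — the classical one-sided section: the plane sits on
  the displacement coordinate halfway between the global maximum and
  minimum of respiration, and upward (exhale→inhale) crossings are
  recorded.  Because the recorded sample lies within one sampling step of
  the plane, SD_x is bounded by v/fs under this placement; it is kept for
  comparison and diagnostic use.

Crossing detection uses a Schmitt-trigger hysteresis (default 20% of the
half-range of the section coordinate): after a crossing is recorded the
detector re-arms only once the trajectory has retreated beyond the
hysteresis band, so sensor noise near the plane (e.g. v ≈ 0 on the
end-of-exhale plateau) cannot create spurious section points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, InputError
from .trace_io import RespTrace

HYSTERESIS_FRAC = 0.2


@dataclass
class PhasePortrait:
    """Displacement/velocity trajectory sampled at ``fs`` Hz."""

    x: np.ndarray   # cm
    v: np.ndarray   # cm/s
    fs: float

    def __post_init__(self) -> None:
        if len(self.x) != len(self.v):
            raise InputError("x and v must have the same length")


@dataclass
class PoincareResult:
    """Section crossing points and their dispersion indices."""

    points: np.ndarray      # (k, 2) array of (x_k, v_k)
    plane_level: float      # level of the section plane (cm or cm/s)
    mode: str               # "turnaround" or "midrange"
    direction: str          # "up" or "down"
    sd_x: float             # population SD of x_k (cm)
    sd_v: float             # population SD of v_k (cm/s)


def estimate_velocity(trace: RespTrace,
                      smooth_window: int = 0) -> PhasePortrait:
    """Velocity by central differences, one-sided at the endpoints.

    ``smooth_window`` > 1 applies a moving-average pre-smoothing to x
    (reflect-padded, so the ends are not biased); the returned portrait
    carries the smoothed displacement so that (x, v) stay consistent.
    """
    x = np.asarray(trace.x, dtype=float)
    if len(x) < 3:
        raise InputError("need at least 3 samples to estimate velocity")
    if smooth_window and smooth_window > 1:
        w = int(smooth_window)
        kernel = np.ones(w) / w
        pad = w // 2
        xp = np.pad(x, (pad, pad + (w % 2 == 0)), mode="reflect")
        x = np.convolve(xp, kernel, mode="valid")[:len(trace.x)]
    v = np.gradient(x) * trace.fs
    return PhasePortrait(x=x, v=v, fs=trace.fs)


def _hysteresis_crossings(c: np.ndarray, level: float, h: float,
                          direction: str) -> np.ndarray:
    """Indices of the first sample at-or-after each accepted crossing.

    ``direction="up"``: crossings c[i] < level <= c[i+1], armed once c has
    been <= level - h.  ``direction="down"``: mirrored.  The detector
    starts armed if the trace begins beyond the arming band; with h = 0
    every raw crossing is accepted.
    """
    if direction == "down":
        c = -np.asarray(c)
        level = -level
    else:
        c = np.asarray(c)
    hits = []
    armed = c[0] <= level - h
    for i in range(len(c) - 1):
        if not armed and c[i] <= level - h:
            armed = True
        if armed and c[i] < level <= c[i + 1]:
            hits.append(i + 1)
            armed = h == 0.0
    return np.asarray(hits, dtype=int)


def poincare_section(portrait: PhasePortrait,
                     mode: str = "turnaround",
                     direction: str | None = None,
                     hysteresis_frac: float | None = None,
                     valid: np.ndarray | None = None,
                     ddof: int = 0) -> PoincareResult:
    """Modified Poincaré section of a phase-space portrait.

    Parameters
    ----------
    portrait : PhasePortrait
    mode : {"turnaround", "midrange"}
        Section placement (see module docstring).
    direction : {"up", "down"}, optional
        Crossing direction; defaults to "down" for turnaround (one
        end-of-inhale point per cycle) and "up" for midrange.
    hysteresis_frac : float, optional
        Schmitt-trigger band as a fraction of the half-range of the
        section coordinate.  Defaults to 0.2 for turnaround mode and
        0.0 (spec-literal raw crossings) for midrange mode.
    valid : bool array, optional
        Per-sample mask; samples outside the mask (e.g. discarded
        outlier cycles) contribute neither to the plane level nor to the
        recorded crossings.
    ddof : int
        Degrees of freedom for the SDs (0 = population SD, the default).

    Returns
    -------
    PoincareResult

    Raises
    ------
    AnalysisError
        If fewer than two crossings are found.
    """
    if mode not in ("turnaround", "midrange"):
        raise InputError(f"unknown Poincaré mode {mode!r}")
    coord = portrait.v if mode == "turnaround" else portrait.x
    if direction is None:
        direction = "down" if mode == "turnaround" else "up"
    if direction not in ("up", "down"):
        raise InputError(f"unknown crossing direction {direction!r}")
    if hysteresis_frac is None:
        hysteresis_frac = HYSTERESIS_FRAC if mode == "turnaround" else 0.0

    if valid is None:
        valid = np.ones(len(coord), dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
        if len(valid) != len(coord):
            raise InputError("valid mask length must match the portrait")
    cmax = float(np.max(coord[valid]))
    cmin = float(np.min(coord[valid]))
    level = 0.5 * (cmax + cmin)
    h = hysteresis_frac * 0.5 * (cmax - cmin)

    hits = _hysteresis_crossings(coord, level, h, direction)
    hits = hits[valid[hits] & valid[np.maximum(hits - 1, 0)]]
    if len(hits) < 2:
        raise AnalysisError("insufficient cycles for Poincaré section "
                            f"({len(hits)} crossing(s) found)")
    points = np.column_stack([portrait.x[hits], portrait.v[hits]])
    sd_x = float(np.std(points[:, 0], ddof=ddof))
    sd_v = float(np.std(points[:, 1], ddof=ddof))
    return PoincareResult(points=points, plane_level=level, mode=mode,
                          direction=direction, sd_x=sd_x, sd_v=sd_v)
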