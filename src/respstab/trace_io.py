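"""Respiration-trace container and file I/O.

A respiration trace is a uniformly sampled time–amplitude series: the
anterior–posterior surface displacement (in the tracker's distance units,
assumed cm) of a marker followed by an optical respiratory-gating camera,
at a fixed sampling rate (tens of Hz).

Two plain-text formats are supported:

* **csv** — two numeric columns ``time_s, amplitude``; ``#`` comment lines
  are ignored; no header required.
* **vxp dialect** — a minimal self-describing export format in the style of
  optical-gating vendor files: ``key=value`` header lines up to a
  ``[Data]`` marker, then one amplitude sample per line.  The only required
  key is ``samples_per_second``.

Amplitude units are carried as metadata and never rescaled implicitly; all
downstream cutoffs are expressed in trace units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

#: Assumed sampling rate (Hz) for headerless sources that do not state one.
DEFAULT_FS = 25.0

#: Allowed deviation of csv time steps from the median step, as a fraction
#: of the median step, before the grid is rejected as non-uniform.
UNIFORMITY_TOL = 0.10

_VXP_DATA_MARKER = "[Data]"


@dataclass
class RespTrace:
    """Uniformly sampled (time, displacement) respiration series.

    Attributes
    ----------
    t : np.ndarray
        Sample times in seconds, a strictly increasing uniform grid.
    x : np.ndarray
        Displacement samples in trace units (assumed cm).
    fs : float
        Sampling rate in Hz; ``t[i+1] - t[i] == 1/fs``.
    meta : dict
        Free-form source annotations (units, source file, device notes).
    """

    t: np.ndarray
    x: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.ndim != 1 or self.x.ndim != 1:
            raise InputError("t and x must be one-dimensional arrays")
        if len(self.t) != len(self.x):
            raise InputError("t and x must have the same length")
        if len(self.t) < 2:
            raise InputError("a trace needs at least 2 samples")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.x)):
            raise InputError("displacement samples must be finite")
        steps = np.diff(self.t)
        if np.any(steps <= 0):
            raise InputError("time grid must be strictly increasing")
        if np.max(np.abs(steps - 1.0 / self.fs)) > 1e-9:
            raise InputError("time grid is not uniform at 1/fs within 1e-9 s")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Recording span t[-1] - t[0] in seconds."""
        return float(self.t[-1] - self.t[0])

    def copy(self, **updates) -> "RespTrace":
        kwargs = dict(t=self.t.copy(), x=self.x.copy(), fs=self.fs,
                      meta=dict(self.meta))
        kwargs.update(updates)
        return RespTrace(**kwargs)


def uniform_time_grid(t0: float, n: int, fs: float) -> np.ndarray:
    """Canonical uniform grid ``t0 + arange(n)/fs`` used by all constructors."""
    return t0 + np.arange(n) / fs


def _sniff_format(path: str) -> str:
    with open(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == _VXP_DATA_MARKER or ("=" in line and "," not in line):
                return "vxp"
            return "csv"
    raise InputError(f"empty trace file: {path}")


def read_trace(path: str, format: str = "auto") -> RespTrace:
    """Read a respiration trace from ``path``.

    Parameters
    ----------
    path : str
        File to read.
    format : {"auto", "csv", "vxp"}
        ``auto`` decides by file extension, falling back to content sniffing.

    Returns
    -------
    RespTrace

    Raises
    ------
    InputError
        Empty file, non-monotonic time, or a csv time grid whose deviation
        from uniformity exceeds 10% of the median step (use :func:`resample`
        on explicitly constructed data instead).
    """
    if not os.path.exists(path):
        raise InputError(f"trace file does not exist: {path}")
    if format == "auto":
        ext = os.path.splitext(path)[1].lower()
        if ext == ".vxp":
            format = "vxp"
        elif ext in (".csv", ".txt"):
            format = _sniff_format(path)
        else:
            format = _sniff_format(path)
    if format == "csv":
        return _read_csv(path)
    if format == "vxp":
        return _read_vxp(path)
    raise InputError(f"unknown trace format: {format!r}")


def _read_csv(path: str) -> RespTrace:
    # An optional "# samples_per_second=<fs>" comment (written by
    # write_trace) makes the rate round-trip exactly; otherwise the rate
    # is recovered from the median time step.
    fs_hint = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            if "samples_per_second=" in line:
                fs_hint = float(line.split("samples_per_second=")[1])
    try:
        data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    except ValueError as exc:
        raise InputError(f"cannot parse csv trace {path}: {exc}") from exc
    if data.size == 0:
        raise InputError(f"empty trace file: {path}")
    if data.shape[1] != 2:
        raise InputError(
            f"csv trace must have two columns (time_s, amplitude), "
            f"got {data.shape[1]} in {path}")
    t_raw, x = data[:, 0], data[:, 1]
    if len(t_raw) < 2:
        raise InputError(f"trace {path} has fewer than 2 samples")
    steps = np.diff(t_raw)
    if np.any(steps <= 0):
        raise InputError(f"non-monotonic time column in {path}")
    med = float(np.median(steps))
    if np.max(np.abs(steps - med)) > UNIFORMITY_TOL * med:
        raise InputError(
            f"time grid in {path} deviates from uniformity by more than "
            f"{UNIFORMITY_TOL:.0%} of the median step; load the columns "
            f"yourself and use respstab.trace_io.resample")
    fs = fs_hint if fs_hint is not None else 1.0 / med
    t = uniform_time_grid(float(t_raw[0]), len(x), fs)
    return RespTrace(t=t, x=x.astype(float), fs=fs,
                     meta={"source": path, "format": "csv"})


def _read_vxp(path: str) -> RespTrace:
    header: dict[str, str] = {}
    samples: list[float] = []
    in_data = False
    with open(path, "r") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == _VXP_DATA_MARKER:
                in_data = True
                continue
            if not in_data:
                if "=" not in line:
                    raise InputError(
                        f"malformed vxp header line in {path}: {line!r}")
                key, _, value = line.partition("=")
                header[key.strip()] = value.strip()
            else:
                try:
                    samples.append(float(line))
                except ValueError as exc:
                    raise InputError(
                        f"bad vxp sample in {path}: {line!r}") from exc
    if not samples:
        raise InputError(f"vxp file {path} contains no samples")
    if "samples_per_second" not in header:
        raise InputError(
            f"vxp file {path} lacks required key samples_per_second")
    fs = float(header["samples_per_second"])
    if fs <= 0:
        raise InputError(f"non-positive samples_per_second in {path}")
    t0 = float(header.get("start_time_s", 0.0))
    x = np.array(samples, dtype=float)
    meta = {"source": path, "format": "vxp"}
    meta.update({k: v for k, v in header.items()
                 if k not in ("samples_per_second", "start_time_s")})
    return RespTrace(t=uniform_time_grid(t0, len(x), fs), x=x, fs=fs,
                     meta=meta)


def write_trace(trace: RespTrace, path: str, format: str = "csv") -> None:
    """Write ``trace`` so that :func:`read_trace` reproduces it exactly.

    Full ``repr`` float precision is used, so the round trip is
    bit-identical in both sample values and sampling rate.
    """
    if format == "csv":
        with open(path, "w") as fh:
            fh.write("# respstab trace: time_s,amplitude\n")
            fh.write(f"# samples_per_second={float(trace.fs)!r}\n")
            for ti, xi in zip(trace.t, trace.x):
                fh.write(f"{float(ti)!r},{float(xi)!r}\n")
    elif format == "vxp":
        with open(path, "w") as fh:
            fh.write(f"samples_per_second={trace.fs!r}\n")
            fh.write(f"start_time_s={float(trace.t[0])!r}\n")
            for key, value in trace.meta.items():
                if key in ("source", "format"):
                    continue
                fh.write(f"{key}={value}\n")
            fh.write(_VXP_DATA_MARKER + "\n")
            for xi in trace.x:
                fh.write(f"{float(xi)!r}\n")
    else:
        raise InputError(f"unknown trace format: {format!r}")


def resample(trace: RespTrace, fs_new: float) -> RespTrace:
    """Linearly interpolate ``trace`` onto a uniform grid at ``fs_new`` Hz.

    The new grid spans ``[t[0], t[-1]]``; both endpoints are grid nodes.
    Resampling at the trace's own rate returns the samples unchanged.
    """
    if not np.isfinite(fs_new) or fs_new <= 0:
        raise InputError(f"fs_new must be positive, got {fs_new}")
    t0, t1 = float(trace.t[0]), float(trace.t[-1])
    n_new = int(np.floor((t1 - t0) * fs_new + 1e-9)) + 1
    t_new = uniform_time_grid(t0, n_new, fs_new)
    x_new = np.interp(t_new, trace.t, trace.x)
    meta = dict(trace.meta)
    meta["resampled_from_fs"] = trace.fs
    return RespTrace(t=t_new, x=x_new, fs=float(fs_new), meta=meta)
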