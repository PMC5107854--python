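"""Four-group respiratory-pattern classification, ROC cutoff derivation,
and ANOVA/Scheffé group-difference testing.

The taxonomy crosses two binary verdicts — amplitude regularity (from the
Poincaré dispersion SD_x) and period regularity (from the fundamental
spectral peak A1) — into four groups:

====== =================== ==================
Group  amplitude regular?  period regular?
====== =================== ==================
A      yes                 yes
B      yes                 no
C      no                  yes
D      no                  no
====== =================== ==================

each subdivided by the presence of baseline drift (MUD−MDD above the
drift cutoff).  The default cutoffs are the published ROC-derived values
(0.11 for SD_x, 0.062 for SD_v, 0.117 for A1, 0.349 for MUD−MDD); they
are expressed in trace units and are calibration-dependent on the
amplitude units and on the A1 normalization convention (here: one-sided
amplitude spectrum, 2/N scaling).  Boundary values classify as regular
(inclusive comparisons toward regular).  Note the direction of the A1
rule: a *taller* fundamental peak means a *more regular* period, so the
pattern is period-irregular iff A1 < cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError, InputError

ALPHA = 0.05


@dataclass
class Cutoffs:
    """Decision thresholds, in trace units.  Defaults are the published
    ROC-derived values; ``provenance`` records where they came from."""

    sd_x_cut: float = 0.11    # cm; amplitude regular iff SD_x <= this
    sd_v_cut: float = 0.062   # cm/s; reported, not in the primary rule
    a1_cut: float = 0.117     # trace units; period regular iff A1 >= this
    drift_cut: float = 0.349  # cm; drift present iff MUD-MDD > this
    a1_direction_regular_if_ge: bool = True
    provenance: str = "published ROC cutoffs (visual reference standard)"

    def __post_init__(self) -> None:
        if min(self.sd_x_cut, self.sd_v_cut, self.a1_cut,
               self.drift_cut) <= 0:
            raise InputError("all cutoffs must be positive")


@dataclass
class StabilityReport:
    """All stability indices and the resulting group assignment."""

    sd_x: float
    sd_v: float
    a1: float
    mud_mdd: float
    lle: float | None = None
    amp_regular: bool | None = None
    period_regular: bool | None = None
    drift_present: bool | None = None
    group: str | None = None
    cutoffs_used: Cutoffs | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "sd_x": self.sd_x, "sd_v": self.sd_v, "a1": self.a1,
            "mud_mdd": self.mud_mdd, "lle": self.lle,
            "amp_regular": self.amp_regular,
            "period_regular": self.period_regular,
            "drift_present": self.drift_present, "group": self.group,
        }
        if self.cutoffs_used is not None:
            out["cutoffs"] = {
                "sd_x_cut": self.cutoffs_used.sd_x_cut,
                "sd_v_cut": self.cutoffs_used.sd_v_cut,
                "a1_cut": self.cutoffs_used.a1_cut,
                "drift_cut": self.cutoffs_used.drift_cut,
                "provenance": self.cutoffs_used.provenance,
            }
        out.update(self.extras)
        return out


def classify_trace(sd_x: float, sd_v: float, a1: float, mud_mdd: float,
                   lle: float | None = None,
                   cutoffs: Cutoffs | None = None,
                   amp_rule: str = "sd_x") -> StabilityReport:
    """Assign the four-group label from the stability indices.

    ``amp_rule`` selects the amplitude-regularity test: ``"sd_x"`` (the
    default; strongest single index), ``"sd_v"``, or ``"both"`` (regular
    only if both dispersions pass).  SD_v is always reported.
    """
    cutoffs = cutoffs or Cutoffs()
    for name, value in (("sd_x", sd_x), ("sd_v", sd_v), ("a1", a1),
                        ("mud_mdd", mud_mdd)):
        if not math.isfinite(value):
            raise InputError(f"non-finite index {name}={value}")
    if amp_rule not in ("sd_x", "sd_v", "both"):
        raise InputError(f"unknown amp_rule {amp_rule!r}")
    by_x = sd_x <= cutoffs.sd_x_cut
    by_v = sd_v <= cutoffs.sd_v_cut
    amp_regular = {"sd_x": by_x, "sd_v": by_v, "both": by_x and by_v}[amp_rule]
    if cutoffs.a1_direction_regular_if_ge:
        period_regular = a1 >= cutoffs.a1_cut
    else:
        period_regular = a1 <= cutoffs.a1_cut
    drift_present = mud_mdd > cutoffs.drift_cut
    if amp_regular:
        group = "A" if period_regular else "B"
    else:
        group = "C" if period_regular else "D"
    return StabilityReport(sd_x=sd_x, sd_v=sd_v, a1=a1, mud_mdd=mud_mdd,
                           lle=lle, amp_regular=bool(amp_regular),
                           period_regular=bool(period_regular),
                           drift_present=bool(drift_present), group=group,
                           cutoffs_used=cutoffs)


@dataclass
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    flipped: bool   # True if scores were negated to orient AUC >= 0.5


def roc_cutoff(scores, labels) -> RocResult:
    """ROC analysis of one index against binary regular/irregular labels.

    AUC by the Mann–Whitney identity (ties counted 1/2); the cutoff
    maximizes Youden's J and is reported as the midpoint between the
    adjacent distinct scores.  If AUC < 0.5 the score orientation is
    flipped (recorded in ``flipped``) so the returned AUC is >= 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise InputError("scores and labels must be 1-D and equally long")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise InputError("roc_cutoff needs both classes present")

    ranks = sps.rankdata(scores)   # average ranks -> ties count 1/2
    auc = (float(np.sum(ranks[labels == 1])) - n_pos * (n_pos + 1) / 2.0) \
        / (n_pos * n_neg)
    flipped = auc < 0.5
    eff = -scores if flipped else scores
    if flipped:
        auc = 1.0 - auc

    # Candidate thresholds: midpoints between adjacent distinct scores,
    # plus outer sentinels.
    distinct = np.unique(eff)
    if len(distinct) == 1:
        mids = np.array([distinct[0]])
    else:
        mids = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for thr in mids:
        pred = eff >= thr
        sens = float(np.sum(pred & (labels == 1))) / n_pos
        spec = float(np.sum(~pred & (labels == 0))) / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    _, thr, sens, spec = best
    cutoff = -thr if flipped else thr
    return RocResult(auc=auc, cutoff=float(cutoff), sensitivity=sens,
                     specificity=spec, flipped=bool(flipped))


@dataclass
class AnovaResult:
    F: float
    p: float
    pairwise: dict          # (g1, g2) -> significant at alpha (Scheffé)
    subsets: str            # homogeneous subsets, e.g. "A, B < C, D"


def anova_scheffe(groups: dict, alpha: float = ALPHA) -> AnovaResult:
    """One-way ANOVA with Scheffé post hoc pairwise comparisons.

    Parameters
    ----------
    groups : dict
        Mapping of group name to 1-D array of index values; at least two
        groups of at least two values each.

    Returns
    -------
    AnovaResult
        Includes a homogeneous-subset string in increasing order of group
        mean (e.g. ``"A, B < C, D"``); groups within one subset do not
        differ significantly from any other member of the subset.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(names) < 2 or any(len(d) < 2 for d in data):
        raise InputError("need >= 2 groups with >= 2 values each")
    k = len(names)
    n_total = sum(len(d) for d in data)
    grand = np.concatenate(data)
    ssw = sum(float(np.sum((d - d.mean()) ** 2)) for d in data)
    if ssw == 0.0 and np.all(grand == grand[0]):
        raise AnalysisError("zero variance: all values identical")
    F, p = sps.f_oneway(*data)
    msw = ssw / (n_total - k)
    crit = (k - 1) * sps.f.ppf(1 - alpha, k - 1, n_total - k)
    pairwise = {}
    for i in range(k):
        for j in range(i + 1, k):
            di, dj = data[i], data[j]
            diff2 = (di.mean() - dj.mean()) ** 2
            denom = msw * (1.0 / len(di) + 1.0 / len(dj))
            stat = diff2 / denom if denom > 0 else np.inf
            pairwise[(names[i], names[j])] = bool(stat > crit)

    # Homogeneous subsets in increasing order of mean.
    order = sorted(range(k), key=lambda i: data[i].mean())
    subsets: list[list[int]] = []
    for idx in order:
        placed = False
        if subsets:
            current = subsets[-1]
            if not any(pairwise[tuple(sorted((names[idx], names[o]),
                                             key=names.index))]
                       for o in current):
                current.append(idx)
                placed = True
        if not placed:
            subsets.append([idx])
    subset_str = " < ".join(", ".join(names[i] for i in s) for s in subsets)
    return AnovaResult(F=float(F), p=float(p), pairwise=pairwise,
                       subsets=subset_str)


@dataclass
class CohortReport:
    """Per-trace indices plus cohort-level summaries."""

    table: pd.DataFrame                  # one row per trace
    group_stats: pd.DataFrame | None     # mean/SD per group per index
    anova: dict                          # index -> AnovaResult
    roc: dict                            # index -> RocResult (needs labels)
    cutoffs: Cutoffs


def cohort_report(traces, cutoffs: Cutoffs | None = None,
                  labels=None, with_lle: bool = False,
                  config=None) -> CohortReport:
    """Analyze a cohort of traces and summarize group differences.

    Parameters
    ----------
    traces : sequence of RespTrace
    cutoffs : Cutoffs, optional
    labels : sequence of str, optional
        Ground-truth group labels ("A".."D"); when given, group summary
        statistics and ANOVA are computed over these labels and ROC
        cutoffs are re-derived for each index against the implied binary
        regular/irregular reference (amplitude irregular = C/D, period
        irregular = B/D, drift from MUD−MDD is not re-derived without a
        drift reference).
    with_lle : bool
        Also estimate the LLE per trace (slow; off by default).

    Per-trace analysis errors are recorded as flagged rows, not raised.
    """
    from .pipeline import RunConfig, analyze_trace  # local: avoid cycle

    cutoffs = cutoffs or Cutoffs()
    cfg = config or RunConfig()
    rows = []
    for i, trace in enumerate(traces):
        row = {"trace": i}
        try:
            rep = analyze_trace(trace, config=cfg, cutoffs=cutoffs,
                                with_lle=with_lle)
            row.update(rep.to_dict())
            row.pop("cutoffs", None)
            row["error"] = ""
        except (InputError, AnalysisError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    if labels is not None:
        table["true_group"] = list(labels)

    indices = ["sd_x", "sd_v", "a1", "mud_mdd"]
    ok = table[table["error"] == ""] if "error" in table else table
    group_col = "true_group" if labels is not None else "group"
    group_stats = None
    anova: dict = {}
    roc: dict = {}
    if group_col in ok and ok[group_col].nunique() > 1 and len(ok) > 3:
        group_stats = ok.groupby(group_col)[indices].agg(["mean", "std"])
        for idx in indices:
            grouped = {g: sub[idx].to_numpy()
                       for g, sub in ok.groupby(group_col)
                       if len(sub) >= 2}
            if len(grouped) >= 2:
                try:
                    anova[idx] = anova_scheffe(grouped)
                except (InputError, AnalysisError):
                    pass
    if labels is not None and len(ok) > 3:
        truth = ok[group_col]
        refs = {"sd_x": truth.isin(["C", "D"]),
                "sd_v": truth.isin(["C", "D"]),
                "a1": truth.isin(["B", "D"])}
        for idx, ref in refs.items():
            if ref.nunique() == 2:
                roc[idx] = roc_cutoff(ok[idx].to_numpy(),
                                      ref.to_numpy().astype(int))
    return CohortReport(table=table, group_stats=group_stats, anova=anova,
                        roc=roc, cutoffs=cutoffs)
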