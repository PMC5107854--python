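"""Independent oracle implementations used only by the tests.

Each routine here re-derives a quantity along a deliberately different
route from the package (plain loops, direct definitions, closed forms) so
that agreement is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np


def brute_force_auc(scores, labels) -> float:
    """AUC by direct pair counting: P(score_pos > score_neg) + 0.5 ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oneway_f(groups) -> float:
    """Textbook one-way ANOVA F from explicit sums of squares."""
    data = [np.asarray(g, dtype=float) for g in groups]
    all_values = np.concatenate(data)
    grand = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in data)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in data)
    df_b = len(data) - 1
    df_w = len(all_values) - len(data)
    return (ss_between / df_b) / (ss_within / df_w)


def rosenstein_lle(x, fs, tau, m, theiler, max_steps):
    """Independent largest-Lyapunov estimate (mean log-divergence slope).

    Plain-loop implementation: explicit delay vectors, per-point linear
    scan for the nearest distinct neighbour outside the Theiler window,
    restricted to points that support the full expansion horizon, and a
    hand-written least-squares slope.  Returns the exponent in 1/s.
    """
    x = np.asarray(x, dtype=float)
    n_emb = len(x) - (m - 1) * tau
    emb = np.array([[x[i + k * tau] for k in range(m)]
                    for i in range(n_emb)])
    n_ref = n_emb - max_steps
    neighbours = {}
    for j in range(n_ref):
        diffs = emb[:n_ref] - emb[j]
        dist = np.sqrt((diffs ** 2).sum(axis=1))
        best, best_d = -1, np.inf
        for k in range(n_ref):
            if abs(k - j) <= theiler or dist[k] <= 0.0:
                continue
            if dist[k] < best_d:
                best, best_d = k, dist[k]
        if best >= 0:
            neighbours[j] = best
    curve = []
    for i in range(max_steps + 1):
        logs = []
        for j, k in neighbours.items():
            d = np.sqrt(((emb[j + i] - emb[k + i]) ** 2).sum())
            if d > 0.0:
                logs.append(np.log(d))
        curve.append(float(np.mean(logs)))
    steps = np.arange(len(curve), dtype=float)
    curve = np.asarray(curve)
    sx = steps - steps.mean()
    slope = float((sx * (curve - curve.mean())).sum() / (sx ** 2).sum())
    return slope * fs
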