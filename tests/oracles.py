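"""Independent brute-force oracles: plain-Python loop implementations used to
verify the vectorized package code.  Deliberately naive and kept free of any
package internals."""

from __future__ import annotations

import math


def two_pass_mean_sd(values):
    """Textbook two-pass sample mean / SD (n-1)."""
    vals = [v for v in values if v == v]  # drop NaN
    n = len(vals)
    mean = sum(vals) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return mean, math.sqrt(var)


def fractional_rank(values):
    """O(n^2) fractional ranks (rank/n, ascending, mean rank for ties)."""
    n = len(values)
    out = []
    for v in values:
        below = sum(1 for u in values if u < v)
        ties = sum(1 for u in values if u == v)
        mean_rank = below + (1 + ties) / 2.0  # mean of ranks below+1 .. below+ties
        out.append(mean_rank / n)
    return out


def centralized(values):
    return [2.0 * r - 1.0 for r in fractional_rank(values)]


def component_z(subject_row, comp, ref_mean, ref_sd):
    """Z-score of one component for one subject (dict-of-values row)."""
    if comp["aggregation"] == "group_mixed_unit":
        zs = [
            (subject_row[m] - ref_mean[m]) / ref_sd[m] for m in comp["members"]
        ]
        return sum(zs) / len(zs)
    if comp["aggregation"] == "group_same_unit":
        total = sum(subject_row[m] for m in comp["members"])
        cid = comp["component_id"]
        return (total - ref_mean[cid]) / ref_sd[cid]
    cid = comp["component_id"]
    return (subject_row[cid] - ref_mean[cid]) / ref_sd[cid]


def zref_scores(rows, comps, coef, ref_mean, ref_sd):
    """Loop-and-sum z-referenced index per subject (WDI-G/P family)."""
    out = []
    for row in rows:
        total = 0.0
        for comp in comps:
            total += component_z(row, comp, ref_mean, ref_sd) * coef[comp["component_id"]]
        out.append(total / len(comps))
    return out


def weight_then_z_scores(rows, ids, coef):
    """Weight-then-standardize index per subject (WDI-I / WDI-FG core):
    multiply each column by its coefficient, z-score the weighted column
    within the cohort, average over columns."""
    weighted = {i: [r[i] * coef[i] for r in rows] for i in ids}
    stats = {i: two_pass_mean_sd(weighted[i]) for i in ids}
    out = []
    for k in range(len(rows)):
        total = 0.0
        for i in ids:
            mean, sd = stats[i]
            total += (weighted[i][k] - mean) / sd
        out.append(total / len(ids))
    return out


def auc_pairwise(scores, labels):
    """Exhaustive case-control pairwise AUC: P(case > control) + 0.5 P(tie)."""
    cases = [s for s, y in zip(scores, labels) if y]
    controls = [s for s, y in zip(scores, labels) if not y]
    wins = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                wins += 1.0
            elif c == d:
                wins += 0.5
    return wins / (len(cases) * len(controls))


def youden_scan(scores, labels):
    """Exhaustive threshold scan (midpoints between distinct scores,
    predict positive at score >= cutoff); smallest maximizing cutoff."""
    distinct = sorted(set(scores))
    cuts = [(a + b) / 2.0 for a, b in zip(distinct[:-1], distinct[1:])]
    if not cuts:
        cuts = [distinct[0]]
    n1 = sum(1 for y in labels if y)
    n0 = len(labels) - n1
    best = None
    for cut in cuts:
        tp = sum(1 for s, y in zip(scores, labels) if y and s >= cut)
        tn = sum(1 for s, y in zip(scores, labels) if not y and s < cut)
        j = tp / n1 + tn / n0 - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, cut)
    return best  # (j, cutoff)


def welch_t(a, b):
    """Hand-computed Welch statistic."""
    ma, sa = two_pass_mean_sd(a)
    mb, sb = two_pass_mean_sd(b)
    se = math.sqrt(sa**2 / len(a) + sb**2 / len(b))
    return (ma - mb) / se
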