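"""Independent brute-force oracles used by the test suite.

Everything here is written straight from the defining formulas with plain
loops and library statistics routines, deliberately sharing no code path
with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def pearson_loop(x, y) -> float:
    """Textbook Pearson formula with explicit sums."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    if vx == 0 or vy == 0:
        return float("nan")
    return cov / math.sqrt(vx * vy)


def average_weight(collection, focal: str, gene: str, tissue: str | None = None):
    """Mean per-dataset correlation: the dataset-averaged weight, by loops."""
    weights = []
    for d in collection:
        if tissue is not None and d.tissue != tissue:
            continue
        if focal not in d.genes or gene not in d.genes:
            continue
        r = pearson_loop(d.values.loc[focal], d.values.loc[gene])
        if not math.isnan(r):
            weights.append(r)
    if not weights:
        return float("nan"), 0
    return sum(weights) / len(weights), len(weights)


def pathway_score_loop(collection, de_results, focal: str, members, tissue: str):
    """Pathway score straight from the formula: mean over members of the
    tissue-specific gene weight, restricted to datasets where focal is DE."""
    restricted = [
        d for d in collection
        if d.tissue == tissue and de_results[d.dataset_id].is_de(focal)
    ]
    member_means = []
    for k in sorted(set(members)):
        weights = []
        for d in restricted:
            if focal not in d.genes or k not in d.genes:
                continue
            r = pearson_loop(d.values.loc[focal], d.values.loc[k])
            if not math.isnan(r):
                weights.append(r)
        if weights:
            member_means.append(sum(weights) / len(weights))
    if not member_means:
        return float("nan")
    return sum(member_means) / len(member_means)


def bh_qvalues_loop(pvalues):
    """BH step-up from the definition: q_i = min_{p_(j) >= p_i} m p_(j) / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * pvalues[i] / rank)
        q[i] = running_min
    return q


def hypergeom_upper_tail(a: int, N: int, m: int, q: int) -> float:
    """P(X >= a) by exact combinatorics with big integers."""
    total = math.comb(N, q)
    acc = 0
    for k in range(a, min(m, q) + 1):
        acc += math.comb(m, k) * math.comb(N - m, q - k)
    return acc / total


def anova_by_hand(groups):
    """One-way ANOVA from the sum-of-squares decomposition."""
    groups = [list(map(float, g)) for g in groups]
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(f, dfb, dfw)
    return f, p
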