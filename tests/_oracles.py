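"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately naive — exhaustive enumeration and
direct-formula implementations that share no code with the package — so
that agreement is evidence, not tautology.
"""

from __future__ import annotations

import math
from itertools import combinations


# --- rank-sum test ---------------------------------------------------------


def _u_statistic(case, control) -> float:
    """Mann-Whitney U by direct pairwise comparison (ties count 1/2)."""
    u = 0.0
    for c in case:
        for k in control:
            if c > k:
                u += 1.0
            elif c == k:
                u += 0.5
    return u


def exact_mw_pvalue(case, control) -> float:
    """Two-sided exact p: fraction of labelings with |U - n1*n2/2| >= observed."""
    pooled = list(case) + list(control)
    n1 = len(case)
    mu = n1 * len(control) / 2.0
    dev_obs = abs(_u_statistic(case, control) - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(_u_statistic(grp, rest) - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


# --- hypergeometric --------------------------------------------------------


def exact_hypergeom_upper(t: int, k: int, m: int, n: int) -> float:
    """P(X >= t) by enumerating every k-subset of an n-item population
    whose first m items are the successes."""
    hits = total = 0
    for draw in combinations(range(n), k):
        total += 1
        if sum(1 for i in draw if i < m) >= t:
            hits += 1
    return hits / total


# --- ontology measures -----------------------------------------------------


def ancestors(parents: dict[str, list[tuple[str, str]]], term: str) -> set[str]:
    """Ancestor closure (with self) by naive recursion."""
    out = {term}
    for p, _ in parents[term]:
        out |= ancestors(parents, p)
    return out


def ic_table(
    parents: dict[str, list[tuple[str, str]]], annotations: dict[str, set[str]]
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-term (ic, p) by checking, gene by gene, who reaches each term."""
    closures = {g: set().union(*(ancestors(parents, t) for t in ts)) for g, ts in annotations.items()}
    roots = [t for t, ps in parents.items() if not ps]
    counts = {
        t: sum(1 for cl in closures.values() if t in cl) for t in parents
    }
    ic, p = {}, {}
    for t, c in counts.items():
        if c == 0:
            continue
        root = max(
            (r for r in roots if r in ancestors(parents, t)), key=lambda r: counts[r]
        )
        p[t] = c / counts[root]
        ic[t] = -math.log(p[t])
    return ic, p


def wang_svalue_paths(
    parents: dict[str, list[tuple[str, str]]], term: str, target: str, weights
) -> float:
    """Max product of edge weights over all upward paths term -> target."""
    if term == target:
        return 1.0
    best = 0.0
    for p, rel in parents[term]:
        sub = wang_svalue_paths(parents, p, target, weights)
        if sub > 0:
            best = max(best, weights[rel] * sub)
    return best


def term_similarity(parents, annotations, t1, t2, measure, weights=None) -> float:
    """Direct-formula similarity; shares nothing with the package path."""
    weights = weights or {"is_a": 0.8, "part_of": 0.6}
    if measure == "wang":
        anc1, anc2 = ancestors(parents, t1), ancestors(parents, t2)
        s1 = {a: wang_svalue_paths(parents, t1, a, weights) for a in anc1}
        s2 = {a: wang_svalue_paths(parents, t2, a, weights) for a in anc2}
        common = anc1 & anc2
        if not common:
            return 0.0
        return sum(s1[a] + s2[a] for a in common) / (sum(s1.values()) + sum(s2.values()))
    ic, p = ic_table(parents, annotations)
    common = [t for t in ancestors(parents, t1) & ancestors(parents, t2) if t in ic]
    if not common:
        return 0.0
    anc = sorted(common, key=lambda t: (-ic[t], t))[0]
    if measure == "resnik":
        return ic[anc]
    ic1, ic2 = ic[t1], ic[t2]
    if measure == "jiang":
        return 1.0 - min(1.0, ic1 + ic2 - 2 * ic[anc])
    if ic1 + ic2 == 0:
        return 0.0
    lin = 2 * ic[anc] / (ic1 + ic2)
    return lin if measure == "lin" else lin * (1 - p[anc])


def bma(matrix) -> float:
    """Best-match average of a similarity matrix, written longhand."""
    row_best = [max(row) for row in matrix]
    col_best = [max(matrix[i][j] for i in range(len(matrix))) for j in range(len(matrix[0]))]
    return 0.5 * (sum(row_best) / len(row_best) + sum(col_best) / len(col_best))


def geneset_similarity(parents, annotations, set_a, set_b, measure) -> float:
    """Naive gene-set BMA: gene-gene BMA over term sets, then set-set BMA."""

    def gene_sim(g1, g2):
        ts1, ts2 = sorted(annotations[g1]), sorted(annotations[g2])
        mat = [[term_similarity(parents, annotations, a, b, measure) for b in ts2] for a in ts1]
        return bma(mat)

    a = [g for g in set_a if g in annotations]
    b = [g for g in set_b if g in annotations]
    return bma([[gene_sim(g, h) for h in b] for g in a])
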