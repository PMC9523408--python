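"""Monte-Carlo permutation engine for gene-set statistics.

The empirical p-value is p = (m+1)/(n+1), where n is the number of
Monte-Carlo replicates and m the number of replicates whose statistic is
at least as extreme as the observed one (ties count as extreme); the +1s
include the observed statistic in the reference distribution, so p is
never 0 and is bounded below by 1/(n+1).

Null replicates draw two disjoint gene sets of the observed sizes
uniformly without replacement from a background pool, mirroring disease
DEG sets that share no genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

TAILS = ("upper", "lower")


@dataclass
class BackgroundPool:
    """Ordered, duplicate-free list of genes eligible for resampling."""

    genes: tuple[str, ...]

    def __init__(self, genes: Iterable[str]):
        genes = tuple(genes)
        if len(set(genes)) != len(genes):
            raise ValueError("background pool contains duplicate genes")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def require_superset(self, *gene_sets: Iterable[str]) -> None:
        pool = set(self.genes)
        for s in gene_sets:
            missing = set(s) - pool
            if missing:
                raise ValueError(f"pool is missing observed genes: {sorted(missing)[:5]}")


@dataclass
class PermutationResult:
    """Observed statistic, its Monte-Carlo null sample and empirical p-value."""

    observed: float
    null_values: np.ndarray
    n: int
    m: int
    pvalue: float
    tail: str
    seed: int | None = None

    def summary(self) -> dict:
        return {
            "observed": self.observed,
            "n": self.n,
            "m": self.m,
            "pvalue": self.pvalue,
            "tail": self.tail,
            "null_mean": float(np.mean(self.null_values)),
            "null_sd": float(np.std(self.null_values)),
            "seed": self.seed,
        }


def mc_pvalue(observed: float, null_values: Sequence[float], tail: str = "upper") -> float:
    """Empirical p-value (m+1)/(n+1) of an observed statistic against a null sample.

    Upper tail counts null values >= observed; lower tail counts <= observed.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empty null sample")
    if not (np.isfinite(null).all() and np.isfinite(observed)):
        raise ValueError("non-finite values")
    m = int((null >= observed).sum() if tail == "upper" else (null <= observed).sum())
    return (m + 1) / (null.size + 1)


def _replicate_rng(seed: int, index: int) -> np.random.Generator:
    # one independent, counter-style stream per replicate: extending n leaves
    # the first n replicates bit-identical
    return np.random.default_rng([seed, index])


def draw_disjoint_sets(
    pool: Sequence[str], size_a: int, size_b: int, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Draw two disjoint sets uniformly without replacement from the pool."""
    idx = rng.choice(len(pool), size=size_a + size_b, replace=False)
    return [pool[i] for i in idx[:size_a]], [pool[i] for i in idx[size_a:]]


def permute_statistic(
    statistic: Callable[[Sequence[str], Sequence[str]], float],
    set_a: Iterable[str],
    set_b: Iterable[str],
    pool: BackgroundPool,
    n: int,
    seed: int,
    tail: str = "upper",
    observed: float | None = None,
) -> PermutationResult:
    """Monte-Carlo permutation test of a two-gene-set statistic.

    Each of the ``n`` replicates redraws two disjoint sets of the observed
    sizes from ``pool`` and re-evaluates ``statistic``; the p-value follows
    the (m+1)/(n+1) rule against ``observed`` (computed from the real sets
    unless supplied).  Fully reproducible from ``seed``; a replicate whose
    statistic raises is dropped (more than 1% dropped is a hard error).
    """
    set_a = list(set_a)
    set_b = list(set_b)
    if n < 1:
        raise ValueError("need at least one Monte-Carlo replicate")
    if len(set_a) + len(set_b) > len(pool):
        raise ValueError("pool smaller than the union of the two set sizes")
    if observed is None:
        observed = float(statistic(set_a, set_b))
    null = np.empty(n)
    dropped = 0
    kept = 0
    for i in range(n):
        rand_a, rand_b = draw_disjoint_sets(pool.genes, len(set_a), len(set_b), _replicate_rng(seed, i))
        try:
            null[kept] = float(statistic(rand_a, rand_b))
            kept += 1
        except Exception as exc:  # noqa: BLE001 - statistic is user code
            dropped += 1
            logger.warning("permute_statistic: replicate %d failed: %s", i, exc)
    if dropped > 0.01 * n:
        raise RuntimeError(f"{dropped}/{n} Monte-Carlo replicates failed")
    null = null[:kept]
    pvalue = mc_pvalue(observed, null, tail)
    m = int((null >= observed).sum() if tail == "upper" else (null <= observed).sum())
    return PermutationResult(
        observed=observed, null_values=null, n=kept, m=m, pvalue=pvalue, tail=tail, seed=seed
    )
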