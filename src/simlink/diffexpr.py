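"""Differential expression: fold change + Mann-Whitney rank-sum test.

A gene is called differentially expressed (DEG) when it passes both gates:
|log2 fold change| > log2(fc_threshold) and two-sided rank-sum p < p_threshold
(raw p-values; no multiplicity correction at this stage).  A disease's DEG
set is the intersection of the per-dataset DEG sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: largest per-group size for which the exact enumeration path is used
EXACT_MAX_GROUP = 8

DegTable = pd.DataFrame  # columns: gene (index), log2fc, pvalue, is_deg


@dataclass
class DiseaseDegSet:
    """DEGs shared by all of one disease's datasets."""

    disease: str
    genes: frozenset[str]
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.genes)


def _exact_mw_p(case: np.ndarray, control: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration of all labelings.

    Midranks handle ties; two-sidedness is |U - n1*n2/2| >= observed, which
    coincides with the usual doubling rule when the null is symmetric
    (always true without ties).
    """
    n1, n2 = len(case), len(control)
    pooled = np.concatenate([case, control])
    ranks = stats.rankdata(pooled)
    mu = n1 * n2 / 2.0
    w_obs = ranks[:n1].sum()
    u_obs = w_obs - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    total = 0
    hits = 0
    for idx in combinations(range(n1 + n2), n1):
        w = ranks[list(idx)].sum()
        u = w - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def mann_whitney_p(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Exact enumeration (with midrank ties) when both groups have <= 8
    values; otherwise the normal approximation with tie and continuity
    correction.  Returns 1.0 in the degenerate all-identical case.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError(
            f"each group needs >= 2 values, got {case.size} and {control.size}"
        )
    if not (np.isfinite(case).all() and np.isfinite(control).all()):
        raise ValueError("non-finite values in input")
    pooled = np.concatenate([case, control])
    if np.ptp(pooled) == 0:
        logger.debug("mann_whitney_p: all values identical, p = 1")
        return 1.0
    if case.size <= EXACT_MAX_GROUP and control.size <= EXACT_MAX_GROUP:
        return _exact_mw_p(case, control)
    res = stats.mannwhitneyu(
        case, control, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def _mann_whitney_p_rows(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Row-wise rank-sum p over a matrix split into case/control columns.

    Vectorised asymptotic path for the common many-genes case; rows where
    every value is identical get p = 1.
    """
    n1, n2 = case.shape[1], control.shape[1]
    if n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        return np.array(
            [mann_whitney_p(case[i], control[i]) for i in range(case.shape[0])]
        )
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(
            case, control, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=1,
        )
        p = np.asarray(res.pvalue, dtype=float)
    flat = np.ptp(np.hstack([case, control]), axis=1) == 0
    p[flat] = 1.0
    if np.isnan(p).any():
        raise AssertionError("unexpected NaN p-value from rank-sum test")
    return p


def call_degs(
    dataset,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> DegTable:
    """Score every gene of a log2-scale dataset and flag DEGs.

    log2fc = mean(case) - mean(control); the fold-change gate is
    |log2fc| > log2(fc_threshold).  Returns a DataFrame indexed by gene
    with columns ``log2fc``, ``pvalue``, ``is_deg``.
    """
    if fc_threshold < 1 or not (0 < p_threshold <= 1):
        raise ValueError("need fc_threshold >= 1 and 0 < p_threshold <= 1")
    case = dataset.matrix[dataset.case_samples].to_numpy(dtype=float)
    control = dataset.matrix[dataset.control_samples].to_numpy(dtype=float)
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    pvalues = _mann_whitney_p_rows(case, control)
    gate = math.log2(fc_threshold)
    is_deg = (np.abs(log2fc) > gate) & (pvalues < p_threshold)
    table = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalues, "is_deg": is_deg},
        index=pd.Index(dataset.genes, name="gene"),
    )
    logger.info(
        "call_degs[%s]: %d / %d genes pass |log2FC| > %.3f and p < %g",
        dataset.dataset_id, int(is_deg.sum()), len(table), gate, p_threshold,
    )
    return table


def deg_genes(table: DegTable) -> frozenset[str]:
    """The DEG gene set of a scored table."""
    return frozenset(table.index[table["is_deg"]])


def intersect_deg_sets(
    deg_sets: Sequence[Iterable[str]], disease: str, provenance: Sequence[str] = ()
) -> DiseaseDegSet:
    """Intersect per-dataset DEG sets into one disease DEG set."""
    if len(deg_sets) < 2:
        raise ValueError("need at least two DEG sets to intersect")
    sets = [frozenset(s) for s in deg_sets]
    common = frozenset.intersection(*sets)
    logger.info(
        "intersect_deg_sets[%s]: sizes %s -> intersection %d",
        disease, [len(s) for s in sets], len(common),
    )
    if not common:
        logger.warning("intersect_deg_sets[%s]: empty intersection", disease)
    return DiseaseDegSet(disease=disease, genes=common, provenance=tuple(provenance))
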