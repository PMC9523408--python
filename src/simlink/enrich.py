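"""Hypergeometric term enrichment with Benjamini-Hochberg correction.

For a query gene set of size k drawn from a background of n genes, of
which m are annotated to a term, the enrichment p-value is the upper-tail
hypergeometric probability P(X >= t) of observing at least the t overlap
genes.  Annotations are propagated up the ontology before testing (a gene
annotated to a term is annotated to all its ancestors), the standard GO
enrichment semantics.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def hypergeom_upper(t_overlap: int, k_interest: int, m_termsize: int, n_background: int) -> float:
    """P(X >= t_overlap) with X ~ Hypergeom(n_background, m_termsize, k_interest).

    Computed via the survival function (log-space internally in scipy), so
    it is stable for large backgrounds.
    """
    if not (0 <= m_termsize <= n_background and 0 <= k_interest <= n_background):
        raise ValueError("term size and query size must lie within the background")
    if not (0 <= t_overlap <= min(k_interest, m_termsize)):
        raise ValueError(
            f"overlap {t_overlap} inconsistent with k={k_interest}, m={m_termsize}"
        )
    if t_overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(t_overlap - 1, n_background, m_termsize, k_interest))


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def propagate_annotations(
    annotations: Mapping[str, Iterable[str]], dag
) -> dict[str, frozenset[str]]:
    """Extend each gene's annotations to the full ancestor closure."""
    out: dict[str, frozenset[str]] = {}
    for gene, terms in annotations.items():
        closure: set[str] = set()
        for t in terms:
            closure |= dag.ancestors(t)
        out[gene] = frozenset(closure)
    return out


def enrich_terms(
    query: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    background: Iterable[str],
    dag=None,
    min_term_size: int = 3,
    fdr_cut: float = 0.05,
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Term-by-term hypergeometric enrichment of a query gene set.

    ``annotations`` maps gene -> terms; when ``dag`` is given they are
    first propagated to ancestors.  Query genes outside the background are
    dropped (logged).  Returns one row per term with at least
    ``min_term_size`` annotated background genes, sorted by p-value, with
    BH-adjusted ``fdr`` and a ``significant`` flag at ``fdr_cut``.
    """
    background = set(background)
    query = set(query)
    outside = query - background
    if outside:
        logger.warning("enrich_terms: %d query genes outside background dropped", len(outside))
        query -= outside
    if not query:
        raise ValueError("query is empty after restriction to the background")
    if dag is not None:
        annotations = propagate_annotations(
            {g: ts for g, ts in annotations.items() if g in background}, dag
        )
    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        if gene not in background:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    n = len(background)
    k = len(query)
    rows = []
    for term in sorted(term_genes):
        members = term_genes[term]
        m = len(members)
        if m < min_term_size:
            continue
        t = len(members & query)
        rows.append(
            {
                "term": term,
                "name": (term_names or {}).get(term, term),
                "t_overlap": t,
                "k_interest": k,
                "m_termsize": m,
                "n_background": n,
                "pvalue": hypergeom_upper(t, k, m, n),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "name", "t_overlap", "k_interest", "m_termsize",
                     "n_background", "pvalue", "fdr", "significant"]
        )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["pvalue"])
    table["significant"] = table["fdr"] < fdr_cut
    table = table.sort_values(["pvalue", "term"], kind="mergesort").reset_index(drop=True)
    return table
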