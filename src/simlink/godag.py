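"""Ontology DAG, information content, and semantic-similarity measures.

Implements the five term-level measures used to compare disease gene sets
functionally — Wang (graph-based S-values), Resnik, Lin, Jiang and Rel
(IC-based through the most informative common ancestor) — and their
aggregation to gene and gene-set level by the best-match average (BMA).

Information content is ic(t) = -ln p(t), with p(t) the fraction of
annotated genes reaching t (a gene annotated to a term is implicitly
annotated to all its ancestors).  Natural log follows the usual GO
semantic-similarity convention; lin/jiang/rel/wang are scale-free in any
case, resnik is reported unnormalised by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEASURES = ("wang", "resnik", "lin", "jiang", "rel")
COMBINES = ("bma", "max", "avg")

#: contribution weights per edge type in the Wang measure (published defaults)
WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}

RELATIONS = ("is_a", "part_of")


class NoCommonAncestorError(ValueError):
    """Two terms share no (IC-defined) common ancestor, e.g. different roots."""


@dataclass
class TermIC:
    """Per-term information content and annotation probability."""

    ic: dict[str, float]
    p: dict[str, float]


class OntologyDag:
    """Rooted DAG of terms with typed child->parent edges and gene annotations.

    Parameters
    ----------
    edges
        (child, parent, relation) triples; relation in {"is_a", "part_of"}.
    annotations
        gene -> set of directly annotated term ids.
    terms
        Optional explicit term universe (defaults to terms seen in edges).
    names
        Optional term id -> human-readable name.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, str]],
        annotations: Mapping[str, Iterable[str]] | None = None,
        terms: Iterable[str] | None = None,
        names: Mapping[str, str] | None = None,
    ) -> None:
        self.parents: dict[str, tuple[tuple[str, str], ...]] = {}
        edge_list = list(edges)
        for child, parent, rel in edge_list:
            if rel not in RELATIONS:
                raise ValueError(f"unsupported relation {rel!r}")
            self.parents.setdefault(child, ())
            self.parents.setdefault(parent, ())
            self.parents[child] = self.parents[child] + ((parent, rel),)
        if terms is not None:
            for t in terms:
                self.parents.setdefault(t, ())
        self.names = dict(names or {})
        graph = nx.DiGraph((c, p) for c, p, _ in edge_list)
        if edge_list and not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology contains a cycle")
        self.annotations: dict[str, frozenset[str]] = {}
        for gene, ts in (annotations or {}).items():
            ts = frozenset(ts)
            unknown = ts - self.parents.keys()
            if unknown:
                raise ValueError(f"gene {gene!r} annotated to unknown terms {sorted(unknown)}")
            if ts:
                self.annotations[gene] = ts
        self._anc_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t, ps in self.parents.items() if not ps)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including the term itself."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        out = {term}
        stack = [term]
        while stack:
            for parent, _ in self.parents[stack.pop()]:
                if parent not in out:
                    out.add(parent)
                    stack.append(parent)
        result = frozenset(out)
        self._anc_cache[term] = result
        return result

    def annotated_genes(self, genes: Iterable[str]) -> list[str]:
        """Subset of ``genes`` (order kept, duplicates removed) with annotations."""
        seen: dict[str, None] = {}
        for g in genes:
            if g in self.annotations:
                seen.setdefault(g)
        return list(seen)


# ---------------------------------------------------------------------------
# I/O


def read_obo(
    path: str | Path, namespace: str | None = "biological_process"
) -> OntologyDag:
    """Parse an OBO 1.2 file; keep is_a/part_of edges, optionally one namespace."""
    import obonet

    graph = obonet.read_obo(str(path))
    if namespace is not None:
        keep = {n for n, d in graph.nodes(data=True) if d.get("namespace", namespace) == namespace}
    else:
        keep = set(graph.nodes)
    edges = []
    ignored = 0
    for child, parent, key in graph.edges(keys=True):
        if child not in keep or parent not in keep:
            continue
        if key in RELATIONS:
            edges.append((child, parent, key))
        else:
            ignored += 1
    if ignored:
        logger.info("read_obo: ignored %d edges of unsupported relation types", ignored)
    names = {n: d.get("name", n) for n, d in graph.nodes(data=True) if n in keep}
    return OntologyDag(edges, terms=keep, names=names)


def write_obo(dag: OntologyDag, path: str | Path) -> None:
    """Write a minimal OBO 1.2 file (id, name, is_a, relationship part_of)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.parents):
            fh.write(f"\n[Term]\nid: {term}\nname: {dag.names.get(term, term)}\n")
            for parent, rel in dag.parents[term]:
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (gene, term) TSV into a gene -> terms map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def read_gaf(path: str | Path) -> dict[str, set[str]]:
    """Read gene -> GO term annotations from GAF 2.x (symbol col 2, term col 5).

    Rows whose qualifier contains ``NOT`` are dropped.
    """
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                continue
            if "NOT" in cols[3].split("|"):
                continue
            out.setdefault(cols[1], set()).add(cols[4])
    return out


def write_annotations(annotations: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# information content


def compute_ic(dag: OntologyDag) -> TermIC:
    """Propagate annotations to ancestors and derive per-term IC.

    Each gene counts once per term even when it reaches the term through
    several paths or several directly annotated descendants.  p(t) is
    relative to the root of t's namespace (the root it reaches); terms no
    gene reaches have undefined IC and are excluded (logged).
    """
    if not dag.annotations:
        raise ValueError("compute_ic needs at least one annotated gene")
    counts: dict[str, int] = {}
    for gene, terms in dag.annotations.items():
        reached: set[str] = set()
        for t in terms:
            reached |= dag.ancestors(t)
        for t in reached:
            counts[t] = counts.get(t, 0) + 1
    ic: dict[str, float] = {}
    p: dict[str, float] = {}
    for term, count in counts.items():
        root_counts = [counts[r] for r in dag.ancestors(term) if r in dag.roots]
        total = max(root_counts)
        p[term] = count / total
        ic[term] = float(-np.log(count / total))
    n_undefined = len(dag.terms) - len(ic)
    if n_undefined:
        logger.info("compute_ic: %d terms with no annotated gene excluded", n_undefined)
    return TermIC(ic=ic, p=p)


def mica(t1: str, t2: str, dag: OntologyDag, ic: TermIC) -> str:
    """Most informative common ancestor (ancestor sets include the terms).

    Ties broken by lexicographically smallest term id.  Raises
    :class:`NoCommonAncestorError` when the terms live under different
    roots or share no IC-defined ancestor.
    """
    common = dag.ancestors(t1) & dag.ancestors(t2)
    candidates = [t for t in common if t in ic.ic]
    if not candidates:
        raise NoCommonAncestorError(f"{t1} and {t2} share no common ancestor with defined IC")
    return min(candidates, key=lambda t: (-ic.ic[t], t))


# ---------------------------------------------------------------------------
# term-level similarity


def _wang_svalues(
    dag: OntologyDag, term: str, weights: Mapping[str, float]
) -> dict[str, float]:
    """S-values of ``term``'s ancestor closure: S(term)=1, S(a)=max over
    paths of the product of edge weights from term up to a."""
    svalues = {term: 1.0}
    # max-relaxation; weights < 1 so values only propagate upward and settle
    frontier = [term]
    while frontier:
        nxt = []
        for t in frontier:
            for parent, rel in dag.parents[t]:
                cand = svalues[t] * weights[rel]
                if cand > svalues.get(parent, 0.0):
                    svalues[parent] = cand
                    nxt.append(parent)
        frontier = nxt
    return svalues


def term_sim(
    t1: str,
    t2: str,
    measure: str,
    dag: OntologyDag,
    ic: TermIC | None = None,
    wang_weights: Mapping[str, float] = WANG_WEIGHTS,
) -> float:
    """Similarity of two terms under one of the five measures.

    Pairs without a common ancestor (different namespaces) score 0.
    ``ic`` is required for every measure except ``wang``.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    if measure == "wang":
        s1 = _wang_svalues(dag, t1, wang_weights)
        s2 = _wang_svalues(dag, t2, wang_weights)
        common = s1.keys() & s2.keys()
        if not common:
            return 0.0
        return sum(s1[t] + s2[t] for t in common) / (sum(s1.values()) + sum(s2.values()))
    if ic is None:
        raise ValueError(f"measure {measure!r} requires information content")
    try:
        anc = mica(t1, t2, dag, ic)
    except NoCommonAncestorError:
        return 0.0
    ic_m = ic.ic[anc]
    if measure == "resnik":
        return ic_m
    if t1 not in ic.ic or t2 not in ic.ic:
        logger.warning("term with undefined IC in %s similarity: %s / %s", measure, t1, t2)
        return 0.0
    ic1, ic2 = ic.ic[t1], ic.ic[t2]
    if measure == "jiang":
        return 1.0 - min(1.0, ic1 + ic2 - 2.0 * ic_m)
    if ic1 + ic2 == 0:
        return 0.0  # both terms are roots
    lin = 2.0 * ic_m / (ic1 + ic2)
    if measure == "lin":
        return lin
    return lin * (1.0 - ic.p[anc])  # rel


# ---------------------------------------------------------------------------
# gene-set similarity


def _term_matrix(
    terms: Sequence[str],
    measure: str,
    dag: OntologyDag,
    ic: TermIC | None,
    wang_weights: Mapping[str, float],
) -> np.ndarray:
    n = len(terms)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = term_sim(terms[i], terms[j], measure, dag, ic, wang_weights)
            mat[i, j] = mat[j, i] = s
    return mat


def _pad_terms(
    gene_terms: Sequence[Sequence[int]], pad: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pad ragged per-gene term-index lists; returns (index array, valid mask)."""
    k = max(len(t) for t in gene_terms)
    idx = np.full((len(gene_terms), k), pad, dtype=int)
    mask = np.zeros((len(gene_terms), k), dtype=bool)
    for i, ts in enumerate(gene_terms):
        idx[i, : len(ts)] = ts
        mask[i, : len(ts)] = True
    return idx, mask


def pairwise_gene_similarity(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    measure: str,
    dag: OntologyDag,
    ic: TermIC | None = None,
    wang_weights: Mapping[str, float] = WANG_WEIGHTS,
    block: int = 256,
) -> pd.DataFrame:
    """Gene-by-gene similarity matrix; each entry is the BMA over the two
    genes' direct term sets.  All genes must be annotated."""
    for g in list(genes_a) + list(genes_b):
        if g not in dag.annotations:
            raise ValueError(f"gene {g!r} has no annotations")
    terms = sorted({t for g in list(genes_a) + list(genes_b) for t in dag.annotations[g]})
    tindex = {t: i for i, t in enumerate(terms)}
    tmat = _term_matrix(terms, measure, dag, ic, wang_weights)
    # dummy padding term with -inf similarity so padded slots never win a max
    ext = np.full((len(terms) + 1, len(terms) + 1), -np.inf)
    ext[: len(terms), : len(terms)] = tmat
    ia, ma = _pad_terms([sorted(tindex[t] for t in dag.annotations[g]) for g in genes_a], len(terms))
    ib, mb = _pad_terms([sorted(tindex[t] for t in dag.annotations[g]) for g in genes_b], len(terms))
    na, nb = len(genes_a), len(genes_b)
    out = np.empty((na, nb))
    ca = ma.sum(axis=1)
    cb = mb.sum(axis=1)
    for start in range(0, na, block):
        stop = min(start + block, na)
        # (chunk, nb, ka, kb) block of term-level similarities
        g = ext[ia[start:stop, None, :, None], ib[None, :, None, :]]
        rowmax = g.max(axis=3)  # best match in B for each of A's terms
        colmax = g.max(axis=2)  # best match in A for each of B's terms
        rowmean = np.where(ma[start:stop, None, :], rowmax, 0.0).sum(axis=2) / ca[start:stop, None]
        colmean = np.where(mb[None, :, :], colmax, 0.0).sum(axis=2) / cb[None, :]
        out[start:stop] = 0.5 * (rowmean + colmean)
    return pd.DataFrame(out, index=list(genes_a), columns=list(genes_b))


def _combine_matrix(mat: np.ndarray, combine: str) -> float:
    if combine == "bma":
        return float(0.5 * (mat.max(axis=1).mean() + mat.max(axis=0).mean()))
    if combine == "max":
        return float(mat.max())
    if combine == "avg":
        return float(mat.mean())
    raise ValueError(f"combine must be one of {COMBINES}")


def geneset_sim(
    set_a: Iterable[str],
    set_b: Iterable[str],
    measure: str,
    dag: OntologyDag,
    ic: TermIC | None = None,
    combine: str = "bma",
    wang_weights: Mapping[str, float] = WANG_WEIGHTS,
) -> float:
    """Functional similarity of two gene sets.

    Unannotated genes are dropped (logged); order and duplicates within a
    set are irrelevant.  Raises if either set has no annotated gene.
    """
    a = dag.annotated_genes(sorted(set(set_a)))
    b = dag.annotated_genes(sorted(set(set_b)))
    for name, original, kept in (("A", set(set_a), a), ("B", set(set_b), b)):
        dropped = len(original) - len(kept)
        if dropped:
            logger.info("geneset_sim: dropped %d unannotated genes from set %s", dropped, name)
        if not kept:
            raise ValueError(f"gene set {name} has no annotated genes")
    mat = pairwise_gene_similarity(a, b, measure, dag, ic, wang_weights)
    return _combine_matrix(mat.to_numpy(), combine)


class GeneSetSimilarityCache:
    """Precomputed gene-by-gene similarity over a gene pool.

    Makes Monte-Carlo nulls over resampled gene sets cheap: the full
    pairwise matrix is computed once and set-level scores are BMA reads of
    submatrices.
    """

    def __init__(
        self,
        pool: Sequence[str],
        measure: str,
        dag: OntologyDag,
        ic: TermIC | None = None,
        wang_weights: Mapping[str, float] = WANG_WEIGHTS,
    ) -> None:
        self.genes = dag.annotated_genes(pool)
        if not self.genes:
            raise ValueError("no annotated genes in pool")
        self.index = {g: i for i, g in enumerate(self.genes)}
        self.measure = measure
        self.matrix = pairwise_gene_similarity(
            self.genes, self.genes, measure, dag, ic, wang_weights
        ).to_numpy()

    def set_sim(self, set_a: Iterable[str], set_b: Iterable[str], combine: str = "bma") -> float:
        ia = [self.index[g] for g in set_a if g in self.index]
        ib = [self.index[g] for g in set_b if g in self.index]
        if not ia or not ib:
            raise ValueError("a gene set has no annotated genes in the cache pool")
        return _combine_matrix(self.matrix[np.ix_(ia, ib)], combine)
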