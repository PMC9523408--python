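"""Protein-interaction network over two disease gene sets.

Edges come from a scored interaction table (STRING-style: protein1,
protein2, combined_score); only scores strictly greater than the
confidence threshold (default 0.4) are kept.  The statistic of interest
is the cross-set connectivity — the number of retained edges with one
endpoint in each disease's gene set — tested against a Monte-Carlo null
that redraws both sets from the background pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from simlink.permtest import BackgroundPool, PermutationResult, permute_statistic

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.4


def read_interactions(path: str | Path) -> pd.DataFrame:
    """Read a 3-column (protein1, protein2, combined_score) table.

    Whitespace- or tab-delimited; header row optional.  STRING's integer
    0-1000 combined scores are auto-detected (max > 1) and rescaled to 0-1.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"interaction table {path} needs 3 columns")
    df = df.iloc[:, :3]
    df.columns = ["gene_a", "gene_b", "score"]
    first_score = pd.to_numeric(df["score"].iloc[0], errors="coerce")
    if np.isnan(first_score):  # header row
        df = df.iloc[1:].reset_index(drop=True)
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    if df["score"].max() > 1:
        logger.info("read_interactions: rescaling 0-1000 combined scores to 0-1")
        df["score"] = df["score"] / 1000.0
    return df


@dataclass
class InteractionNetwork:
    """Undirected weighted graph over the union of two disease gene sets."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def disease_of(self, gene: str) -> str:
        return self.graph.nodes[gene]["disease"]

    def cross_edges(self) -> int:
        """Edges with one endpoint in each disease-exclusive set."""
        tags = nx.get_node_attributes(self.graph, "disease")
        return sum(
            1
            for u, v in self.graph.edges
            if {tags[u], tags[v]} == {"A", "B"}
        )


def build_network(
    interactions: pd.DataFrame,
    nodes_a: Iterable[str],
    nodes_b: Iterable[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> InteractionNetwork:
    """Induced interaction network over the two gene sets.

    Keeps edges with both endpoints in the union and score strictly above
    ``threshold``; self-loops dropped, duplicate pairs collapsed (max
    score), malformed scores outside [0,1] rejected with a logged count.
    Genes of both sets are tagged "shared".  Every input gene appears as a
    node, isolated ones with degree 0.
    """
    set_a, set_b = set(nodes_a), set(nodes_b)
    shared = set_a & set_b
    if shared:
        logger.warning("build_network: %d genes in both disease sets tagged 'shared'", len(shared))
    graph = nx.Graph()
    for gene in sorted(set_a | set_b):
        tag = "shared" if gene in shared else ("A" if gene in set_a else "B")
        graph.add_node(gene, disease=tag)
    scores = interactions["score"].to_numpy(dtype=float)
    bad = (scores < 0) | (scores > 1) | ~np.isfinite(scores)
    if bad.any():
        logger.warning("build_network: rejected %d rows with scores outside [0,1]", int(bad.sum()))
    keep = ~bad & (scores > threshold)
    members = set_a | set_b
    n_loops = 0
    for ga, gb, score in interactions.loc[keep, ["gene_a", "gene_b", "score"]].itertuples(index=False):
        if ga == gb:
            n_loops += 1
            continue
        if ga not in members or gb not in members:
            continue
        u, v = (ga, gb) if ga <= gb else (gb, ga)
        if graph.has_edge(u, v):
            graph[u][v]["score"] = max(graph[u][v]["score"], float(score))
        else:
            graph.add_edge(u, v, score=float(score))
    if n_loops:
        logger.info("build_network: dropped %d self-loops", n_loops)
    return InteractionNetwork(graph=graph, threshold=threshold)


@dataclass
class HubReport:
    """Degrees, per-disease hub lists and the cross-set edge count."""

    degrees: pd.Series
    hubs_a: list[str]
    hubs_b: list[str]
    cross_edges: int
    n_nodes_total: int
    n_nodes_connected: int


def degree_and_hubs(net: InteractionNetwork, top_k: int = 10) -> HubReport:
    """Rank genes by degree per disease; ties broken by gene symbol.

    Both the total node count (all input genes) and the non-isolated node
    count are reported, since published networks often count only the
    latter.
    """
    degrees = pd.Series(dict(net.graph.degree), name="degree").sort_index()
    by_disease: dict[str, list[str]] = {"A": [], "B": []}
    for gene in net.nodes:
        tag = net.disease_of(gene)
        if tag in by_disease:
            by_disease[tag].append(gene)
    hubs = {
        tag: sorted(genes, key=lambda g: (-degrees[g], g))[:top_k]
        for tag, genes in by_disease.items()
    }
    return HubReport(
        degrees=degrees,
        hubs_a=hubs["A"],
        hubs_b=hubs["B"],
        cross_edges=net.cross_edges(),
        n_nodes_total=len(net.nodes),
        n_nodes_connected=int((degrees > 0).sum()),
    )


class _CrossEdgeCounter:
    """Fast cross-set edge counting against a fixed thresholded edge list."""

    def __init__(self, interactions: pd.DataFrame, threshold: float):
        scores = interactions["score"].to_numpy(dtype=float)
        keep = np.isfinite(scores) & (scores >= 0) & (scores <= 1) & (scores > threshold)
        pairs = set()
        for ga, gb in interactions.loc[keep, ["gene_a", "gene_b"]].itertuples(index=False):
            if ga != gb:
                pairs.add((ga, gb) if ga <= gb else (gb, ga))
        self.pairs = pairs

    def count(self, set_a: Sequence[str], set_b: Sequence[str]) -> int:
        a, b = set(set_a), set(set_b)
        return sum(1 for u, v in self.pairs if (u in a and v in b) or (u in b and v in a))


def connectivity_test(
    interactions: pd.DataFrame,
    nodes_a: Iterable[str],
    nodes_b: Iterable[str],
    pool: BackgroundPool,
    n: int,
    seed: int,
    threshold: float = DEFAULT_THRESHOLD,
) -> PermutationResult:
    """Upper-tail Monte-Carlo test of the observed cross-set connectivity.

    Each replicate redraws two disjoint gene sets of the observed sizes
    from the background pool and recounts cross-set edges in the induced
    thresholded network.
    """
    counter = _CrossEdgeCounter(interactions, threshold)
    return permute_statistic(
        statistic=lambda a, b: counter.count(a, b),
        set_a=sorted(set(nodes_a)),
        set_b=sorted(set(nodes_b)),
        pool=pool,
        n=n,
        seed=seed,
        tail="upper",
    )


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    """Edge-list TSV (gene_a, gene_b, score) for external visualisation."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for u, v, d in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['score']:.6g}\n")


def write_sif(net: InteractionNetwork, path: str | Path) -> None:
    """SIF export (Cytoscape import); isolated nodes on their own lines."""
    with open(path, "w") as fh:
        for u, v in sorted(net.graph.edges):
            fh.write(f"{u}\tpp\t{v}\n")
        for node in sorted(net.nodes):
            if net.graph.degree(node) == 0:
                fh.write(f"{node}\n")


def write_node_attributes(
    net: InteractionNetwork, path: str | Path, regulation: dict[str, str] | None = None
) -> None:
    """Node attribute TSV: disease tag, degree, optional regulation direction."""
    regulation = regulation or {}
    with open(path, "w") as fh:
        fh.write("gene\tdisease\tdegree\tregulation\n")
        for node in sorted(net.nodes):
            fh.write(
                f"{node}\t{net.disease_of(node)}\t{net.graph.degree(node)}"
                f"\t{regulation.get(node, 'NA')}\n"
            )
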