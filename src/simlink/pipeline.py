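"""End-to-end orchestration of the two-disease comparison.

Stage order: preprocess -> per-dataset DEG calling -> per-disease DEG
intersections -> cross-disease overlap -> semantic similarity (all
configured measures) with Monte-Carlo p-values -> interaction network,
hubs and cross-set connectivity test -> term enrichment of each DEG set
and of the hub genes.  Every filter logs before/after counts; outputs are
a machine-readable JSON report plus TSV tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from simlink import diffexpr, enrich, godag, ppinet
from simlink.expression import ExpressionDataset, log2_transform, read_expression, restrict_to_common_genes
from simlink.godag import GeneSetSimilarityCache, OntologyDag, compute_ic
from simlink.permtest import BackgroundPool, permute_statistic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    ``datasets`` maps disease label -> list of dataset descriptors
    (``id``, ``expression``, ``labels``, ``platform``, optional
    ``transform`` in {"none", "log2", "log2p1"}).
    """

    datasets: dict[str, list[dict[str, str]]]
    ontology: str
    annotations: str
    interactions: str
    out_dir: str | None = None
    namespace: str | None = None
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    ppi_threshold: float = 0.4
    ss_measures: tuple[str, ...] = ("wang", "resnik", "lin", "jiang", "rel")
    combine: str = "bma"
    n_perm_ss: int = 10000
    n_perm_net: int = 1000
    top_k_hubs: int = 10
    seed: int = 0
    fdr_cut: float = 0.05
    min_term_size: int = 3

    def __post_init__(self) -> None:
        if self.n_perm_ss < 1 or self.n_perm_net < 1:
            raise ValueError("permutation counts must be >= 1")
        if self.fc_threshold <= 1 or self.p_threshold <= 0 or self.ppi_threshold < 0:
            raise ValueError("invalid thresholds")
        if len(self.datasets) != 2:
            raise ValueError("exactly two diseases are compared")
        for disease, specs in self.datasets.items():
            if len(specs) < 2:
                raise ValueError(f"disease {disease!r} needs at least two datasets")
        unknown = set(self.ss_measures) - set(godag.MEASURES)
        if unknown:
            raise ValueError(f"unknown similarity measures {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "ss_measures" in data:
            data["ss_measures"] = tuple(data["ss_measures"])
        return cls(**data)


def _load_datasets(config: RunConfig) -> dict[str, list[ExpressionDataset]]:
    out: dict[str, list[ExpressionDataset]] = {}
    for disease, specs in config.datasets.items():
        loaded = []
        for entry in specs:
            ds = read_expression(
                entry["expression"],
                entry["labels"],
                platform=entry.get("platform", "microarray"),
                dataset_id=entry.get("id", entry["expression"]),
            )
            transform = entry.get("transform", "none")
            if transform == "log2":
                ds = ds.with_matrix(log2_transform(ds.matrix, offset=0.0))
            elif transform == "log2p1":
                ds = ds.with_matrix(log2_transform(ds.matrix, offset=1.0))
            elif transform != "none":
                raise ValueError(f"unknown transform {transform!r}")
            loaded.append(ds)
        out[disease] = loaded
    return out


def analyze(
    datasets: Mapping[str, Sequence[ExpressionDataset]],
    dag: OntologyDag,
    interactions: pd.DataFrame,
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Run every analysis stage on in-memory inputs and return the report.

    ``datasets`` maps the two disease labels to their (already
    log2-scale) expression datasets.
    """
    out_path = Path(out_dir) if out_dir else None
    if out_path:
        out_path.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    report: dict[str, Any] = {"stages": completed}

    def _finish_stage(name: str) -> None:
        completed.append(name)
        if out_path:
            (out_path / "MANIFEST").write_text("\n".join(completed) + "\n")

    def _fail(name: str, exc: Exception) -> RuntimeError:
        return RuntimeError(f"pipeline stage {name!r} failed: {exc}")

    disease_a, disease_b = sorted(datasets)

    # --- preprocess -------------------------------------------------------
    try:
        flat = [ds for specs in datasets.values() for ds in specs]
        flat = restrict_to_common_genes(flat)
        it = iter(flat)
        datasets = {d: [next(it) for _ in specs] for d, specs in datasets.items()}
        background_genes = flat[0].genes
        report["n_common_genes"] = len(background_genes)
    except Exception as exc:
        raise _fail("preprocess", exc) from exc
    _finish_stage("preprocess")

    # --- per-dataset DEGs -------------------------------------------------
    deg_sets: dict[str, list[frozenset[str]]] = {}
    report["degs"] = {}
    try:
        for disease, specs in datasets.items():
            deg_sets[disease] = []
            for ds in specs:
                table = diffexpr.call_degs(ds, config.fc_threshold, config.p_threshold)
                genes = diffexpr.deg_genes(table)
                deg_sets[disease].append(genes)
                report["degs"][ds.dataset_id] = {"n_genes": len(table), "n_deg": len(genes)}
                if out_path:
                    table.to_csv(out_path / f"deg_{ds.dataset_id}.tsv", sep="\t")
    except Exception as exc:
        raise _fail("differential_expression", exc) from exc
    _finish_stage("differential_expression")

    # --- per-disease intersection & cross-disease overlap -----------------
    try:
        sets = {
            d: diffexpr.intersect_deg_sets(
                deg_sets[d], d, [ds.dataset_id for ds in datasets[d]]
            )
            for d in datasets
        }
        genes_a = sorted(sets[disease_a].genes)
        genes_b = sorted(sets[disease_b].genes)
        if not genes_a or not genes_b:
            raise ValueError("a disease DEG intersection is empty")
        overlap = set(genes_a) & set(genes_b)
        report["disease_deg_sets"] = {
            disease_a: {"size": len(genes_a), "genes": genes_a},
            disease_b: {"size": len(genes_b), "genes": genes_b},
        }
        report["cross_disease_overlap"] = len(overlap)
    except Exception as exc:
        raise _fail("deg_intersection", exc) from exc
    _finish_stage("deg_intersection")

    # --- semantic similarity with Monte-Carlo null ------------------------
    try:
        ic = compute_ic(dag)
        annotated_pool = dag.annotated_genes(background_genes)
        pool_ss = BackgroundPool(annotated_pool)
        ann_a = dag.annotated_genes(genes_a)
        ann_b = dag.annotated_genes(genes_b)
        if not ann_a or not ann_b:
            raise ValueError("a disease DEG set has no annotated genes")
        report["semantic_similarity"] = {}
        for i, measure in enumerate(config.ss_measures):
            cache = GeneSetSimilarityCache(annotated_pool, measure, dag, ic)
            result = permute_statistic(
                statistic=lambda a, b: cache.set_sim(a, b, config.combine),
                set_a=ann_a,
                set_b=ann_b,
                pool=pool_ss,
                n=config.n_perm_ss,
                seed=_substream(config.seed, 100 + i),
                tail="upper",
            )
            report["semantic_similarity"][measure] = result.summary()
            if out_path:
                np.savetxt(out_path / f"ss_null_{measure}.tsv", result.null_values, fmt="%.8g")
    except Exception as exc:
        raise _fail("semantic_similarity", exc) from exc
    _finish_stage("semantic_similarity")

    # --- interaction network ---------------------------------------------
    try:
        net = ppinet.build_network(interactions, genes_a, genes_b, config.ppi_threshold)
        hubs = ppinet.degree_and_hubs(net, config.top_k_hubs)
        conn = ppinet.connectivity_test(
            interactions,
            genes_a,
            genes_b,
            BackgroundPool(background_genes),
            n=config.n_perm_net,
            seed=_substream(config.seed, 200),
            threshold=config.ppi_threshold,
        )
        report["network"] = {
            "n_nodes_total": hubs.n_nodes_total,
            "n_nodes_connected": hubs.n_nodes_connected,
            "n_edges": net.n_edges,
            "cross_edges": hubs.cross_edges,
            "hubs": {disease_a: hubs.hubs_a, disease_b: hubs.hubs_b},
            "connectivity": conn.summary(),
        }
        if out_path:
            ppinet.write_edge_list(net, out_path / "network_edges.tsv")
            ppinet.write_sif(net, out_path / "network.sif")
            ppinet.write_node_attributes(net, out_path / "network_nodes.tsv")
            hubs.degrees.to_csv(out_path / "degrees.tsv", sep="\t", header=["degree"])
    except Exception as exc:
        raise _fail("network", exc) from exc
    _finish_stage("network")

    # --- enrichment -------------------------------------------------------
    try:
        hub_genes = sorted(set(hubs.hubs_a) | set(hubs.hubs_b))
        report["enrichment"] = {}
        for label, query in (
            (disease_a, genes_a),
            (disease_b, genes_b),
            ("hubs", hub_genes),
        ):
            annotated_query = dag.annotated_genes(query)
            if not annotated_query:
                logger.warning("enrichment[%s]: no annotated query genes, skipped", label)
                continue
            table = enrich.enrich_terms(
                annotated_query,
                dag.annotations,
                background_genes,
                dag=dag,
                min_term_size=config.min_term_size,
                fdr_cut=config.fdr_cut,
                term_names=dag.names,
            )
            report["enrichment"][label] = {
                "n_terms_tested": len(table),
                "n_significant": int(table["significant"].sum()),
                "top_terms": table.head(5)["term"].tolist(),
            }
            if out_path:
                table.to_csv(out_path / f"enrichment_{label}.tsv", sep="\t", index=False)
    except Exception as exc:
        raise _fail("enrichment", exc) from exc
    _finish_stage("enrichment")

    if out_path:
        (out_path / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _substream(seed: int, offset: int) -> int:
    return (seed * 1000 + offset) % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """File-based entry point: load all inputs per the config, then analyze."""
    datasets = _load_datasets(config)
    dag = godag.read_obo(config.ontology, namespace=config.namespace)
    annotations = godag.read_annotations(config.annotations)
    dag = OntologyDag(
        [(c, p, r) for c, ps in dag.parents.items() for p, r in ps],
        annotations=annotations,
        terms=dag.terms,
        names=dag.names,
    )
    interactions = ppinet.read_interactions(config.interactions)
    return analyze(datasets, dag, interactions, config, out_dir=config.out_dir)
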