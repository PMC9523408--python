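"""Synthetic two-disease study generator with planted ground truth.

Emulates the structure of a cross-disease transcriptome comparison: two
diseases, each measured in two datasets (one tagged microarray, one
RNA-seq), with a disjoint set of truly differential genes planted per
disease; an ontology DAG whose branches carry the functional signal (both
diseases' planted genes annotate the same branch when the scenario plants
shared function); and a scored interaction table with planted cross-disease
edges over a sparse random background.

All randomness derives from ``scenario.seed`` through per-component
streams, so every artefact is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from simlink.expression import ExpressionDataset
from simlink.godag import OntologyDag, write_annotations, write_obo

logger = logging.getLogger(__name__)

#: log2-scale baseline intensity distribution shared by both platforms
BASELINE_MEAN = 7.0
BASELINE_SD = 1.0


@dataclass
class SyntheticScenario:
    """Ground-truth parameters of one synthetic study.

    Defaults describe a moderately powered study: 2000 genes, 10 case vs
    10 control samples per dataset, 50 planted DEGs per disease with a
    +1.0 log2-fold shift over noise sd 0.5, planted genes of both diseases
    annotated under one ontology branch, and 2 planted interaction
    partners per disease-A gene over a 0.001-density background.

    The ontology mimics the sparsity that makes real GO similarity work:
    many narrow branches (functional modules) relative to the gene-set
    sizes, so two random gene sets rarely share specific terms, while the
    planted sets share a two-leaf module of one branch.
    """

    seed: int = 0
    n_genes: int = 2000
    n_case: int = 10
    n_control: int = 10
    n_planted: int = 50
    effect_size: float = 1.0
    noise_sd: float = 0.5
    n_branches: int = 100
    branch_depth: int = 2
    leaves_per_branch: int = 3
    terms_per_gene: int = 2
    annotation_purity: float = 0.9
    annotated_fraction: float = 1.0
    shared_branch: bool = True
    ppi_background_p: float = 0.001
    planted_cross_degree: int = 2
    n_decoy_edges: int = 50

    def __post_init__(self) -> None:
        if 2 * self.n_planted > self.n_genes:
            raise ValueError("planted DEG sets exceed the gene universe")
        if self.n_branches < 2:
            raise ValueError("need >= 2 branches to separate disease functions")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("noise_sd and effect_size must be non-negative")

    @property
    def genes(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    @property
    def planted_a(self) -> list[str]:
        """Truly differential genes of disease A (disjoint from B's)."""
        return self.genes[: self.n_planted]

    @property
    def planted_b(self) -> list[str]:
        return self.genes[self.n_planted : 2 * self.n_planted]


def _rng(scenario: SyntheticScenario, stream: int) -> np.random.Generator:
    return np.random.default_rng([scenario.seed, stream])


def make_expression(scenario: SyntheticScenario) -> dict[str, ExpressionDataset]:
    """Four labelled datasets: diseases A and B, two platforms each.

    Per dataset, each gene gets a baseline ~ Normal(7, 1) on the log2
    scale; case samples of that disease's planted genes are shifted by
    ``effect_size``; iid Gaussian noise with sd ``noise_sd`` on every value.
    """
    out: dict[str, ExpressionDataset] = {}
    genes = scenario.genes
    specs = [
        ("A1", "A", "rnaseq"),
        ("A2", "A", "microarray"),
        ("B1", "B", "rnaseq"),
        ("B2", "B", "microarray"),
    ]
    for stream, (ds_id, disease, platform) in enumerate(specs):
        rng = _rng(scenario, stream)
        baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=scenario.n_genes)
        n_samples = scenario.n_case + scenario.n_control
        values = baseline[:, None] + rng.normal(0.0, scenario.noise_sd, (scenario.n_genes, n_samples))
        planted = scenario.planted_a if disease == "A" else scenario.planted_b
        planted_rows = [genes.index(g) for g in planted]
        values[np.ix_(planted_rows, range(scenario.n_case))] += scenario.effect_size
        samples = [f"{ds_id}_case{i}" for i in range(scenario.n_case)] + [
            f"{ds_id}_ctrl{i}" for i in range(scenario.n_control)
        ]
        labels = pd.Series(
            ["case"] * scenario.n_case + ["control"] * scenario.n_control, index=samples
        )
        out[ds_id] = ExpressionDataset(
            matrix=pd.DataFrame(values, index=genes, columns=samples),
            labels=labels,
            platform=platform,
            dataset_id=ds_id,
        )
    return out


def make_dag(scenario: SyntheticScenario) -> OntologyDag:
    """Rooted DAG of ``n_branches`` chains with leaf fan-out, plus annotations.

    Planted disease-A genes annotate leaves of branch 0; planted disease-B
    genes annotate the same branch when ``shared_branch`` (high expected
    similarity) or branch 1 otherwise.  A random ``annotated_fraction`` of
    the remaining genes annotate random leaves of random branches,
    providing an annotated background pool.
    """
    rng = _rng(scenario, 2)
    edges: list[tuple[str, str, str]] = []
    names: dict[str, str] = {"T:R": "root"}
    branch_leaves: list[list[str]] = []
    for b in range(scenario.n_branches):
        parent = "T:R"
        for d in range(1, scenario.branch_depth + 1):
            term = f"T:{b}.{d}"
            names[term] = f"branch{b} level{d}"
            edges.append((term, parent, "is_a"))
            parent = term
        leaves = []
        for l in range(scenario.leaves_per_branch):
            leaf = f"T:{b}.L{l}"
            names[leaf] = f"branch{b} leaf{l}"
            # mixed edge types exercise the Wang weighting
            rel = "is_a" if l % 2 == 0 else "part_of"
            edges.append((leaf, parent, rel))
            leaves.append(leaf)
        branch_leaves.append(leaves)

    annotations: dict[str, set[str]] = {}
    all_leaves = [l for ls in branch_leaves for l in ls]

    def annotate(genes: list[str], leaves: list[str]) -> None:
        # with prob annotation_purity a term comes from the gene's home
        # module, otherwise from anywhere: imperfect curation
        for g in genes:
            terms: set[str] = set()
            while len(terms) < min(scenario.terms_per_gene, len(leaves)):
                pool = leaves if rng.random() < scenario.annotation_purity else all_leaves
                terms.add(str(rng.choice(pool)))
            annotations[g] = terms

    module_a = branch_leaves[0]
    module_b = module_a if scenario.shared_branch else branch_leaves[1]
    annotate(scenario.planted_a, module_a)
    annotate(scenario.planted_b, module_b)

    rest = scenario.genes[2 * scenario.n_planted :]
    n_extra = max(0, int(scenario.annotated_fraction * scenario.n_genes) - 2 * scenario.n_planted)
    extra = list(rng.choice(rest, size=min(n_extra, len(rest)), replace=False))
    for g in extra:
        branch = int(rng.integers(scenario.n_branches))
        annotate([str(g)], branch_leaves[branch])
    return OntologyDag(edges, annotations=annotations, names=names)


def make_ppi(scenario: SyntheticScenario) -> pd.DataFrame:
    """Scored interaction table with planted cross-disease edges.

    Background edges appear pair-wise with probability ``ppi_background_p``
    and scores Uniform(0.41, 1), so the retained network density equals the
    background probability.  Every planted-A gene is wired to
    ``planted_cross_degree`` planted-B genes.  ``n_decoy_edges`` extra
    cross-disease edges get sub-threshold scores (<= 0.4) and must be
    filtered out downstream.
    """
    rng = _rng(scenario, 3)
    genes = scenario.genes
    n = scenario.n_genes
    rows: list[tuple[str, str, float]] = []
    if scenario.ppi_background_p > 0:
        iu, ju = np.triu_indices(n, k=1)
        hit = rng.random(iu.size) < scenario.ppi_background_p
        for i, j in zip(iu[hit], ju[hit]):
            rows.append((genes[i], genes[j], float(rng.uniform(0.41, 1.0))))
    for ga in scenario.planted_a:
        k = min(scenario.planted_cross_degree, scenario.n_planted)
        if k == 0:
            continue
        partners = rng.choice(scenario.planted_b, size=k, replace=False)
        for gb in partners:
            rows.append((ga, str(gb), float(rng.uniform(0.41, 1.0))))
    for _ in range(scenario.n_decoy_edges):
        ga = str(rng.choice(scenario.planted_a))
        gb = str(rng.choice(scenario.planted_b))
        rows.append((ga, gb, float(rng.uniform(0.05, 0.4))))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])


def write_scenario_files(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, str]:
    """Materialise the scenario as plain-text files for the CLI pipeline.

    Writes expression + label TSVs per dataset, the ontology as OBO, the
    annotation TSV, the interaction table and a ground-truth JSON; returns
    the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for ds_id, ds in make_expression(scenario).items():
        epath = outdir / f"expr_{ds_id}.tsv"
        lpath = outdir / f"labels_{ds_id}.tsv"
        ds.matrix.to_csv(epath, sep="\t", float_format="%.17g")
        ds.labels.to_csv(lpath, sep="\t", header=False)
        paths[f"expression_{ds_id}"] = str(epath)
        paths[f"labels_{ds_id}"] = str(lpath)
    dag = make_dag(scenario)
    write_obo(dag, outdir / "ontology.obo")
    write_annotations(dag.annotations, outdir / "annotations.tsv")
    make_ppi(scenario).to_csv(outdir / "interactions.tsv", sep="\t", index=False, header=False)
    truth = {
        "planted_a": scenario.planted_a,
        "planted_b": scenario.planted_b,
        "scenario": asdict(scenario),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    paths.update(
        ontology=str(outdir / "ontology.obo"),
        annotations=str(outdir / "annotations.tsv"),
        interactions=str(outdir / "interactions.tsv"),
        truth=str(outdir / "truth.json"),
    )
    return paths
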