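"""Expression-matrix I/O and gene-level preprocessing.

Matrices are genes-in-rows, samples-in-columns tables on a log2 scale
(log2 intensity for microarray, log2(FPKM+1) for RNA-seq).  Probe-level
arrays are collapsed to gene level by averaging replicate probes; probes
mapping to zero or multiple gene symbols are dropped before collapsing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
PLATFORMS = ("microarray", "rnaseq")


@dataclass
class ExpressionDataset:
    """A labelled gene-by-sample expression matrix.

    Parameters
    ----------
    matrix
        Real-valued DataFrame, gene symbols as index, sample ids as columns.
    labels
        Series mapping every sample id to ``"case"`` or ``"control"``.
    platform
        ``"microarray"`` or ``"rnaseq"``; drives the default log2 offset.
    dataset_id
        Free-text identifier used in logs and reports.
    """

    matrix: pd.DataFrame
    labels: pd.Series
    platform: str = "microarray"
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}, got {self.platform!r}")
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene identifiers: {dups[:5]}")
        self.labels = pd.Series(self.labels)
        missing = [s for s in self.matrix.columns if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without a case/control label: {missing}")
        self.labels = self.labels.loc[list(self.matrix.columns)]
        bad = sorted(set(self.labels) - {CASE, CONTROL})
        if bad:
            raise ValueError(f"labels must be 'case' or 'control', got {bad}")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError(
                f"need >= 2 case and >= 2 control samples, got "
                f"{self.n_case} case / {self.n_control} control"
            )
        values = self.matrix.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {self.matrix.index[r]!r}, "
                f"sample {self.matrix.columns[c]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def case_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == CONTROL])

    @property
    def n_case(self) -> int:
        return int((self.labels == CASE).sum())

    @property
    def n_control(self) -> int:
        return int((self.labels == CONTROL).sum())

    def with_matrix(self, matrix: pd.DataFrame) -> "ExpressionDataset":
        return ExpressionDataset(matrix, self.labels.copy(), self.platform, self.dataset_id)


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene symbol map with ambiguous probes removed."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for probe, gene in self.mapping.items():
            if not isinstance(gene, str) or not gene:
                raise ValueError(f"probe {probe!r} maps to invalid gene {gene!r}")

    def __len__(self) -> int:
        return len(self.mapping)


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id, group) TSV into a label Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    if df["sample"].duplicated().any():
        raise ValueError(f"duplicated sample ids in label file {path}")
    return df.set_index("sample")["group"]


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    # locate the offending cell before failing, for a usable error message
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"non-numeric value at row {row!r}, column {col!r} in {path}")
        df[col] = coerced
    return df


def read_expression(
    path: str | Path,
    labels: pd.Series | Mapping[str, str] | str | Path,
    platform: str = "microarray",
    dataset_id: str = "",
) -> ExpressionDataset:
    """Read a delimited expression table (genes in rows, header = sample ids).

    ``labels`` may be a Series/dict of sample -> group or a path to a
    two-column TSV.  Values are read back untransformed.
    """
    matrix = _read_table(path)
    if isinstance(labels, (str, Path)):
        labels = read_labels(labels)
    return ExpressionDataset(
        matrix, pd.Series(labels), platform=platform, dataset_id=dataset_id or str(path)
    )


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the matrix as TSV (full float precision, round-trip safe)."""
    dataset.matrix.to_csv(path, sep="\t", float_format="%.17g")


def read_probe_map(path: str | Path) -> ProbeMap:
    """Read a two-column (probe_id, gene_symbol) TSV, dropping ambiguous probes.

    A probe listed with more than one distinct gene symbol is removed
    entirely, matching standard array preprocessing.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"], dtype=str)
    n_genes = df.groupby("probe")["gene"].nunique()
    ambiguous = set(n_genes.index[n_genes > 1])
    if ambiguous:
        logger.info("dropping %d ambiguous probes from %s", len(ambiguous), path)
    df = df[~df["probe"].isin(ambiguous)].drop_duplicates()
    return ProbeMap(dict(zip(df["probe"], df["gene"])))


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: ProbeMap) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    Each gene's value per sample is the arithmetic mean over its probes.
    Probes absent from ``probe_map`` are dropped.  Idempotent when the rows
    are already gene symbols mapping to themselves.
    """
    genes = probe_matrix.index.map(lambda p: probe_map.mapping.get(p))
    keep = genes.notna()
    if not keep.any():
        raise ValueError("no probe in the matrix is present in the probe map")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    collapsed = probe_matrix[keep].groupby(genes[keep]).mean()
    collapsed.index.name = probe_matrix.index.name
    return collapsed


def log2_transform(matrix: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Return log2(x + offset) elementwise.

    Use ``offset=0`` for already-positive microarray intensities and
    ``offset=1`` for FPKM (log2(FPKM+1) avoids -inf at zero).
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("log2_transform requires non-negative values")
    if (values + offset <= 0).any():
        raise ValueError("zero values with offset 0: log2 undefined; use a positive offset")
    return pd.DataFrame(np.log2(values + offset), index=matrix.index, columns=matrix.columns)


def restrict_to_common_genes(datasets: Sequence[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict every dataset to the genes present in all of them, same order.

    Cross-platform comparisons are only meaningful on the shared gene
    coverage, so downstream stages operate on this intersection.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    common: set[str] = set(datasets[0].genes)
    for ds in datasets[1:]:
        common &= set(ds.genes)
    if not common:
        raise ValueError("datasets share no genes")
    order = [g for g in datasets[0].genes if g in common]
    for ds in datasets:
        logger.info(
            "restrict_to_common_genes: %s %d -> %d genes",
            ds.dataset_id, len(ds.genes), len(order),
        )
    return [ds.with_matrix(ds.matrix.loc[order]) for ds in datasets]
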