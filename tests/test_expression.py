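import numpy as np
import pandas as pd
import pytest

from simlink.expression import (
    ExpressionDataset,
    ProbeMap,
    collapse_probes,
    log2_transform,
    read_expression,
    read_probe_map,
    restrict_to_common_genes,
    write_expression,
)


@pytest.fixture
def tsv(tmp_path):
    def write(name, text):
        p = tmp_path / name
        p.write_text(text)
        return p

    return write


class TestReadExpression:
    def test_reads_matrix_with_labels(self, tsv):
        path = tsv("e.tsv", "gene\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\ng2\t5\t6\t7\t8\ng3\t0\t0\t1\t1\n")
        labels = pd.Series(["case", "case", "control", "control"], index=["s1", "s2", "s3", "s4"])
        ds = read_expression(path, labels)
        assert ds.matrix.shape == (3, 4)
        assert ds.case_samples == ["s1", "s2"]
        assert ds.matrix.loc["g2", "s3"] == 7

    def test_duplicate_gene_rows_rejected(self, tsv):
        path = tsv("dup.tsv", "gene\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\ng1\t5\t6\t7\t8\n")
        labels = {"s1": "case", "s2": "case", "s3": "control", "s4": "control"}
        with pytest.raises(ValueError, match="duplicated gene"):
            read_expression(path, labels)

    def test_non_numeric_cell_names_location(self, tsv):
        path = tsv("bad.tsv", "gene\ts1\ts2\ts3\ts4\ng1\t1\toops\t3\t4\n")
        with pytest.raises(ValueError, match="g1.*s2"):
            read_expression(path, {"s1": "case", "s2": "case", "s3": "control", "s4": "control"})

    def test_missing_label_is_hard_error(self, tsv):
        path = tsv("e.tsv", "gene\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\n")
        with pytest.raises(ValueError, match="without a case/control label"):
            read_expression(path, {"s1": "case", "s2": "case", "s3": "control"})

    def test_too_few_controls_rejected(self, dataset_factory):
        with pytest.raises(ValueError, match=">= 2"):
            dataset_factory(np.ones((2, 4)), ["case", "case", "case", "control"])

    def test_round_trip_preserves_values(self, tmp_path, dataset_factory):
        rng = np.random.default_rng(0)
        ds = dataset_factory(rng.normal(7, 1, (20, 6)), ["case"] * 3 + ["control"] * 3)
        out = tmp_path / "rt.tsv"
        write_expression(ds, out)
        back = read_expression(out, ds.labels)
        np.testing.assert_allclose(back.matrix.to_numpy(), ds.matrix.to_numpy(), rtol=0, atol=1e-9)


class TestCollapseProbes:
    PM = ProbeMap({"p1": "GENE1", "p2": "GENE1", "p4": "GENE2"})

    def test_replicate_probes_averaged(self):
        mat = pd.DataFrame({"s1": [2.0, 4.0]}, index=["p1", "p2"])
        out = collapse_probes(mat, self.PM)
        assert out.loc["GENE1", "s1"] == 3.0

    def test_unmapped_probe_dropped(self):
        mat = pd.DataFrame({"s1": [2.0, 4.0, 9.0]}, index=["p1", "p2", "p3"])
        out = collapse_probes(mat, self.PM)
        assert list(out.index) == ["GENE1"]

    def test_single_probe_identity(self):
        mat = pd.DataFrame({"s1": [5.5], "s2": [1.0]}, index=["p4"])
        out = collapse_probes(mat, self.PM)
        assert out.loc["GENE2"].tolist() == [5.5, 1.0]

    def test_idempotent_on_gene_level_matrix(self):
        mat = pd.DataFrame({"s1": [2.0, 4.0, 7.0]}, index=["p1", "p2", "p4"])
        once = collapse_probes(mat, self.PM)
        identity = ProbeMap({g: g for g in once.index})
        pd.testing.assert_frame_equal(collapse_probes(once, identity), once)

    def test_disjoint_probe_sets_error(self):
        mat = pd.DataFrame({"s1": [1.0]}, index=["nope"])
        with pytest.raises(ValueError, match="probe map"):
            collapse_probes(mat, self.PM)

    def test_ambiguous_probes_removed_on_read(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("p1\tGENE1\np1\tGENE2\np2\tGENE3\n")
        pm = read_probe_map(p)
        assert pm.mapping == {"p2": "GENE3"}


class TestLog2Transform:
    def test_offset_one(self):
        mat = pd.DataFrame({"s": [7.0, 0.0]})
        out = log2_transform(mat, offset=1.0)
        assert out["s"].tolist() == [3.0, 0.0]

    def test_zero_without_offset_errors(self):
        with pytest.raises(ValueError, match="log2 undefined"):
            log2_transform(pd.DataFrame({"s": [0.0]}), offset=0.0)

    def test_negative_input_errors(self):
        with pytest.raises(ValueError, match="non-negative"):
            log2_transform(pd.DataFrame({"s": [-1.0]}), offset=1.0)


class TestRestrictToCommonGenes:
    def test_intersection(self, dataset_factory):
        d1 = dataset_factory(np.ones((3, 4)), ["case"] * 2 + ["control"] * 2, genes=["A", "B", "C"])
        d2 = dataset_factory(np.ones((3, 4)), ["case"] * 2 + ["control"] * 2, genes=["B", "C", "D"])
        r1, r2 = restrict_to_common_genes([d1, d2])
        assert r1.genes == r2.genes == ["B", "C"]

    def test_identical_lists_unchanged(self, dataset_factory):
        d1 = dataset_factory(np.ones((2, 4)), ["case"] * 2 + ["control"] * 2, genes=["A", "B"])
        d2 = dataset_factory(np.ones((2, 4)), ["case"] * 2 + ["control"] * 2, genes=["A", "B"])
        r1, r2 = restrict_to_common_genes([d1, d2])
        assert r1.genes == ["A", "B"]

    def test_disjoint_lists_error(self, dataset_factory):
        d1 = dataset_factory(np.ones((1, 4)), ["case"] * 2 + ["control"] * 2, genes=["A"])
        d2 = dataset_factory(np.ones((1, 4)), ["case"] * 2 + ["control"] * 2, genes=["B"])
        with pytest.raises(ValueError, match="no genes"):
            restrict_to_common_genes([d1, d2])

    def test_single_dataset_rejected(self, dataset_factory):
        d1 = dataset_factory(np.ones((1, 4)), ["case"] * 2 + ["control"] * 2)
        with pytest.raises(ValueError, match="two datasets"):
            restrict_to_common_genes([d1])
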