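import numpy as np
import pandas as pd
import pytest

from simlink.expression import ExpressionDataset
from simlink.godag import OntologyDag, compute_ic
from simlink.synthdata import SyntheticScenario

# Three-branch toy ontology used throughout: each branch is a depth-3 chain
# hanging off the root by a part_of edge, fanning into two is_a leaves.
# Branches meet only at the root, so cross-branch similarity is near zero.
TOY_EDGES = [
    edge
    for b in "XYZ"
    for edge in [
        (f"{b}1", "R", "part_of"),
        (f"{b}2", f"{b}1", "is_a"),
        (f"{b}3", f"{b}2", "is_a"),
        (f"{b}a", f"{b}3", "is_a"),
        (f"{b}b", f"{b}3", "is_a"),
    ]
]

TOY_ANNOTATIONS = {
    "gx1": {"Xa"},
    "gx2": {"Xb"},
    "gx3": {"Xa", "Xb"},
    # direct annotations on internal terms give the X chain strictly
    # increasing IC with depth (ties would otherwise resolve to the
    # lexicographically smallest ancestor)
    "gx4": {"X2"},
    "gx5": {"X1"},
    "gx6": {"X3"},
    "gy1": {"Ya"},
    "gy2": {"Yb"},
    "gy3": {"Y2"},
    "gz1": {"Za"},
    "gz2": {"Za", "Yb"},
}


@pytest.fixture(scope="session")
def toy_parents():
    parents = {}
    for child, parent, rel in TOY_EDGES:
        parents.setdefault(child, []).append((parent, rel))
        parents.setdefault(parent, [])
    return parents


@pytest.fixture(scope="session")
def toy_dag():
    return OntologyDag(TOY_EDGES, annotations=TOY_ANNOTATIONS)


@pytest.fixture(scope="session")
def toy_ic(toy_dag):
    return compute_ic(toy_dag)


@pytest.fixture(scope="session")
def small_scenario():
    """Scaled-down study for quick pipeline-level tests."""
    return SyntheticScenario(
        seed=7, n_genes=400, n_planted=25, n_branches=30, annotated_fraction=1.0
    )


def make_dataset(values, labels, genes=None, dataset_id="test", platform="microarray"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionDataset(
        matrix=pd.DataFrame(values, index=genes, columns=samples),
        labels=pd.Series(labels, index=samples),
        platform=platform,
        dataset_id=dataset_id,
    )


@pytest.fixture
def dataset_factory():
    return make_dataset
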