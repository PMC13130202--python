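import numpy as np
import pytest

from multidda.data_io import (
    AssociationMatrix,
    DatasetBundle,
    MeshDag,
    ModalityMatrix,
    MODALITIES,
)
from multidda.synthetic import SyntheticSpec, generate_bundle

import networkx as nx


@pytest.fixture
def diamond_dag():
    """r -> a -> c, r -> b -> c plus sibling leaves under the root."""
    g = nx.DiGraph()
    g.add_edges_from([("r", "a"), ("r", "b"), ("a", "c"), ("b", "c")])
    return MeshDag(g, {"dC": "c", "dA": "a", "dB": "b"})


@pytest.fixture
def toy_bundle():
    """2 drugs x 2 diseases, identity associations, tiny DAG."""
    drugs = ["c1", "c2"]
    mods = {
        m: ModalityMatrix(m, drugs, [f"{m}1", f"{m}2", f"{m}3"],
                          np.array([[1, 0, 1], [0, 1, 0]], dtype=np.int8))
        for m in MODALITIES
    }
    assoc = AssociationMatrix(drugs, ["d1", "d2"], np.eye(2, dtype=np.int8))
    g = nx.DiGraph()
    g.add_edges_from([("root", "n1"), ("root", "n2")])
    dag = MeshDag(g, {"d1": "n1", "d2": "n2"})
    return DatasetBundle(mods, assoc, dag)


def small_spec(seed=0, **kw):
    """A fast bundle for training-path tests (seconds, not minutes)."""
    defaults = dict(
        n_drugs=16, n_diseases=24, latent_rank=3, density=0.12,
        modality_dims={"target": 20, "enzyme": 10, "pathway": 15,
                       "substructure": 25, "ddi": 30},
        informativeness={m: 0.8 for m in MODALITIES},
        dag_depth=3, dag_branching=3, seed=seed,
    )
    defaults.update(kw)
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    bundle, gt = generate_bundle(small_spec(seed=0))
    return bundle, gt
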