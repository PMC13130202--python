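"""Heterogeneous drug–disease graph assembly.

Drugs and diseases become one node set (drugs first, 0-based).  The block
adjacency combines the two similarity matrices with the known association
matrix:

    A = [[S^c,       A_known],
         [A_knownᵀ,  S^d    ]]

Initial node features mirror the association structure only:

    H0 = [[0,        A_known],
          [A_knownᵀ, 0      ]]

so the first convolution level learns purely from graph topology.
Normalization is the symmetric GCN renormalization with self-loops,
Â = D̃^{-1/2}(A + I)D̃^{-1/2}.  Per-fold masking removes held-out test
positives from A_known before assembly so that neither A nor H0 leaks
test labels into training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix, ValidationError
from .similarity import SimilarityMatrix


@dataclass
class HeteroGraph:
    """Block adjacency, its normalized form, and initial node features."""

    adjacency: np.ndarray       # (n, n), n = |C| + |D|
    normalized: np.ndarray      # Â, same shape
    h0: np.ndarray              # initial node features, same shape
    drug_ids: list[str]
    disease_ids: list[str]

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_drugs + self.n_diseases

    # block accessors — assemble_adjacency is invertible through these
    @property
    def drug_block(self) -> np.ndarray:
        c = self.n_drugs
        return self.adjacency[:c, :c]

    @property
    def disease_block(self) -> np.ndarray:
        c = self.n_drugs
        return self.adjacency[c:, c:]

    @property
    def association_block(self) -> np.ndarray:
        c = self.n_drugs
        return self.adjacency[:c, c:]


def assemble_adjacency(sc: SimilarityMatrix, sd: SimilarityMatrix,
                       a_known: AssociationMatrix) -> HeteroGraph:
    """Build the (|C|+|D|)-node heterogeneous graph from its three blocks."""
    c, d = a_known.values.shape
    if sc.n != c:
        raise ValidationError(f"drug similarity is {sc.n}x{sc.n} but "
                              f"associations have {c} drugs")
    if sd.n != d:
        raise ValidationError(f"disease similarity is {sd.n}x{sd.n} but "
                              f"associations have {d} diseases")
    ak = a_known.values.astype(np.float64)
    adjacency = np.block([[sc.values, ak], [ak.T, sd.values]])
    h0 = np.block([[np.zeros((c, c)), ak], [ak.T, np.zeros((d, d))]])
    return HeteroGraph(
        adjacency=adjacency,
        normalized=normalize_adjacency(adjacency),
        h0=h0,
        drug_ids=list(a_known.drug_ids),
        disease_ids=list(a_known.disease_ids),
    )


def normalize_adjacency(a: np.ndarray) -> np.ndarray:
    """Symmetric renormalization Â = D̃^{-1/2}(A + I)D̃^{-1/2} with self-loops."""
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if (a < 0).any():
        raise ValueError("adjacency has negative entries")
    a_tilde = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def mask_test_fold(a_known: AssociationMatrix,
                   test_pairs) -> AssociationMatrix:
    """Return a copy of ``a_known`` with the given positive entries zeroed.

    ``test_pairs`` are (drug_index, disease_index) tuples and must all be
    known positives; the input matrix is left untouched.
    """
    values = a_known.values.copy()
    for i, j in test_pairs:
        if values[i, j] != 1:
            raise ValidationError(f"pair ({i}, {j}) is not a known positive")
        values[i, j] = 0
    return AssociationMatrix(list(a_known.drug_ids), list(a_known.disease_ids),
                             values)


# single-file archive of a built graph (CLI exchange format) -----------------


def save_graph(graph: HeteroGraph, path) -> None:
    """Write A, Â, H0 and the id maps into one ``.npz`` archive."""
    np.savez_compressed(
        path,
        adjacency=graph.adjacency,
        normalized=graph.normalized,
        h0=graph.h0,
        drug_ids=np.array(graph.drug_ids, dtype=object),
        disease_ids=np.array(graph.disease_ids, dtype=object),
    )


def load_graph(path) -> HeteroGraph:
    with np.load(path, allow_pickle=True) as z:
        return HeteroGraph(
            adjacency=z["adjacency"],
            normalized=z["normalized"],
            h0=z["h0"],
            drug_ids=[str(x) for x in z["drug_ids"]],
            disease_ids=[str(x) for x in z["disease_ids"]],
        )
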