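"""Drug–drug Jaccard similarity and DAG-based disease semantic similarity.

Drugs are compared by the Jaccard index of their concatenated binary
feature vectors (targets, enzymes, DDI profile, pathways, substructures):

    S^c_ij = |x_i ∩ x_j| / |x_i ∪ x_j|,   x_i = ∥_k c_k(i)

Diseases are compared through their positions in the MeSH-style DAG.  Each
disease d assigns every ancestor node n a contribution C_d(n) that decays
with distance from d:

    C_d(d) = 1
    C_d(n) = max_{n' ∈ children(n) on a path to d} Δ · C_d(n')

and the semantic similarity of two diseases is the contribution mass of
their shared ancestors relative to their total semantic values:

    S^d_ij = Σ_{n ∈ N(d_i) ∩ N(d_j)} (C_{d_i}(n) + C_{d_j}(n))
             / (DV(d_i) + DV(d_j)),     DV(d) = Σ_{n ∈ N(d)} C_d(n)

where N(d) is the ancestor closure of d (including d).  Both matrices are
symmetric with entries in [0, 1] and unit diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import DatasetBundle, MeshDag, MODALITY_CODES

logger = logging.getLogger("multidda")

DEFAULT_DELTA = 0.5


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over drugs or diseases."""

    entity_ids: list[str]
    values: np.ndarray  # (n, n) float64 in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix is not square over entity_ids")

    @property
    def n(self) -> int:
        return len(self.entity_ids)


@dataclass
class SemanticContribution:
    """Per-ancestor contribution values C_d(n) for one disease."""

    disease: str
    values: dict[str, float]  # DAG node -> contribution in (0, 1]


def jaccard(u: np.ndarray, v: np.ndarray) -> float:
    """Jaccard index of two binary vectors; 0 when the union is empty."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    union = np.count_nonzero(u | v)
    if union == 0:
        return 0.0
    return np.count_nonzero(u & v) / union


def _resolve_modalities(use_modalities) -> list[str]:
    names = []
    for m in use_modalities:
        names.append(MODALITY_CODES.get(m, m))
    return names


def drug_similarity(bundle: DatasetBundle, use_modalities=("t", "e", "n", "p", "l")
                    ) -> SimilarityMatrix:
    """Pairwise Jaccard similarity over concatenated modality vectors.

    ``use_modalities`` accepts short codes (t/e/n/p/l) or full modality
    names; at least one modality must be selected and present in the bundle.
    """
    names = _resolve_modalities(use_modalities)
    if not names:
        raise ValueError("at least one modality must be selected")
    missing = [n for n in names if n not in bundle.modalities]
    if missing:
        raise ValueError(f"modalities not in bundle: {missing}")

    x = np.concatenate(
        [bundle.modalities[n].values.astype(bool) for n in names], axis=1
    )
    # |∩| = X Xᵀ over booleans; |∪| = |u| + |v| - |∩|
    xi = x.astype(np.int64)
    inter = xi @ xi.T
    sizes = xi.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return SimilarityMatrix(list(bundle.drug_ids), s)


def semantic_contribution(dag: MeshDag, disease: str,
                          delta: float = DEFAULT_DELTA) -> SemanticContribution:
    """Discounted contribution C_d(n) of each ancestor n of ``disease``.

    The disease's own node contributes 1; every other ancestor contributes
    Δ times the best contribution among its children that lie on a path
    toward the disease, so contributions decay geometrically with distance.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    node = dag.node_of(disease)
    closure = dag.ancestors(node)
    contrib = {node: 1.0}
    # process ancestors in order of increasing distance from the disease node:
    # repeatedly relax until fixed point (closure is small; DAG so terminates)
    pending = closure - {node}
    while pending:
        progressed = False
        for n in list(pending):
            kids = [c for c in dag.graph.successors(n) if c in closure and c in contrib]
            all_kids = [c for c in dag.graph.successors(n) if c in closure]
            if kids and len(kids) == len(all_kids):
                contrib[n] = delta * max(contrib[c] for c in kids)
                pending.discard(n)
                progressed = True
        if not progressed:  # pragma: no cover - impossible in a DAG
            raise RuntimeError("contribution recursion did not converge")
    return SemanticContribution(disease, contrib)


def disease_similarity(dag: MeshDag, delta: float = DEFAULT_DELTA,
                       disease_ids=None) -> SimilarityMatrix:
    """Semantic similarity matrix over all mapped diseases (or ``disease_ids``)."""
    if disease_ids is None:
        disease_ids = list(dag.disease_map)
    contribs = {d: semantic_contribution(dag, d, delta).values for d in disease_ids}
    dv = {d: sum(c.values()) for d, c in contribs.items()}

    n = len(disease_ids)
    s = np.eye(n)
    disjoint = 0
    for i in range(n):
        ci = contribs[disease_ids[i]]
        for j in range(i + 1, n):
            cj = contribs[disease_ids[j]]
            shared = ci.keys() & cj.keys()
            if not shared:
                disjoint += 1
                continue
            num = sum(ci[k] + cj[k] for k in shared)
            s[i, j] = s[j, i] = num / (dv[disease_ids[i]] + dv[disease_ids[j]])
    if disjoint:
        logger.info("disease_similarity: %d pairs share no ancestor (similarity 0)",
                    disjoint)
    return SimilarityMatrix(list(disease_ids), s)


def write_similarity(sim: SimilarityMatrix, path) -> None:
    """Square TSV with entity IDs as both header and index."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(sim.entity_ids) + "\n")
        for i, eid in enumerate(sim.entity_ids):
            fh.write(eid + "\t" + "\t".join(f"{v:.12g}" for v in sim.values[i]) + "\n")


def read_similarity(path) -> SimilarityMatrix:
    from .data_io import _read_tsv_lines

    rows = _read_tsv_lines(path)
    ids = rows[0][1:]
    values = np.array([[float(c) for c in r[1:]] for r in rows[1:]])
    return SimilarityMatrix(ids, values)
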