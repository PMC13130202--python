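"""Readers, writers and validation for the on-disk dataset formats.

All files are UTF-8 tab-separated text; lines starting with ``#`` are
comments.  Three formats are handled:

* modality matrix — header row of feature IDs, first column of drug IDs,
  binary cells (one file per modality: target, enzyme, pathway,
  substructure, ddi);
* association edge list — ``drug_id<TAB>disease_id[<TAB>weight]``;
* disease DAG — a parent→child edge list plus a disease→DAG-node mapping.

Writers produce files the readers accept bit-exactly (modulo trailing
whitespace), which is property-tested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger("multidda")

MODALITIES = ("target", "enzyme", "pathway", "substructure", "ddi")

#: short labels used in formulas and on the command line
MODALITY_CODES = {
    "t": "target",
    "e": "enzyme",
    "n": "ddi",
    "p": "pathway",
    "l": "substructure",
}


class FormatError(ValueError):
    """A file violates the on-disk format contract."""


class ValidationError(ValueError):
    """Individually well-formed inputs are mutually inconsistent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ModalityMatrix:
    """Binary drug × feature matrix for one descriptor modality."""

    modality: str
    drug_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # (|C|, n_k) int8, entries in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.drug_ids), len(self.feature_ids)):
            raise ValidationError(
                f"{self.modality}: shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.feature_ids)} features"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise FormatError(f"{self.modality}: non-binary entries present")
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.feature_ids, "feature")
        zero_rows = np.flatnonzero(self.values.sum(axis=1) == 0)
        if zero_rows.size:
            logger.warning(
                "%s: %d drug(s) with no annotated feature (e.g. %s)",
                self.modality, zero_rows.size, self.drug_ids[zero_rows[0]],
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class AssociationMatrix:
    """Binary drug × disease association matrix (bipartite, rows = drugs)."""

    drug_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray  # (|C|, |D|) int8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ValidationError("association matrix shape/ID mismatch")
        if not np.isin(self.values, (0, 1)).all():
            raise FormatError("association matrix has non-binary entries")
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.disease_ids, "disease")

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    @property
    def density(self) -> float:
        return self.n_positives / self.values.size

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (drug_idx, disease_idx) of known associations."""
        return [tuple(p) for p in np.argwhere(self.values == 1)]


@dataclass
class MeshDag:
    """Rooted DAG of disease descriptors plus a disease→node mapping.

    Edges point parent → child (broader → more specific term), as in the
    MeSH disease branch.  Acyclicity is verified on construction; the
    ancestor closure of a node always contains the node itself.
    """

    graph: nx.DiGraph
    disease_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValidationError(f"DAG contains a cycle: {cycle}")
        roots = self.roots()
        for disease, node in self.disease_map.items():
            if node not in self.graph:
                raise ValidationError(
                    f"disease {disease!r} maps to unknown node {node!r}"
                )
        if self.disease_map:
            reachable: set[str] = set()
            for r in roots:
                reachable.add(r)
                reachable.update(nx.descendants(self.graph, r))
            unreachable = {
                d for d, n in self.disease_map.items() if n not in reachable
            }
            if unreachable:
                raise ValidationError(
                    f"diseases not reachable from any root: {sorted(unreachable)}"
                )

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def roots(self) -> list[str]:
        return [n for n in self.graph if self.graph.in_degree(n) == 0]

    def ancestors(self, node: str) -> set[str]:
        """Ancestor closure of ``node``: the node itself plus everything above it."""
        return {node} | nx.ancestors(self.graph, node)

    def node_of(self, disease: str) -> str:
        try:
            return self.disease_map[disease]
        except KeyError:
            raise ValidationError(f"disease {disease!r} is not mapped to a DAG node")


@dataclass
class DatasetBundle:
    """Aligned modality matrices + associations + disease DAG."""

    modalities: dict[str, ModalityMatrix]
    associations: AssociationMatrix
    dag: MeshDag

    @property
    def drug_ids(self) -> list[str]:
        return self.associations.drug_ids

    @property
    def disease_ids(self) -> list[str]:
        return self.associations.disease_ids

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)


def _check_unique(ids: list[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} ID {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv_lines(path) -> list[list[str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.lstrip().startswith("#"):
                continue
            rows.append(line.split("\t"))
    return rows


def read_modality_matrix(path, modality: str) -> ModalityMatrix:
    """Read one binary drug × feature TSV (header = feature IDs, col 0 = drug IDs)."""
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    rows = _read_tsv_lines(path)
    if not rows:
        raise FormatError(f"{path}: empty modality file")
    feature_ids = rows[0][1:]
    drug_ids, data = [], []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(feature_ids) + 1:
            raise FormatError(f"{path}: line {r} has {len(row)} fields, "
                              f"expected {len(feature_ids) + 1}")
        drug_ids.append(row[0])
        vals = []
        for c, cell in enumerate(row[1:]):
            if cell not in ("0", "1"):
                raise FormatError(
                    f"{path}: non-binary value {cell!r} at drug {row[0]!r}, "
                    f"feature {feature_ids[c]!r}"
                )
            vals.append(int(cell))
        data.append(vals)
    return ModalityMatrix(modality, drug_ids, feature_ids,
                          np.array(data, dtype=np.int8))


def read_association_table(path) -> AssociationMatrix:
    """Read a drug–disease edge list into a dense binary matrix.

    Unlisted pairs are 0 (no known association).  IDs appear in first-seen
    file order; duplicate pairs are collapsed to a single 1 with a warning.
    """
    rows = _read_tsv_lines(path)
    if not rows:
        raise FormatError(f"{path}: empty association file")
    drug_ids: list[str] = []
    disease_ids: list[str] = []
    drug_pos: dict[str, int] = {}
    dis_pos: dict[str, int] = {}
    pairs: list[tuple[int, int]] = []
    seen = set()
    for r, row in enumerate(rows, start=1):
        if len(row) not in (2, 3):
            raise FormatError(f"{path}: line {r} has {len(row)} fields, expected 2-3")
        drug, disease = row[0], row[1]
        if len(row) == 3 and row[2] not in ("", "1"):
            if row[2] == "0":
                continue  # explicit non-edge
            raise FormatError(f"{path}: line {r}: weight {row[2]!r} is not binary")
        if drug not in drug_pos:
            drug_pos[drug] = len(drug_ids)
            drug_ids.append(drug)
        if disease not in dis_pos:
            dis_pos[disease] = len(disease_ids)
            disease_ids.append(disease)
        key = (drug_pos[drug], dis_pos[disease])
        if key in seen:
            warnings.warn(f"{path}: duplicate pair ({drug}, {disease}); keeping one")
            continue
        seen.add(key)
        pairs.append(key)
    if not pairs:
        raise FormatError(f"{path}: no associations listed")
    values = np.zeros((len(drug_ids), len(disease_ids)), dtype=np.int8)
    for i, j in pairs:
        values[i, j] = 1
    return AssociationMatrix(drug_ids, disease_ids, values)


def read_mesh_dag(edge_path, mapping_path) -> MeshDag:
    """Read a parent→child edge list and a disease→node mapping."""
    g = nx.DiGraph()
    for r, row in enumerate(_read_tsv_lines(edge_path), start=1):
        if len(row) != 2:
            raise FormatError(f"{edge_path}: line {r} has {len(row)} fields, expected 2")
        g.add_edge(row[0], row[1])
    mapping: dict[str, str] = {}
    for r, row in enumerate(_read_tsv_lines(mapping_path), start=1):
        if len(row) != 2:
            raise FormatError(f"{mapping_path}: line {r} has {len(row)} fields")
        disease, node = row
        if disease in mapping:
            raise ValidationError(f"disease {disease!r} mapped more than once")
        if node not in g:
            raise ValidationError(
                f"{mapping_path}: disease {disease!r} maps to node {node!r} "
                "absent from the edge file"
            )
        mapping[disease] = node
    return MeshDag(g, mapping)


# ---------------------------------------------------------------------------
# writers (round-trip exact against the readers above)
# ---------------------------------------------------------------------------


def write_modality_matrix(mat: ModalityMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\t" + "\t".join(mat.feature_ids) + "\n")
        for i, drug in enumerate(mat.drug_ids):
            fh.write(drug + "\t" + "\t".join(str(int(v)) for v in mat.values[i]) + "\n")


def write_association_table(assoc: AssociationMatrix, path) -> None:
    """Write positive pairs as an edge list (row-major order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in assoc.positive_pairs():
            fh.write(f"{assoc.drug_ids[i]}\t{assoc.disease_ids[j]}\n")


def write_mesh_dag(dag: MeshDag, edge_path, mapping_path) -> None:
    with open(edge_path, "w", encoding="utf-8") as fh:
        for parent, child in dag.graph.edges:
            fh.write(f"{parent}\t{child}\n")
    with open(mapping_path, "w", encoding="utf-8") as fh:
        for disease, node in dag.disease_map.items():
            fh.write(f"{disease}\t{node}\n")


# bundle directory layout -----------------------------------------------------

_BUNDLE_FILES = {m: f"{m}.tsv" for m in MODALITIES}


def write_bundle(bundle: DatasetBundle, directory) -> None:
    """Write a complete bundle into ``directory`` in the formats above."""
    import os

    os.makedirs(directory, exist_ok=True)
    for name, mat in bundle.modalities.items():
        write_modality_matrix(mat, os.path.join(directory, _BUNDLE_FILES[name]))
    write_association_table(bundle.associations,
                            os.path.join(directory, "associations.tsv"))
    write_mesh_dag(bundle.dag, os.path.join(directory, "dag_edges.tsv"),
                   os.path.join(directory, "disease_map.tsv"))


def expand_associations(assoc: AssociationMatrix, drug_order: list[str],
                        disease_order: list[str]) -> AssociationMatrix:
    """Re-embed an edge-list-derived matrix into a full ID universe.

    Edge lists cannot carry drugs/diseases that have no association, so the
    authoritative orderings come from the modality files (drugs) and the
    disease-mapping file (diseases).
    """
    unknown_drugs = set(assoc.drug_ids) - set(drug_order)
    unknown_dis = set(assoc.disease_ids) - set(disease_order)
    if unknown_drugs or unknown_dis:
        raise ValidationError(
            f"association IDs missing from the ID universe: "
            f"{sorted(unknown_drugs) + sorted(unknown_dis)}")
    values = np.zeros((len(drug_order), len(disease_order)), dtype=np.int8)
    di = {d: i for i, d in enumerate(drug_order)}
    zi = {z: j for j, z in enumerate(disease_order)}
    for i, j in assoc.positive_pairs():
        values[di[assoc.drug_ids[i]], zi[assoc.disease_ids[j]]] = 1
    return AssociationMatrix(list(drug_order), list(disease_order), values)


def read_bundle(directory) -> DatasetBundle:
    import os

    modalities = {
        m: read_modality_matrix(os.path.join(directory, f), m)
        for m, f in _BUNDLE_FILES.items()
        if os.path.exists(os.path.join(directory, f))
    }
    assoc = read_association_table(os.path.join(directory, "associations.tsv"))
    dag = read_mesh_dag(os.path.join(directory, "dag_edges.tsv"),
                        os.path.join(directory, "disease_map.tsv"))
    if modalities:
        drug_order = next(iter(modalities.values())).drug_ids
        assoc = expand_associations(assoc, drug_order,
                                    list(dag.disease_map))
    return validate_bundle(modalities, assoc, dag)


# ---------------------------------------------------------------------------
# cross-file validation
# ---------------------------------------------------------------------------


def validate_bundle(
    modalities: dict[str, ModalityMatrix],
    associations: AssociationMatrix,
    dag: MeshDag,
) -> DatasetBundle:
    """Reconcile drug orderings across files and check disease/DAG coverage.

    If any modality's drug set differs from the association table's, the
    bundle is restricted to the sorted intersection with a warning; an empty
    intersection is an error.
    """
    if not modalities:
        raise ValidationError("no modality matrices supplied")

    drug_sets = [set(m.drug_ids) for m in modalities.values()]
    shared = set(associations.drug_ids).intersection(*drug_sets)
    if not shared:
        raise ValidationError("no drug ID shared by all modality/association files")

    orderings = {tuple(m.drug_ids) for m in modalities.values()}
    orderings.add(tuple(associations.drug_ids))
    if len(orderings) > 1:
        order = sorted(shared)
        warnings.warn(
            f"drug ID orderings differ across files; restricting to the "
            f"{len(order)} shared drugs in sorted order"
        )
        modalities = {
            name: _reindex_modality(m, order) for name, m in modalities.items()
        }
        keep = [associations.drug_ids.index(d) for d in order]
        associations = AssociationMatrix(
            order, associations.disease_ids, associations.values[keep]
        )

    missing = [d for d in associations.disease_ids if d not in dag.disease_map]
    if missing:
        raise ValidationError(
            f"{len(missing)} disease(s) not mapped in the DAG, e.g. {missing[0]!r}"
        )

    bundle = DatasetBundle(modalities, associations, dag)
    dims = ", ".join(f"{n}={m.n_features}" for n, m in modalities.items())
    logger.info(
        "bundle: %d drugs, %d diseases, %d associations (density %.4f); "
        "modality dims: %s",
        bundle.n_drugs, bundle.n_diseases, associations.n_positives,
        associations.density, dims,
    )
    return bundle


def _reindex_modality(mat: ModalityMatrix, order: list[str]) -> ModalityMatrix:
    idx = [mat.drug_ids.index(d) for d in order]
    return ModalityMatrix(mat.modality, list(order), mat.feature_ids, mat.values[idx])
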