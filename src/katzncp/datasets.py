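"""Association tables, disease ancestor DAGs, and synthetic fixtures.

The predictor consumes two inputs:

* a Boolean miRNA x disease association matrix ``MD`` (rows are miRNAs,
  columns are diseases), read from a two-column pair list plus two ordered
  name lists;
* a forest of per-disease directed acyclic graphs, each giving a disease's
  ancestor terms in a MeSH-style hierarchy.  Edges run parent -> child and
  the disease itself is the unique sink of its own DAG.

All file formats are plain TSV (UTF-8, ``#`` comment lines ignored) so that
fixtures are inspectable and diffable.  Two generators produce synthetic
inputs with the statistical structure the pipeline assumes: a plain sparse
generator and a block-structured one in which clusters of miRNAs attach
preferentially to clusters of diseases that share ancestor vocabulary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "AssociationMatrix",
    "DiseaseDagForest",
    "SyntheticConfig",
    "load_associations",
    "save_associations",
    "load_dag_forest",
    "save_dag_forest",
    "generate_synthetic",
    "generate_block_synthetic",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AssociationMatrix:
    """Boolean miRNA x disease association matrix with ordered name lists."""

    values: np.ndarray
    mirna_names: list[str]
    disease_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        self.mirna_names = list(self.mirna_names)
        self.disease_names = list(self.disease_names)

    @property
    def nm(self) -> int:
        return self.values.shape[0]

    @property
    def nd(self) -> int:
        return self.values.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        if self.values.shape != (len(self.mirna_names), len(self.disease_names)):
            raise ValueError("matrix shape does not match name lists")
        if len(set(self.mirna_names)) != len(self.mirna_names):
            raise ValueError("duplicate miRNA names")
        if len(set(self.disease_names)) != len(self.disease_names):
            raise ValueError("duplicate disease names")
        if not self.values.any():
            raise ValueError("association matrix contains no positive entry")

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.mirna_names), list(self.disease_names)
        )


class DiseaseDagForest:
    """Per-disease ancestor DAGs.

    Each disease ``d`` maps to a directed acyclic graph over its ancestor
    term set ``N(d)`` (which includes ``d`` itself); edges point from parent
    term to child term, so ``d`` is the unique sink reachable from every
    node.
    """

    def __init__(self, dags: dict[str, nx.DiGraph] | None = None):
        self.dags: dict[str, nx.DiGraph] = dict(dags or {})

    @property
    def diseases(self) -> list[str]:
        return list(self.dags)

    def __contains__(self, disease: str) -> bool:
        return disease in self.dags

    def __len__(self) -> int:
        return len(self.dags)

    def node_set(self, disease: str) -> set[str]:
        """Ancestor term set N(d), including the disease itself."""
        return set(self.dags[disease].nodes)

    def add_disease(self, disease: str, edges: Iterable[tuple[str, str]] = ()) -> None:
        g = nx.DiGraph()
        g.add_node(disease)
        g.add_edges_from(edges)
        self.dags[disease] = g

    def validate(self) -> None:
        for disease, g in self.dags.items():
            if disease not in g:
                raise ValueError(f"disease {disease!r} absent from its own node set")
            if not nx.is_directed_acyclic_graph(g):
                raise ValueError(f"ancestor graph of {disease!r} contains a cycle")
            if list(g.successors(disease)):
                raise ValueError(f"disease {disease!r} is not a sink of its DAG")
            # every node must reach the disease along parent->child edges
            reaches = nx.ancestors(g, disease) | {disease}
            if reaches != set(g.nodes):
                stray = set(g.nodes) - reaches
                raise ValueError(
                    f"nodes {sorted(stray)} in DAG of {disease!r} do not reach it"
                )


@dataclass
class SyntheticConfig:
    """Parameters of the plain synthetic generator."""

    n_mirnas: int = 50
    n_diseases: int = 30
    density: float = 0.1
    dag_depth: int = 4
    shared_ancestor_pool: int = 20
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_mirnas, self.n_diseases, self.dag_depth + 1,
               self.shared_ancestor_pool) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must lie in (0, 1]")
        if self.density * self.n_mirnas * self.n_diseases < 1:
            raise ValueError("requested density yields no positive association")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _read_lines(path: str | Path) -> list[str]:
    out = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def _read_name_list(path: str | Path) -> list[str]:
    names = _read_lines(path)
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate names in list file {path}")
    return names


def load_associations(
    pair_table: str | Path,
    mirna_list: str | Path,
    disease_list: str | Path,
) -> AssociationMatrix:
    """Read the known-association matrix from a pair list and two name lists.

    The pair table has one ``miRNA<TAB>disease`` row per association; the
    name lists fix row/column order.  Unknown names are fatal; duplicated
    pairs are collapsed with a warning (curation exports commonly repeat
    pairs).
    """
    mirnas = _read_name_list(mirna_list)
    diseases = _read_name_list(disease_list)
    m_index = {n: i for i, n in enumerate(mirnas)}
    d_index = {n: j for j, n in enumerate(diseases)}

    values = np.zeros((len(mirnas), len(diseases)), dtype=bool)
    n_dupes = 0
    for line in _read_lines(pair_table):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"malformed association row: {line!r}")
        m, d = fields
        if m not in m_index:
            raise ValueError(f"unknown miRNA name in pair table: {m!r}")
        if d not in d_index:
            raise ValueError(f"unknown disease name in pair table: {d!r}")
        if values[m_index[m], d_index[d]]:
            n_dupes += 1
        values[m_index[m], d_index[d]] = True
    if n_dupes:
        warnings.warn(f"{n_dupes} duplicate association pair(s) collapsed")

    am = AssociationMatrix(values, mirnas, diseases)
    am.validate()
    return am


def save_associations(
    am: AssociationMatrix,
    pair_table: str | Path,
    mirna_list: str | Path,
    disease_list: str | Path,
) -> None:
    Path(mirna_list).write_text("\n".join(am.mirna_names) + "\n", encoding="utf-8")
    Path(disease_list).write_text("\n".join(am.disease_names) + "\n", encoding="utf-8")
    rows = [
        f"{am.mirna_names[i]}\t{am.disease_names[j]}"
        for i, j in zip(*np.nonzero(am.values))
    ]
    Path(pair_table).write_text("\n".join(rows) + "\n", encoding="utf-8")


def load_dag_forest(dag_file: str | Path) -> DiseaseDagForest:
    """Read per-disease ancestor DAGs from a 3-column edge-list TSV.

    ``disease<TAB>parent<TAB>child`` rows add an edge to that disease's DAG;
    a single-column row declares a disease with no ancestors (singleton DAG).
    """
    forest = DiseaseDagForest()
    edges: dict[str, list[tuple[str, str]]] = {}
    for line in _read_lines(dag_file):
        fields = line.split("\t")
        if len(fields) == 1:
            edges.setdefault(fields[0], [])
        elif len(fields) == 3:
            disease, parent, child = fields
            edges.setdefault(disease, []).append((parent, child))
        else:
            raise ValueError(f"malformed DAG row: {line!r}")
    for disease, edge_list in edges.items():
        forest.add_disease(disease, edge_list)
    forest.validate()
    return forest


def save_dag_forest(forest: DiseaseDagForest, dag_file: str | Path) -> None:
    rows = []
    for disease in forest.diseases:
        g = forest.dags[disease]
        if g.number_of_edges() == 0:
            rows.append(disease)
        for parent, child in sorted(g.edges):
            rows.append(f"{disease}\t{parent}\t{child}")
    Path(dag_file).write_text("\n".join(rows) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# synthetic generators
# ---------------------------------------------------------------------------


def _chain_dag(disease: str, ancestors: list[str]) -> list[tuple[str, str]]:
    """Ancestor chain t_k -> ... -> t_1 -> disease as parent->child edges."""
    nodes = ancestors + [disease]
    return [(nodes[k], nodes[k + 1]) for k in range(len(nodes) - 1)][::-1]


def generate_synthetic(config: SyntheticConfig) -> tuple[AssociationMatrix, DiseaseDagForest]:
    """Deterministic synthetic association matrix plus ancestor forest.

    The association matrix places exactly ``round(density * nm * nd)`` ones
    at uniformly sampled positions, so the realised density matches the
    request for every seed.  Each disease receives an ancestor chain of
    uniform random depth in ``[0, dag_depth]`` drawn without replacement
    from a shared term pool, so some disease pairs share ancestors (nonzero
    off-diagonal semantic similarity) and some share none.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nm, nd = config.n_mirnas, config.n_diseases

    n_ones = max(1, int(round(config.density * nm * nd)))
    flat = rng.choice(nm * nd, size=n_ones, replace=False)
    values = np.zeros(nm * nd, dtype=bool)
    values[flat] = True
    values = values.reshape(nm, nd)

    mirnas = [f"mir-{i:03d}" for i in range(nm)]
    diseases = [f"dis-{j:03d}" for j in range(nd)]
    pool = [f"T{t:03d}" for t in range(config.shared_ancestor_pool)]

    forest = DiseaseDagForest()
    for disease in diseases:
        depth = int(rng.integers(0, config.dag_depth + 1))
        depth = min(depth, len(pool))
        ancestors = list(rng.choice(pool, size=depth, replace=False))
        forest.add_disease(disease, _chain_dag(disease, ancestors))

    am = AssociationMatrix(values, mirnas, diseases)
    am.validate()
    forest.validate()
    return am, forest


def generate_block_synthetic(
    n_mirnas: int = 40,
    n_diseases: int = 25,
    density: float = 0.15,
    n_blocks: int = 5,
    preference: float = 20.0,
    dag_depth: int = 3,
    terms_per_block: int = 4,
    seed: int = 0,
) -> tuple[AssociationMatrix, DiseaseDagForest]:
    """Block-structured fixture: miRNA clusters attach to disease clusters.

    miRNAs and diseases are assigned round-robin to ``n_blocks`` clusters.
    A within-block pair is ``preference`` times more likely to be associated
    than a between-block pair, with the two rates solved so the expected
    overall density equals ``density``.  Each block owns a disjoint ancestor
    term subpool, so semantic similarity is high within a disease block and
    zero across blocks — the structure consistency-projection methods are
    meant to exploit.
    """
    if density <= 0 or density > 1:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    k = n_blocks
    # density = (p_in + (k-1) p_out) / k with p_in = preference * p_out
    p_out = density * k / (preference + k - 1)
    p_in = min(1.0, preference * p_out)

    m_block = np.arange(n_mirnas) % k
    d_block = np.arange(n_diseases) % k
    same = m_block[:, None] == d_block[None, :]
    p = np.where(same, p_in, p_out)
    values = rng.random((n_mirnas, n_diseases)) < p
    if not values.any():  # pathological tiny configuration
        values[0, 0] = True

    mirnas = [f"mir-{i:03d}" for i in range(n_mirnas)]
    diseases = [f"dis-{j:03d}" for j in range(n_diseases)]

    forest = DiseaseDagForest()
    for j, disease in enumerate(diseases):
        block_pool = [f"B{d_block[j]}T{t}" for t in range(terms_per_block)]
        depth = int(rng.integers(1, min(dag_depth, terms_per_block) + 1))
        ancestors = list(rng.choice(block_pool, size=depth, replace=False))
        forest.add_disease(disease, _chain_dag(disease, ancestors))

    am = AssociationMatrix(values, mirnas, diseases)
    am.validate()
    forest.validate()
    return am, forest
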