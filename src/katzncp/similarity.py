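"""Disease, miRNA and kernel similarity matrices.

Four similarity sources feed the heterogeneous network:

* two disease *semantic* similarities over the ancestor DAG forest — the
  hop-discounted scheme (each ancestor contributes ``0.5`` per hop toward
  the disease, best path wins) and the information-content scheme (an
  ancestor term contributes ``-log`` of the fraction of diseases whose DAG
  contains it);
* miRNA *functional* similarity, the best-match average of disease
  similarities between the two miRNAs' associated disease sets;
* Gaussian interaction-profile kernels ``GD``/``GM`` over the columns/rows
  of the association matrix, with bandwidth set to the inverse mean squared
  profile norm.

The integrated matrices ``ID``/``IM`` take the mean of the two
semantic/functional schemes where both entities have that information and
fall back to the Gaussian kernel elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .datasets import AssociationMatrix, DiseaseDagForest

__all__ = [
    "SimilarityMatrix",
    "ContributionMap",
    "wang_contributions",
    "xuan_term_information",
    "xuan_contributions",
    "semantic_similarity",
    "semantic_mask",
    "mirna_functional_similarity",
    "gaussian_profile_kernel",
    "integrate_disease",
    "integrate_mirna",
]

_KINDS = {"DD1", "DD2", "MM1", "MM2", "GD", "GM", "ID", "IM"}


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entity names.

    ``defined`` optionally marks which entries are meaningful: functional
    similarity is undefined (NaN, ``defined=False``) when either miRNA has
    no associated disease, and the integration step uses that mask to fall
    back to the Gaussian kernel.
    """

    values: np.ndarray
    names: list[str]
    kind: str
    defined: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.names = list(self.names)
        if self.kind not in _KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self, atol: float = 1e-12) -> None:
        v = self.values
        if v.shape != (len(self.names), len(self.names)):
            raise ValueError("similarity matrix shape does not match names")
        finite = np.isfinite(v)
        if self.defined is not None and not finite[self.defined].all():
            raise ValueError("non-finite entry marked as defined")
        vv = v[finite]
        if not np.allclose(v, v.T, atol=atol, equal_nan=True):
            raise ValueError(f"{self.kind} matrix not symmetric")
        if vv.size and (vv.min() < -atol or vv.max() > 1 + atol):
            raise ValueError(f"{self.kind} entries outside [0, 1]")


@dataclass
class ContributionMap:
    """Ancestor contributions toward one disease plus their sum DV(d)."""

    disease: str
    contributions: dict[str, float]
    dv: float = field(init=False)

    def __post_init__(self) -> None:
        self.dv = float(sum(self.contributions.values()))


# ---------------------------------------------------------------------------
# semantic similarity over the ancestor forest
# ---------------------------------------------------------------------------


def wang_contributions(forest: DiseaseDagForest, disease: str) -> ContributionMap:
    """Hop-discounted ancestor contributions.

    The disease contributes 1 to itself; any other ancestor term contributes
    half the best contribution among its children inside the disease's own
    DAG, i.e. ``0.5 ** (shortest hop distance to the disease)``.
    Computed by dynamic programming in reverse topological order (children
    before parents), so each node's children are resolved before it.
    """
    g = forest.dags[disease]
    contributions: dict[str, float] = {}
    for node in reversed(list(nx.topological_sort(g))):
        if node == disease:
            contributions[node] = 1.0
        else:
            contributions[node] = max(
                0.5 * contributions[c] for c in g.successors(node)
            )
    return ContributionMap(disease, contributions)


def xuan_term_information(forest: DiseaseDagForest) -> dict[str, float]:
    """Information content of each term: -log(fraction of DAGs containing it)."""
    n = len(forest)
    counts: dict[str, int] = {}
    for d in forest.diseases:
        for term in forest.node_set(d):
            counts[term] = counts.get(term, 0) + 1
    return {term: -np.log(c / n) for term, c in counts.items()}


def xuan_contributions(
    forest: DiseaseDagForest,
    disease: str,
    term_information: dict[str, float] | None = None,
) -> ContributionMap:
    """Information-content ancestor contributions.

    A term present in every disease's DAG carries ``-log 1 = 0`` — no
    discriminative information — which is a legitimate value, not an error.
    ``term_information`` may be passed to share the forest-wide term counts
    across diseases.
    """
    if term_information is None:
        term_information = xuan_term_information(forest)
    contributions = {t: term_information[t] for t in forest.node_set(disease)}
    return ContributionMap(disease, contributions)


def semantic_similarity(
    contribs: dict[str, ContributionMap],
    names: list[str] | None = None,
    kind: str = "DD1",
) -> SimilarityMatrix:
    """Pairwise disease similarity from per-disease contribution maps.

    sim(i, j) = sum over shared ancestor terms of the two contributions,
    divided by DV(i) + DV(j).  The diagonal is 1 whenever DV > 0; a pair
    with DV(i) + DV(j) = 0 (possible only under the information-content
    scheme when every term is universal) gets similarity 0 with a warning.
    """
    if names is None:
        names = list(contribs)
    n = len(names)
    values = np.zeros((n, n))
    warned = False
    for a in range(n):
        ca = contribs[names[a]]
        for b in range(a, n):
            cb = contribs[names[b]]
            denom = ca.dv + cb.dv
            if denom == 0.0:
                if not warned:
                    warnings.warn(
                        "disease pair with zero total semantic value; "
                        "similarity set to 0"
                    )
                    warned = True
                sim = 0.0
            else:
                shared = ca.contributions.keys() & cb.contributions.keys()
                sim = sum(
                    ca.contributions[t] + cb.contributions[t] for t in shared
                ) / denom
            values[a, b] = values[b, a] = sim
    np.fill_diagonal(values, [1.0 if contribs[d].dv > 0 else values[i, i]
                              for i, d in enumerate(names)])
    out = SimilarityMatrix(values, names, kind)
    out.validate(atol=1e-9)
    return out


def semantic_mask(forest: DiseaseDagForest, disease_names: list[str]) -> np.ndarray:
    """True where both diseases possess an ancestor DAG in the forest."""
    has = np.array([d in forest for d in disease_names], dtype=bool)
    return np.outer(has, has)


# ---------------------------------------------------------------------------
# miRNA functional similarity
# ---------------------------------------------------------------------------


def mirna_functional_similarity(
    dd: SimilarityMatrix, md: AssociationMatrix, kind: str = "MM1"
) -> SimilarityMatrix:
    """Best-match average similarity between two miRNAs' disease sets.

    For miRNAs with disease sets ``Di`` and ``Dj``, every disease in one set
    is matched to its most similar disease in the other set and the matched
    similarities are averaged over ``|Di| + |Dj|``.  Entries involving a
    miRNA with no associated disease are undefined: NaN with
    ``defined=False`` (the integration step substitutes the Gaussian
    kernel there), never silently 0.
    """
    if dd.names != md.disease_names:
        raise ValueError("disease similarity and association matrix disagree on names")
    nm = md.nm
    sets = [np.flatnonzero(md.values[i]) for i in range(nm)]
    nonempty = np.array([s.size > 0 for s in sets])
    values = np.full((nm, nm), np.nan)
    ddv = dd.values
    for i in range(nm):
        if not nonempty[i]:
            continue
        for j in range(i, nm):
            if not nonempty[j]:
                continue
            sub = ddv[np.ix_(sets[i], sets[j])]
            num = sub.max(axis=1).sum() + sub.max(axis=0).sum()
            values[i, j] = values[j, i] = num / (sets[i].size + sets[j].size)
    out = SimilarityMatrix(
        values, md.mirna_names, kind, defined=np.outer(nonempty, nonempty)
    )
    out.validate(atol=1e-9)
    return out


# ---------------------------------------------------------------------------
# Gaussian interaction-profile kernels
# ---------------------------------------------------------------------------


def gaussian_profile_kernel(md: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """Gaussian kernel over association profiles.

    ``axis='disease'`` compares columns of MD (profiles over miRNAs),
    ``axis='mirna'`` compares rows.  The bandwidth gamma is the reciprocal
    of the mean squared profile norm, so the kernel adapts to the matrix
    density.  An all-zero matrix leaves gamma undefined and is fatal.
    """
    if axis == "disease":
        profiles = md.values.T.astype(float)
        names, kind = md.disease_names, "GD"
    elif axis == "mirna":
        profiles = md.values.astype(float)
        names, kind = md.mirna_names, "GM"
    else:
        raise ValueError("axis must be 'disease' or 'mirna'")

    mean_sq_norm = (profiles ** 2).sum(axis=1).mean()
    if mean_sq_norm == 0.0:
        raise ValueError("all-zero association matrix: kernel bandwidth undefined")
    gamma = 1.0 / mean_sq_norm

    sq = cdist(profiles, profiles, metric="sqeuclidean")
    values = np.exp(-gamma * sq)
    np.fill_diagonal(values, 1.0)
    out = SimilarityMatrix(values, names, kind)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def _blend(
    s1: SimilarityMatrix,
    s2: SimilarityMatrix,
    kernel: SimilarityMatrix,
    mask: np.ndarray,
    kind: str,
) -> SimilarityMatrix:
    if not (s1.values.shape == s2.values.shape == kernel.values.shape == mask.shape):
        raise ValueError("integration inputs disagree in shape")
    a = np.where(np.isnan(s1.values), 0.0, s1.values)
    b = np.where(np.isnan(s2.values), 0.0, s2.values)
    values = np.where(mask, (a + b) / 2.0, kernel.values)
    np.fill_diagonal(values, 1.0)
    # absorb sub-1e-12 float excursions only; anything larger is a bug upstream
    values = np.clip(values, 0.0, 1.0)
    out = SimilarityMatrix(values, kernel.names, kind)
    out.validate(atol=1e-9)
    return out


def integrate_disease(
    dd1: SimilarityMatrix,
    dd2: SimilarityMatrix,
    gd: SimilarityMatrix,
    semantic_mask: np.ndarray,
) -> SimilarityMatrix:
    """ID: mean of the two semantic schemes where both diseases have a DAG,
    Gaussian kernel elsewhere; unit diagonal."""
    return _blend(dd1, dd2, gd, semantic_mask, "ID")


def integrate_mirna(
    mm1: SimilarityMatrix,
    mm2: SimilarityMatrix,
    gm: SimilarityMatrix,
    functional_mask: np.ndarray | None = None,
) -> SimilarityMatrix:
    """IM: mean of the two functional schemes where defined (both miRNAs
    have at least one association), Gaussian kernel elsewhere."""
    if functional_mask is None:
        if mm1.defined is None:
            raise ValueError("functional mask required when mm1 carries none")
        functional_mask = mm1.defined
    return _blend(mm1, mm2, gm, functional_mask, "IM")
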