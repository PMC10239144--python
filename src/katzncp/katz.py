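"""KATZ walk scoring on the heterogeneous miRNA-disease network.

The integrated miRNA similarity IM, the association matrix MD and the
integrated disease similarity ID are assembled into one symmetric adjacency

    A = [[IM,   MD],
         [MD^T, ID]]

and every node pair is scored by the damped count of walks of all lengths,
``sum_{l>=1} beta^l A^l = (I - beta A)^{-1} - I``.  The damping factor is
parameterised through ``alpha`` as ``beta = alpha / eigA``, where ``eigA``
is the largest eigenvalue of A; since A is symmetric, eigA equals its
spectral norm and any ``alpha < 1`` guarantees convergence of the series.
The estimated association scores MD_e are the upper-right ``nm x nd`` block
of the scored matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datasets import AssociationMatrix
from .similarity import SimilarityMatrix

__all__ = [
    "HeteroAdjacency",
    "ScoreMatrix",
    "DEFAULT_ALPHA",
    "build_adjacency",
    "katz_scores",
    "extract_estimated",
]

#: damping weight selected on the benchmark data (LOOCV grid over alpha)
DEFAULT_ALPHA = 0.02


@dataclass
class HeteroAdjacency:
    """Symmetric block adjacency of the heterogeneous network."""

    values: np.ndarray
    nm: int
    nd: int
    eig_a: float
    alpha: float

    @property
    def beta(self) -> float:
        return self.alpha / self.eig_a


@dataclass
class ScoreMatrix:
    """Real-valued miRNA x disease score matrix at a given pipeline stage."""

    values: np.ndarray
    mirna_names: list[str]
    disease_names: list[str]
    stage: str  # estimated | mirna_projection | disease_projection | final

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("score matrix contains non-finite entries")


def build_adjacency(
    im: SimilarityMatrix,
    id_: SimilarityMatrix,
    md: AssociationMatrix,
    alpha: float = DEFAULT_ALPHA,
) -> HeteroAdjacency:
    """Assemble the block adjacency and its spectral quantities.

    ``alpha`` must lie in [0, 1): at 1 or beyond the walk series diverges.
    ``eigA`` is the largest (signed) eigenvalue; for these nonnegative
    symmetric blocks it coincides with the spectral radius.
    """
    nm, nd = md.nm, md.nd
    if im.n != nm or id_.n != nd:
        raise ValueError("similarity block sizes do not match the association matrix")
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must lie in [0, 1) for the walk series to converge")
    mdv = md.values.astype(float)
    a = np.block([[im.values, mdv], [mdv.T, id_.values]])
    eig_a = float(scipy.linalg.eigvalsh(a, subset_by_index=(a.shape[0] - 1,) * 2)[0])
    if eig_a <= 0.0:
        raise ValueError("largest eigenvalue of the adjacency is not positive")
    return HeteroAdjacency(a, nm, nd, eig_a, alpha)


def katz_scores(adj: HeteroAdjacency) -> np.ndarray:
    """Closed-form walk scores ``(I - beta A)^{-1} - I``.

    Solved as a linear system rather than by explicit inversion.  The result
    is symmetrised to remove solver round-off (A is symmetric, so the exact
    score matrix is too).
    """
    n = adj.values.shape[0]
    m = np.eye(n) - adj.beta * adj.values
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"(I - beta*A) numerically singular (condition number {cond:.3e})"
        )
    s = scipy.linalg.solve(m, np.eye(n), assume_a="sym") - np.eye(n)
    return (s + s.T) / 2.0


def extract_estimated(
    s: np.ndarray, md: AssociationMatrix
) -> ScoreMatrix:
    """Upper-right nm x nd block of the scored network: estimated MD_e."""
    nm, nd = md.nm, md.nd
    if s.shape != (nm + nd, nm + nd):
        raise ValueError("scored matrix has wrong shape for the given blocks")
    return ScoreMatrix(
        s[:nm, nm:], md.mirna_names, md.disease_names, stage="estimated"
    )
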