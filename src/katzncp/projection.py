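"""Network consistency projection refinement of the estimated scores.

The estimated score matrix MD_e is projected onto the miRNA similarity
space and the disease similarity space:

    MD_pm(i, j) = IM(i, :) . MD_e(:, j) / ||MD_e(:, j)||_2
    MD_pd(i, j) = MD_e(i, :) . ID(:, j) / ||MD_e(i, :)||_2

i.e. the scalar projection of a similarity profile onto the corresponding
estimated-score vector.  Both projections are oriented miRNA x disease, so
the final score is their plain elementwise mean.  Columns/rows of MD_e with
zero norm yield zero projections (entities with no signal rank last
deterministically) instead of NaN.
"""

from __future__ import annotations

import numpy as np

from .katz import ScoreMatrix
from .similarity import SimilarityMatrix

__all__ = ["mirna_space_projection", "disease_space_projection", "combine"]


def _safe_divide(num: np.ndarray, denom: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num)
    np.divide(num, denom, out=out, where=denom > 0)
    return out


def mirna_space_projection(im: SimilarityMatrix, md_e: ScoreMatrix) -> ScoreMatrix:
    """Project each miRNA's similarity profile onto each disease's score column."""
    if im.n != md_e.values.shape[0]:
        raise ValueError("miRNA similarity size does not match the score matrix")
    col_norms = np.linalg.norm(md_e.values, axis=0)
    values = _safe_divide(im.values @ md_e.values, col_norms[None, :])
    return ScoreMatrix(values, md_e.mirna_names, md_e.disease_names,
                       stage="mirna_projection")


def disease_space_projection(id_: SimilarityMatrix, md_e: ScoreMatrix) -> ScoreMatrix:
    """Project each disease's similarity profile onto each miRNA's score row."""
    if id_.n != md_e.values.shape[1]:
        raise ValueError("disease similarity size does not match the score matrix")
    row_norms = np.linalg.norm(md_e.values, axis=1)
    values = _safe_divide(md_e.values @ id_.values, row_norms[:, None])
    return ScoreMatrix(values, md_e.mirna_names, md_e.disease_names,
                       stage="disease_projection")


def combine(md_pm: ScoreMatrix, md_pd: ScoreMatrix) -> ScoreMatrix:
    """Final prediction scores: mean of the two space projections."""
    if md_pm.values.shape != md_pd.values.shape:
        raise ValueError("projection score matrices disagree in shape")
    return ScoreMatrix(
        (md_pm.values + md_pd.values) / 2.0,
        md_pm.mirna_names,
        md_pm.disease_names,
        stage="final",
    )
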