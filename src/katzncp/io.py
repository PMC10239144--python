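"""TSV dumps of similarity/score matrices and ranked prediction tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .katz import ScoreMatrix

__all__ = ["write_matrix_tsv", "read_matrix_tsv", "export_ranked_predictions"]


def write_matrix_tsv(
    values: np.ndarray,
    row_names: list[str],
    col_names: list[str],
    path: str | Path,
) -> None:
    """Full-precision TSV dump with a header row and a leading name column."""
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=row_names, columns=col_names)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def export_ranked_predictions(
    scores: ScoreMatrix,
    path: str | Path,
    known: np.ndarray | None = None,
    top: int | None = None,
) -> pd.DataFrame:
    """Per-disease candidate ranking: disease, rank, miRNA, score.

    ``known`` (Boolean miRNA x disease mask) excludes already-known
    associations from the candidate list; ``top`` truncates each disease's
    list.  Returns the table and writes it as TSV.
    """
    rows = []
    for j, disease in enumerate(scores.disease_names):
        col = scores.values[:, j]
        candidates = np.arange(col.size)
        if known is not None:
            candidates = candidates[~known[:, j]]
        order = candidates[np.argsort(-col[candidates], kind="stable")]
        if top is not None:
            order = order[:top]
        for rank, i in enumerate(order, start=1):
            rows.append(
                {"disease": disease, "rank": rank,
                 "mirna": scores.mirna_names[i], "score": col[i]}
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
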