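"""Housekeeping normalization of gene-level microarray matrices.

The input is an already-summarized, log2-scale expression matrix (the
RMA convention), one row per gene — probeset-to-gene collapsing happens
upstream.  To make array values directly comparable to the qPCR Ct
scores, each sample column is referenced to the mean of the same
housekeeping genes used on the qPCR side:

    score(g, s) = value(g, s) - mean_hk value(hk, s)

which, like the delta-Ct score, is invariant to any constant shift of a
sample column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .matrix import ScoreMatrix, read_matrix_tsv, write_matrix_tsv
from .qpcr import DEFAULT_HOUSEKEEPING

__all__ = ["read_expression_matrix", "write_expression_matrix", "hk_normalize_array"]


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log2 expression matrix (TSV dialect).

    Duplicate gene rows, ragged rows and non-numeric cells are parse
    errors naming the offender.
    """
    _, values = read_matrix_tsv(path)
    return values


def write_expression_matrix(values: pd.DataFrame, path: str | Path) -> None:
    write_matrix_tsv(values, path)


def hk_normalize_array(
    matrix: pd.DataFrame, hk_genes: Sequence[str] = DEFAULT_HOUSEKEEPING
) -> ScoreMatrix:
    """Reference each sample to its housekeeping mean; drop housekeeping rows.

    No missing entries are introduced: arrays report every probed gene.
    """
    missing = [g for g in hk_genes if g not in matrix.index]
    if missing:
        raise ValidationError(f"housekeeping gene(s) absent from matrix: {missing}")
    control = matrix.loc[list(hk_genes)].mean(axis=0)
    scored = matrix.drop(index=list(hk_genes)).sub(control, axis=1)
    return ScoreMatrix(scored, platform="array", housekeeping=tuple(hk_genes))
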