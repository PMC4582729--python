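"""Platform-agnostic expression score matrices and their on-disk dialect.

A :class:`ScoreMatrix` holds housekeeping-normalized expression scores
(genes x samples) for one measurement platform.  Scores rise with
expression on both platforms: for qPCR they are Ct scores
(housekeeping average minus target Ct), for arrays they are log2
intensities minus the housekeeping average.  Missing entries (``NaN``)
mark genes flagged unexpressed in a given assay.

The file dialect is tab-separated text: optional ``# key=value`` comment
lines, then a header row whose first column is ``gene_id`` and whose
remaining columns are sample identifiers; missing values are written
``NA``.  Floats are written with Python's shortest round-trip
representation, so write/read cycles are lossless.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

PLATFORMS = ("qpcr", "array")

__all__ = [
    "PLATFORMS",
    "ScoreMatrix",
    "read_commented_tsv",
    "write_commented_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_scores",
    "write_scores",
]


@dataclass(frozen=True)
class ScoreMatrix:
    """Genes x samples matrix of housekeeping-normalized expression scores.

    Parameters
    ----------
    values
        Float DataFrame indexed by gene identifier, one column per sample.
        ``NaN`` entries mark unexpressed (dropped-out) measurements.
    platform
        ``"qpcr"`` or ``"array"``.
    housekeeping
        The housekeeping genes consumed by the normalization.  They are
        controls, not targets, so they must not appear among the rows.
    """

    values: pd.DataFrame
    platform: str
    housekeeping: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        object.__setattr__(self, "housekeeping", tuple(self.housekeeping))
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene rows: {dups}")
        leaked = sorted(set(self.housekeeping) & set(self.values.index))
        if leaked:
            raise ValidationError(
                f"housekeeping genes must not appear as score rows: {leaked}"
            )
        object.__setattr__(self, "values", self.values.astype(float))

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_samples(self, samples: list[str]) -> "ScoreMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return ScoreMatrix(self.values[samples], self.platform, self.housekeeping)


# ---------------------------------------------------------------------------
# dialect helpers


def read_commented_tsv(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    """Read a TSV with leading ``# key=value`` metadata lines.

    Returns the metadata mapping and the data as a DataFrame of strings
    (no type coercion; callers validate their own columns).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, val = stripped.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            body_lines.append(line)
    if not body_lines or not body_lines[0].strip():
        raise ParseError(f"{path}: missing header row")
    try:
        df = pd.read_csv(
            io.StringIO("".join(body_lines)),
            sep="\t",
            dtype=str,
            na_values=[],
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc
    return meta, df


def write_commented_tsv(
    df: pd.DataFrame, path: str | Path, meta: dict[str, str] | None = None
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def parse_float_column(
    raw: "pd.Series", path: Path, col: str, row_labels: "pd.Series"
) -> np.ndarray:
    """Parse a string column to float64 with correctly rounded conversion
    (`float()` round-trips shortest-repr output exactly; pandas' fast
    parser can be one ulp off).  ``NA`` means missing; anything else
    non-numeric is a parse error naming the row."""
    out = np.empty(len(raw))
    for i, s in enumerate(raw):
        s = str(s).strip()
        if s == "NA":
            out[i] = np.nan
            continue
        try:
            out[i] = float(s)
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric value {s!r} for {row_labels.iloc[i]!r} "
                f"in column {col!r}"
            ) from None
    return out


def read_matrix_tsv(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    """Read an expression-matrix file; returns (metadata, genes x samples floats).

    Duplicate gene rows are an error: the matrix must already be gene-level.
    """
    path = Path(path)
    meta, raw = read_commented_tsv(path)
    if raw.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id', got {raw.columns[0]!r}")
    genes = raw["gene_id"]
    dup = genes[genes.duplicated()].unique().tolist()
    if dup:
        raise ParseError(f"{path}: duplicate gene rows: {dup}")
    body = raw.drop(columns="gene_id")
    values = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for col in body.columns:
        values[col] = parse_float_column(body[col], path, col, genes)
    return meta, values


def write_matrix_tsv(
    values: pd.DataFrame, path: str | Path, meta: dict[str, str] | None = None
) -> None:
    df = values.copy()
    df.insert(0, "gene_id", df.index)
    write_commented_tsv(df, path, meta)


def write_scores(scores: ScoreMatrix, path: str | Path) -> None:
    """Persist a ScoreMatrix; platform and housekeeping set go in the header."""
    write_matrix_tsv(
        scores.values,
        path,
        {"platform": scores.platform, "housekeeping": ",".join(scores.housekeeping)},
    )


def read_scores(path: str | Path) -> ScoreMatrix:
    meta, values = read_matrix_tsv(path)
    if "platform" not in meta:
        raise ParseError(f"{path}: missing '# platform=' header")
    hk = tuple(g for g in meta.get("housekeeping", "").split(",") if g)
    return ScoreMatrix(values, meta["platform"], hk)
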