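"""Per-probe scale-and-center calibration.

Each platform's probes have their own location and scale (array probe
affinity vs. qPCR assay efficiency/intercept), so scores from the two
platforms are not directly interchangeable even after housekeeping
normalization.  The calibration step absorbs those probe-specific
differences: a reference cohort supplies, per gene, the observed score
mean and standard deviation, and new samples are mapped to z-values

    z(g, s) = (score(g, s) - mean_g) / sd_g

that live on the mean-zero, SD-one scale the pathway indexes consume.
A table built from one platform's scores applies only to that platform —
cross-application is refused, because the probe constants it absorbs are
platform-specific.

Missing entries (unexpressed genes) are excluded from the mean/SD
estimates and propagate unchanged through the transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ParseError, ValidationError
from .matrix import ScoreMatrix, parse_float_column, read_commented_tsv, write_commented_tsv

__all__ = [
    "CalibrationTable",
    "build_calibration_table",
    "apply_calibration",
    "read_calibration_table",
    "write_calibration_table",
]


@dataclass(frozen=True)
class CalibrationTable:
    """Per-gene (mean, sd) of a reference cohort's scores.

    ``table`` is indexed by gene with float columns ``mean`` and ``sd``
    (sd strictly positive).  ``platform`` records which platform's scores
    the table was built from; ``provenance`` is a free-form note
    identifying the reference cohort.
    """

    table: pd.DataFrame
    platform: str | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.table
        if list(df.columns) != ["mean", "sd"]:
            df = df[["mean", "sd"]]
        df = df.astype(float)
        bad = df.index[~(df["sd"] > 0)].tolist()
        if bad:
            raise ValidationError(f"non-positive sd for gene(s): {bad}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate calibration entries: {dup}")
        object.__setattr__(self, "table", df)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def build_calibration_table(
    reference: ScoreMatrix, provenance: str = ""
) -> CalibrationTable:
    """Estimate per-gene mean and sample SD (n-1 denominator) from a
    reference cohort, skipping missing entries.

    Every gene needs at least two non-missing observations and nonzero
    variance; offenders are named.
    """
    values = reference.values
    n_obs = values.notna().sum(axis=1)
    thin = n_obs.index[n_obs < 2].tolist()
    if thin:
        raise ValidationError(
            f"gene(s) with fewer than 2 reference observations: {thin}"
        )
    mean = values.mean(axis=1, skipna=True)
    sd = values.std(axis=1, ddof=1, skipna=True)
    flat = sd.index[~(sd > 0)].tolist()
    if flat:
        raise ValidationError(f"zero-variance reference gene(s): {flat}")
    table = pd.DataFrame({"mean": mean, "sd": sd})
    table.index.name = "gene_id"
    return CalibrationTable(table, platform=reference.platform, provenance=provenance)


def apply_calibration(scores: ScoreMatrix, calib: CalibrationTable) -> ScoreMatrix:
    """Scale and center scores into z-values; missing stays missing.

    Refuses a platform mismatch: probe constants absorbed by the table are
    platform-specific.
    """
    if calib.platform is not None and calib.platform != scores.platform:
        raise ValidationError(
            f"calibration built from {calib.platform!r} scores cannot be "
            f"applied to {scores.platform!r} scores"
        )
    observed = scores.values.index[scores.values.notna().any(axis=1)]
    missing = [g for g in observed if g not in calib.table.index]
    if missing:
        raise ValidationError(f"gene(s) missing from calibration table: {missing}")
    genes = [g for g in scores.values.index if g in calib.table.index]
    values = scores.values.loc[genes]
    z = values.sub(calib.table.loc[genes, "mean"], axis=0).div(
        calib.table.loc[genes, "sd"], axis=0
    )
    return ScoreMatrix(z, platform=scores.platform, housekeeping=scores.housekeeping)


def write_calibration_table(calib: CalibrationTable, path: str | Path) -> None:
    df = calib.table.reset_index()
    df.columns = ["gene_id", "mean", "sd"]
    meta = {"provenance": calib.provenance}
    if calib.platform is not None:
        meta["platform"] = calib.platform
    write_commented_tsv(df, path, meta)


def read_calibration_table(path: str | Path) -> CalibrationTable:
    path = Path(path)
    meta, df = read_commented_tsv(path)
    for col in ("gene_id", "mean", "sd"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    table = pd.DataFrame(
        {
            "mean": parse_float_column(df["mean"], path, "mean", df["gene_id"]),
            "sd": parse_float_column(df["sd"], path, "sd", df["gene_id"]),
        },
        index=pd.Index(df["gene_id"], name="gene_id"),
    )
    return CalibrationTable(
        table, platform=meta.get("platform"), provenance=meta.get("provenance", "")
    )
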