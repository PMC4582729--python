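"""qPCR Ct-table ingestion and housekeeping (delta-Ct) normalization.

A TaqMan-style assay reports, per gene, the cycle threshold Ct: the PCR
cycle at which amplification crosses detection.  One cycle corresponds to
one doubling of template, so Ct falls by one for every doubling of input
expression.  Genes whose Ct reaches the detection threshold (34 cycles by
default, inclusive) are flagged *unexpressed* for that assay and excluded
downstream — the raw Ct is retained so the threshold policy stays
adjustable.

Normalization references every target to the arithmetic mean Ct of a set
of stably expressed housekeeping genes (GAPDH, HPRT1, GUSB) measured in
the same assay:

    score(g, s) = mean_hk Ct(hk, s) - Ct(g, s)

The subtraction is oriented so the score *rises* with expression, putting
qPCR on the same footing as log-scale array intensities.  Because the
housekeeping average is taken within the assay, any constant per-sample
cycle offset (loading, efficiency) cancels exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, QCError, ValidationError
from .matrix import ScoreMatrix, read_commented_tsv, write_commented_tsv

DEFAULT_HOUSEKEEPING = ("GAPDH", "HPRT1", "GUSB")
DEFAULT_DETECTION_THRESHOLD = 34.0

__all__ = [
    "DEFAULT_HOUSEKEEPING",
    "DEFAULT_DETECTION_THRESHOLD",
    "CtTable",
    "read_ct_table",
    "write_ct_table",
    "flag_unexpressed",
    "housekeeping_average",
    "ct_score",
    "dropout_summary",
]


@dataclass(frozen=True)
class CtTable:
    """One qPCR assay: per-gene Ct values for a single sample.

    ``unexpressed`` lists genes whose Ct met the detection threshold; they
    keep their raw measurement but are treated as missing downstream.
    ``metadata`` carries free-form assay annotations (preservation method,
    RNA quality indicator, ...) that the pipeline passes through untouched.
    """

    sample_id: str
    measurements: Mapping[str, float]
    unexpressed: frozenset[str] = field(default=frozenset())
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", dict(self.measurements))
        object.__setattr__(self, "unexpressed", frozenset(self.unexpressed))
        object.__setattr__(self, "metadata", dict(self.metadata))
        stray = self.unexpressed - set(self.measurements)
        if stray:
            raise ValidationError(
                f"sample {self.sample_id}: unexpressed genes without a "
                f"measurement: {sorted(stray)}"
            )
        for gene, ct in self.measurements.items():
            if not math.isfinite(ct) or ct <= 0:
                raise ValidationError(
                    f"sample {self.sample_id}: Ct for {gene} must be a finite "
                    f"positive number of cycles, got {ct!r}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.measurements)

    def __len__(self) -> int:
        return len(self.measurements)


def read_ct_table(path: str | Path, sample_id: str | None = None) -> CtTable:
    """Read one Ct table (TSV columns ``gene_id``, ``ct``).

    ``# key=value`` comment lines become metadata; a ``sample_id`` metadata
    entry names the sample, else the file stem is used.  No detection
    threshold is applied here — see :func:`flag_unexpressed`.
    """
    path = Path(path)
    meta, df = read_commented_tsv(path)
    for col in ("gene_id", "ct"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    measurements: dict[str, float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gene = str(getattr(row, "gene_id")).strip()
        raw = str(getattr(row, "ct")).strip()
        try:
            ct = float(raw)
        except ValueError:
            raise ParseError(
                f"{path}, row {i}: non-numeric ct value {raw!r} for gene {gene!r}"
            ) from None
        if gene in measurements:
            raise ParseError(f"{path}, row {i}: duplicate gene {gene!r}")
        measurements[gene] = ct
    sid = sample_id or meta.pop("sample_id", None) or path.stem
    return CtTable(sample_id=sid, measurements=measurements, metadata=meta)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    """Write a Ct table in the dialect read_ct_table expects (round-trips).

    The unexpressed set is not written: it is re-derivable from the raw Ct
    values and the threshold, which downstream code re-applies.
    """
    meta = {"sample_id": table.sample_id, **{k: str(v) for k, v in table.metadata.items()}}
    df = pd.DataFrame(
        {"gene_id": list(table.measurements), "ct": list(table.measurements.values())}
    )
    write_commented_tsv(df, path, meta)


def flag_unexpressed(
    table: CtTable,
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
    inclusive: bool = True,
) -> CtTable:
    """Flag genes at or beyond the detection threshold as unexpressed.

    With ``inclusive`` (default) a Ct of exactly ``threshold`` cycles is
    unexpressed; with ``inclusive=False`` only strictly larger Ct is.
    Measurements are left untouched.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    if inclusive:
        flagged = {g for g, ct in table.measurements.items() if ct >= threshold}
    else:
        flagged = {g for g, ct in table.measurements.items() if ct > threshold}
    return replace(table, unexpressed=frozenset(flagged))


def housekeeping_average(table: CtTable, hk_genes: Sequence[str]) -> float:
    """Arithmetic mean Ct of the housekeeping genes — the assay's endogenous
    control.

    Raises
    ------
    ValidationError
        A housekeeping gene was not measured at all.
    QCError
        A housekeeping gene was measured but flagged unexpressed; the whole
        sample fails QC, since its control baseline is unusable.
    """
    if not hk_genes:
        raise ValidationError("housekeeping gene list is empty")
    missing = [g for g in hk_genes if g not in table.measurements]
    if missing:
        raise ValidationError(
            f"sample {table.sample_id}: housekeeping gene(s) not measured: {missing}"
        )
    dead = [g for g in hk_genes if g in table.unexpressed]
    if dead:
        raise QCError(
            f"sample {table.sample_id} failed QC: housekeeping gene(s) "
            f"undetected: {dead}"
        )
    return float(np.mean([table.measurements[g] for g in hk_genes]))


def ct_score(
    tables: Iterable[CtTable], hk_genes: Sequence[str] = DEFAULT_HOUSEKEEPING
) -> ScoreMatrix:
    """Convert assays to a genes x samples matrix of Ct scores.

    score = housekeeping mean - target Ct, so more expression (fewer
    cycles) gives a higher score.  Unexpressed targets become missing
    entries; housekeeping genes are consumed, not scored.
    """
    tables = list(tables)
    columns: dict[str, dict[str, float]] = {}
    gene_order: list[str] = []
    seen = set()
    for table in tables:
        if table.sample_id in columns:
            raise ValidationError(f"duplicate sample id {table.sample_id!r}")
        control = housekeeping_average(table, hk_genes)
        col: dict[str, float] = {}
        for gene, ct in table.measurements.items():
            if gene in hk_genes:
                continue
            if gene not in seen:
                seen.add(gene)
                gene_order.append(gene)
            col[gene] = np.nan if gene in table.unexpressed else control - ct
        columns[table.sample_id] = col
    values = pd.DataFrame(
        {sid: pd.Series(col) for sid, col in columns.items()},
        index=pd.Index(gene_order, name="gene_id"),
        dtype=float,
    )
    return ScoreMatrix(values, platform="qpcr", housekeeping=tuple(hk_genes))


def dropout_summary(tables: Iterable[CtTable]) -> pd.DataFrame:
    """Per-gene detection accounting across a collection of assays.

    Returns a DataFrame indexed by gene with columns ``n_assays`` (assays
    measuring the gene), ``n_unexpressed`` (assays flagging it) and
    ``fraction``.  Assumes the detection threshold has already been
    applied to each table.
    """
    counts: dict[str, list[int]] = {}
    order: list[str] = []
    for table in tables:
        for gene in table.measurements:
            if gene not in counts:
                counts[gene] = [0, 0]
                order.append(gene)
            counts[gene][0] += 1
            if gene in table.unexpressed:
                counts[gene][1] += 1
    if not order:
        return pd.DataFrame(
            columns=["n_assays", "n_unexpressed", "fraction"],
            index=pd.Index([], name="gene_id"),
        )
    df = pd.DataFrame(
        {
            "n_assays": [counts[g][0] for g in order],
            "n_unexpressed": [counts[g][1] for g in order],
        },
        index=pd.Index(order, name="gene_id"),
    )
    df["fraction"] = df["n_unexpressed"] / df["n_assays"]
    return df
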