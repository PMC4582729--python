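"""Pathway-level expression indexes and reference-cohort placement.

The panel's genes are organized into pathways; a sample's *pathway
index* is the unweighted mean of its calibrated z-values over the
pathway's member genes that were actually detected — genes flagged
unexpressed in that assay are excluded from both numerator and
denominator, so a dropout shrinks the denominator instead of dragging
the index down.  A pathway with no detected members has no index (it is
flagged absent, not scored zero).

To interpret a new sample, its pathway indexes are placed within a
reference cohort's index distributions (normal model by default, fitted
mean and SD per pathway; an empirical-percentile variant is available).
A one-sample Kolmogorov–Smirnov test against the standard normal
formalizes the question of whether a batch of mapped samples sits
without bias inside the reference distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ParseError, ValidationError
from .matrix import ScoreMatrix, read_commented_tsv, write_commented_tsv

__all__ = [
    "PathwayMap",
    "default_pathway_map",
    "read_pathway_map",
    "write_pathway_map",
    "PathwayProfile",
    "pathway_index",
    "profiles_to_frame",
    "ReferenceDistribution",
    "build_reference_distribution",
    "map_to_reference",
    "bias_test",
]


@dataclass(frozen=True)
class PathwayMap:
    """Ordered mapping pathway name -> member gene identifiers.

    A gene may belong to several pathways; no pathway may be empty.
    """

    pathways: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for name, members in self.pathways.items():
            members = tuple(members)
            if not members:
                raise ValidationError(f"pathway {name!r} has no member genes")
            if len(set(members)) != len(members):
                dup = sorted({g for g in members if members.count(g) > 1})
                warnings.warn(
                    f"pathway {name!r}: duplicate member(s) {dup} collapsed",
                    stacklevel=2,
                )
                deduped = []
                for g in members:
                    if g not in deduped:
                        deduped.append(g)
                members = tuple(deduped)
            clean[name] = members
        object.__setattr__(self, "pathways", clean)

    @property
    def names(self) -> list[str]:
        return list(self.pathways)

    @property
    def genes(self) -> list[str]:
        """All member genes, first-appearance order, deduplicated."""
        seen: list[str] = []
        for members in self.pathways.values():
            for g in members:
                if g not in seen:
                    seen.append(g)
        return seen

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.pathways.items()}

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.pathways[name]


_DEFAULT_LAYOUT: tuple[tuple[str, int, tuple[str, ...]], ...] = (
    ("wnt", 12, ("WNT16", "WNT3")),
    ("pi3k_akt", 11, ()),
    ("rtk_ras", 10, ("PLA2G2D",)),
    ("notch", 10, ()),
    ("hedgehog", 9, ("CACNG1",)),
    ("cell_cycle", 9, ()),
    ("apoptosis", 9, ()),
    ("dna_repair", 8, ("DNTT",)),
    ("tgf_beta", 7, ()),
    ("neurotrophin", 6, ()),
)


def default_pathway_map() -> PathwayMap:
    """Synthetic stand-in gene panel: 10 pathways, 91 genes.

    Emulates the structure of a curated ovarian-carcinoma risk panel
    (nine core cancer pathways plus a six-gene neurotrophin set) without
    reproducing any published membership list: apart from a handful of
    real gene symbols used as anchors (WNT16, WNT3, DNTT, PLA2G2D,
    CACNG1), member identifiers are synthetic placeholders of the form
    ``<PATHWAY>_Gnn``.
    """
    pathways: dict[str, tuple[str, ...]] = {}
    for name, size, anchors in _DEFAULT_LAYOUT:
        members = list(anchors)
        i = 1
        while len(members) < size:
            members.append(f"{name.upper()}_G{i:02d}")
            i += 1
        pathways[name] = tuple(members)
    return PathwayMap(pathways)


def read_pathway_map(path: str | Path) -> PathwayMap:
    """Read a two-column TSV (``pathway``, ``gene_id``), order-preserving.

    Duplicate (pathway, gene) rows are collapsed with a warning.
    """
    path = Path(path)
    _, df = read_commented_tsv(path)
    for col in ("pathway", "gene_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    pathways: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        name = str(row.pathway).strip()
        gene = str(row.gene_id).strip()
        if not name or not gene:
            raise ParseError(f"{path}: blank pathway or gene identifier")
        pathways.setdefault(name, []).append(gene)
    if not pathways:
        raise ParseError(f"{path}: no pathway rows")
    return PathwayMap({name: tuple(members) for name, members in pathways.items()})


def write_pathway_map(pmap: PathwayMap, path: str | Path) -> None:
    rows = [
        {"pathway": name, "gene_id": gene}
        for name, members in pmap.pathways.items()
        for gene in members
    ]
    write_commented_tsv(pd.DataFrame(rows, columns=["pathway", "gene_id"]), path)


@dataclass(frozen=True)
class PathwayProfile:
    """Per-sample pathway indexes with dropout bookkeeping.

    ``table`` is indexed by pathway with columns ``index`` (NaN when no
    member was detected), ``n_expressed`` and ``n_members``.
    """

    sample_id: str
    table: pd.DataFrame

    @property
    def absent(self) -> list[str]:
        """Pathways whose every member gene dropped out in this sample."""
        return self.table.index[self.table["n_expressed"] == 0].tolist()

    def index_of(self, pathway: str) -> float:
        return float(self.table.loc[pathway, "index"])


def pathway_index(
    z: ScoreMatrix,
    pmap: PathwayMap,
    aggregator: Callable[[np.ndarray], float] = np.mean,
) -> list[PathwayProfile]:
    """Aggregate calibrated z-values into per-sample pathway indexes.

    The aggregator (unweighted mean by default, pluggable) is applied to
    each pathway's *detected* member values only; the denominator is the
    number of detected members, per sample.  Expects calibrated
    (z-scale) input.

    Raises
    ------
    ConfigError
        The map names genes the matrix does not contain.
    """
    missing = [g for g in pmap.genes if g not in z.values.index]
    if missing:
        raise ConfigError(f"pathway map gene(s) absent from matrix: {missing}")
    profiles = []
    for sample in z.samples:
        col = z.values[sample]
        rows = {}
        for name, members in pmap.pathways.items():
            vals = col.loc[list(members)].to_numpy(dtype=float)
            observed = vals[~np.isnan(vals)]
            rows[name] = {
                "index": float(aggregator(observed)) if observed.size else np.nan,
                "n_expressed": int(observed.size),
                "n_members": len(members),
            }
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.index.name = "pathway"
        table = table.astype({"n_expressed": int, "n_members": int})
        profiles.append(PathwayProfile(sample_id=sample, table=table))
    return profiles


def profiles_to_frame(profiles: Iterable[PathwayProfile]) -> pd.DataFrame:
    """Long-format view: one row per (sample, pathway)."""
    rows = []
    for p in profiles:
        for pathway, rec in p.table.iterrows():
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "pathway": pathway,
                    "index": rec["index"],
                    "n_expressed": int(rec["n_expressed"]),
                    "n_members": int(rec["n_members"]),
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "pathway", "index", "n_expressed", "n_members"]
    )


@dataclass(frozen=True)
class ReferenceDistribution:
    """Per-pathway normal fit (mean, sd) of a reference cohort's indexes.

    When built with ``keep_values=True`` the raw reference index values
    are retained so placements can fall back to empirical percentiles.
    """

    table: pd.DataFrame
    reference_values: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        bad = self.table.index[~(self.table["sd"] > 0)].tolist()
        if bad:
            raise ValidationError(f"non-positive reference sd for pathway(s): {bad}")

    @property
    def pathways(self) -> list[str]:
        return list(self.table.index)


def build_reference_distribution(
    z_reference: ScoreMatrix, pmap: PathwayMap, keep_values: bool = False
) -> ReferenceDistribution:
    """Fit a normal (mean, sample SD) to each pathway's reference indexes.

    Needs at least 3 reference samples and nonzero index variance per
    pathway.
    """
    if len(z_reference.samples) < 3:
        raise ValidationError(
            f"reference cohort needs >= 3 samples, got {len(z_reference.samples)}"
        )
    profiles = pathway_index(z_reference, pmap)
    wide = pd.DataFrame(
        {p.sample_id: p.table["index"] for p in profiles}
    )  # pathways x samples
    mean = wide.mean(axis=1, skipna=True)
    sd = wide.std(axis=1, ddof=1, skipna=True)
    flat = sd.index[~(sd > 0)].tolist()
    if flat:
        raise ValidationError(f"zero-variance reference pathway(s): {flat}")
    table = pd.DataFrame({"mean": mean, "sd": sd})
    table.index.name = "pathway"
    return ReferenceDistribution(
        table, reference_values=wide if keep_values else None
    )


def map_to_reference(
    profile: PathwayProfile,
    ref: ReferenceDistribution,
    method: str = "normal",
) -> pd.DataFrame:
    """Place one sample's pathway indexes within the reference distributions.

    Returns a DataFrame indexed by pathway with columns ``index``,
    ``z`` (position in reference SD units) and ``percentile``.  With
    ``method="normal"`` the percentile is Phi(z)*100; ``"empirical"``
    uses the reference cohort's raw index values (requires a
    distribution built with ``keep_values=True``).  Pathways absent in
    the sample (all members dropped out) are skipped with a warning.
    """
    if method not in ("normal", "empirical"):
        raise ValidationError(f"unknown placement method {method!r}")
    if method == "empirical" and ref.reference_values is None:
        raise ValidationError(
            "empirical placement requires a reference built with keep_values=True"
        )
    rows = {}
    for pathway, rec in profile.table.iterrows():
        if rec["n_expressed"] == 0:
            warnings.warn(
                f"sample {profile.sample_id}: pathway {pathway!r} has no "
                "detected members; skipped",
                stacklevel=2,
            )
            continue
        if pathway not in ref.table.index:
            raise ValidationError(f"pathway {pathway!r} missing from reference")
        mu = ref.table.loc[pathway, "mean"]
        sigma = ref.table.loc[pathway, "sd"]
        zpos = (rec["index"] - mu) / sigma
        if method == "normal":
            pct = float(stats.norm.cdf(zpos) * 100.0)
        else:
            pool = ref.reference_values.loc[pathway].dropna().to_numpy()
            pct = float(
                stats.percentileofscore(pool, rec["index"], kind="mean")
            )
        rows[pathway] = {"index": rec["index"], "z": float(zpos), "percentile": pct}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "pathway"
    return out


def bias_test(
    placements: pd.DataFrame, min_samples: int = 3
) -> pd.DataFrame:
    """Kolmogorov–Smirnov check that mapped samples sit unbiased in the
    reference.

    ``placements`` is samples x pathways of reference z-positions (as
    produced by stacking :func:`map_to_reference` outputs).  Per pathway,
    a one-sample KS test of the z-positions against the standard normal;
    pathways with fewer than ``min_samples`` placed samples are skipped
    with a warning.  Returns a DataFrame indexed by pathway with columns
    ``n``, ``statistic``, ``pvalue``.
    """
    rows = {}
    for pathway in placements.columns:
        vals = placements[pathway].dropna().to_numpy(dtype=float)
        if vals.size < min_samples:
            warnings.warn(
                f"pathway {pathway!r}: only {vals.size} placed samples; skipped",
                stacklevel=2,
            )
            continue
        res = stats.kstest(vals, "norm")
        rows[pathway] = {
            "n": int(vals.size),
            "statistic": float(res.statistic),
            "pvalue": float(res.pvalue),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if not len(out):
        out = pd.DataFrame(columns=["n", "statistic", "pvalue"])
    else:
        out = out.astype({"n": int})
    out.index.name = "pathway"
    return out
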