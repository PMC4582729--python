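"""Seeded synthetic matched cohorts for exercising the pipeline.

No patient data ships with this package; instead this module generates
cohorts carrying the statistical structure the downstream comparisons
assume, so every stage can be tested end to end:

* a latent log2 expression matrix per patient, with per-gene baseline
  means, patient-level biological variation, and equicorrelation within
  each pathway block (independence across blocks);
* an array observation per patient: latent value plus Gaussian probe
  noise (log2 units);
* a snap-frozen qPCR assay per patient: Ct = per-gene intercept minus
  latent expression plus cycle noise — one PCR cycle per doubling, so
  the transfer slope is fixed at -1 cycle per log2 unit;
* a matched FFPE qPCR assay: a fresh draw from the frozen Ct model plus
  a patient-level additive degradation shift and extra per-measurement
  noise (the simplest mechanism consistent with the high intra-patient
  correlations such designs report);
* housekeeping genes (GAPDH, HPRT1, GUSB) drawn near-constant so the
  delta-Ct reference is meaningful;
* detection censoring: Ct at or beyond the threshold is flagged
  unexpressed but the raw value is retained, keeping threshold policy
  downstream.

Everything is driven by a single integer seed; identical configurations
reproduce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .matrix import read_matrix_tsv, write_matrix_tsv
from .pathways import PathwayMap, default_pathway_map, read_pathway_map, write_pathway_map
from .qpcr import (
    DEFAULT_DETECTION_THRESHOLD,
    DEFAULT_HOUSEKEEPING,
    CtTable,
    flag_unexpressed,
    read_ct_table,
    write_ct_table,
)

DEFAULT_PATHWAY_SIZES = tuple(
    len(m) for m in default_pathway_map().pathways.values()
)

__all__ = [
    "SimConfig",
    "MatchedCohort",
    "generate_cohort",
    "write_fixture",
    "read_fixture",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults encode the matched-cohort study
    design this package targets.

    Units: expression is log2; Ct values and their noise are PCR cycles
    (one cycle per log2 unit by construction).

    Parameters
    ----------
    n_patients
        Matched frozen/FFPE/array triples to generate (default 18, the
        size of a typical matched-preservation cohort).
    pathway_sizes
        Genes per pathway block; default is the built-in 10-pathway,
        91-gene panel.
    n_housekeeping
        Stable control genes appended to the panel (default 3).
    latent_mean_range
        Per-gene baseline log2 expression means, drawn uniformly; the
        span covers high expressors down to genes whose Ct brushes the
        detection threshold, so low expressors drop out occasionally.
    latent_sd
        Patient-level biological SD (log2) around the gene baseline.
    block_rho
        Equicorrelation of latent expression within a pathway block;
        zero across blocks.
    array_noise_sd
        Array measurement noise SD (log2).
    qpcr_noise_sd
        qPCR measurement noise SD (cycles), applied to every assay.
    qpcr_intercept_range
        Per-gene Ct at zero log2 expression, drawn uniformly (assay
        efficiency differences between TaqMan probes).
    ffpe_shift_mean, ffpe_shift_sd
        Patient-level additive FFPE degradation shift (cycles).
    ffpe_extra_noise_sd
        Additional per-measurement FFPE noise SD (cycles); kept small
        relative to ``latent_sd`` so matched samples stay more alike
        than unrelated ones.
    detection_threshold
        Ct at or beyond which a measurement is flagged unexpressed.
    hk_mean_range
        Baseline log2 expression of housekeeping genes (high, so their
        Ct sits near 20 cycles).
    hk_stability_sd
        Biological SD of housekeeping genes (near zero: they are stable
        by assumption, which is what makes delta-Ct normalization work).
    seed
        Seed for all randomness.
    """

    n_patients: int = 18
    pathway_sizes: tuple[int, ...] = DEFAULT_PATHWAY_SIZES
    n_housekeeping: int = 3
    latent_mean_range: tuple[float, float] = (3.0, 10.0)
    latent_sd: float = 1.0
    block_rho: float = 0.5
    array_noise_sd: float = 0.3
    qpcr_noise_sd: float = 0.3
    qpcr_intercept_range: tuple[float, float] = (34.0, 38.0)
    ffpe_shift_mean: float = 1.5
    ffpe_shift_sd: float = 0.5
    ffpe_extra_noise_sd: float = 0.4
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD
    hk_mean_range: tuple[float, float] = (14.0, 16.0)
    hk_stability_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathway_sizes", tuple(int(k) for k in self.pathway_sizes))
        object.__setattr__(self, "latent_mean_range", tuple(self.latent_mean_range))
        object.__setattr__(self, "qpcr_intercept_range", tuple(self.qpcr_intercept_range))
        object.__setattr__(self, "hk_mean_range", tuple(self.hk_mean_range))
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if not self.pathway_sizes or any(k <= 0 for k in self.pathway_sizes):
            raise ConfigError("pathway_sizes must be a nonempty list of positive ints")
        if self.n_housekeeping < 0:
            raise ConfigError("n_housekeeping must be >= 0")
        for name in (
            "latent_sd",
            "array_noise_sd",
            "qpcr_noise_sd",
            "ffpe_shift_sd",
            "ffpe_extra_noise_sd",
            "hk_stability_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.block_rho < 1.0:
            # equicorrelation outside [0, 1) loses positive definiteness
            # for some block sizes (and >1 is no correlation at all)
            raise ConfigError(
                f"block_rho must lie in [0, 1) for a positive-definite "
                f"within-block correlation, got {self.block_rho}"
            )
        if self.detection_threshold <= 0:
            raise ConfigError("detection_threshold must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pathway_sizes"] = list(self.pathway_sizes)
        d["latent_mean_range"] = list(self.latent_mean_range)
        d["qpcr_intercept_range"] = list(self.qpcr_intercept_range)
        d["hk_mean_range"] = list(self.hk_mean_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulator setting(s): {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class MatchedCohort:
    """One synthetic cohort: latent truth plus all platform observations.

    ``latent`` and ``array`` are genes x patients (housekeeping rows
    included); ``frozen_assays``/``ffpe_assays`` hold one Ct table per
    patient, detection threshold already applied; ``pairing`` links each
    patient's frozen, FFPE and array records; ``gene_params`` records
    the per-gene draws (pathway, latent mean, qPCR intercept); ``truth``
    bundles the config and per-patient FFPE shifts.
    """

    latent: pd.DataFrame
    array: pd.DataFrame
    frozen_assays: tuple[CtTable, ...]
    ffpe_assays: tuple[CtTable, ...]
    pairing: pd.DataFrame
    pathway_map: PathwayMap
    gene_params: pd.DataFrame
    ffpe_shifts: pd.Series
    config: SimConfig

    @property
    def patients(self) -> list[str]:
        return list(self.pairing["patient_id"])

    @property
    def all_assays(self) -> tuple[CtTable, ...]:
        return self.frozen_assays + self.ffpe_assays


def _panel_for(config: SimConfig) -> PathwayMap:
    """The gene panel implied by ``pathway_sizes``: the built-in 91-gene
    panel when sizes match it, otherwise synthetic ``PWnn_Gmm`` names."""
    default = default_pathway_map()
    if config.pathway_sizes == tuple(len(m) for m in default.pathways.values()):
        return default
    return PathwayMap(
        {
            f"pw{i + 1:02d}": tuple(f"PW{i + 1:02d}_G{j + 1:02d}" for j in range(k))
            for i, k in enumerate(config.pathway_sizes)
        }
    )


def _hk_names(n: int) -> list[str]:
    names = list(DEFAULT_HOUSEKEEPING[:n])
    names += [f"HK{i + 1:02d}" for i in range(len(names), n)]
    return names


def generate_cohort(config: SimConfig) -> MatchedCohort:
    """Draw one matched cohort from the generative model (seeded).

    Per gene g and patient p, with latent expression x:

        array[g, p]  = x[g, p] + N(0, array_noise_sd^2)
        frozen Ct    = intercept_g - x[g, p] + N(0, qpcr_noise_sd^2)
        FFPE Ct      = intercept_g - x[g, p] + N(0, qpcr_noise_sd^2)
                       + shift_p + N(0, ffpe_extra_noise_sd^2)

    with shift_p ~ N(ffpe_shift_mean, ffpe_shift_sd^2).  Ct values at or
    beyond the detection threshold are flagged unexpressed.
    """
    rng = np.random.default_rng(config.seed)
    panel = _panel_for(config)
    target_genes = panel.genes
    hk_genes = _hk_names(config.n_housekeeping)
    clash = set(target_genes) & set(hk_genes)
    if clash:
        raise ConfigError(f"housekeeping names collide with panel genes: {sorted(clash)}")
    genes = target_genes + hk_genes
    n = config.n_patients
    n_t = len(target_genes)

    mu_t = rng.uniform(*config.latent_mean_range, size=n_t)
    mu_hk = rng.uniform(*config.hk_mean_range, size=config.n_housekeeping)
    intercepts = rng.uniform(*config.qpcr_intercept_range, size=len(genes))

    # latent deviations: equicorrelated within each pathway block
    latent_t = np.empty((n_t, n))
    row = 0
    for name, members in panel.pathways.items():
        k = len(members)
        corr = np.full((k, k), config.block_rho)
        np.fill_diagonal(corr, 1.0)
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ConfigError(
                f"within-block correlation for pathway {name!r} is not "
                f"positive definite (rho={config.block_rho}, size={k})"
            ) from exc
        z = rng.standard_normal(size=(k, n))
        latent_t[row : row + k, :] = config.latent_sd * (chol @ z)
        row += k
    latent_t += mu_t[:, None]
    latent_hk = mu_hk[:, None] + config.hk_stability_sd * rng.standard_normal(
        size=(config.n_housekeeping, n)
    )
    latent = np.vstack([latent_t, latent_hk]) if config.n_housekeeping else latent_t

    array = latent + config.array_noise_sd * rng.standard_normal(latent.shape)
    frozen_ct = (
        intercepts[:, None]
        - latent
        + config.qpcr_noise_sd * rng.standard_normal(latent.shape)
    )
    shifts = config.ffpe_shift_mean + config.ffpe_shift_sd * rng.standard_normal(n)
    ffpe_ct = (
        intercepts[:, None]
        - latent
        + config.qpcr_noise_sd * rng.standard_normal(latent.shape)
        + shifts[None, :]
        + config.ffpe_extra_noise_sd * rng.standard_normal(latent.shape)
    )
    rqi_frozen = rng.uniform(6.5, 9.8, size=n)
    rqi_ffpe = rng.uniform(1.9, 3.1, size=n)

    patients = [f"P{i + 1:03d}" for i in range(n)]
    gene_index = pd.Index(genes, name="gene_id")
    latent_df = pd.DataFrame(latent, index=gene_index, columns=patients)
    array_df = pd.DataFrame(array, index=gene_index, columns=patients)

    def _assay(p_idx: int, ct_col: np.ndarray, preservation: str, rqi: float) -> CtTable:
        sid = f"{patients[p_idx]}_{'F' if preservation == 'frozen' else 'S'}"
        table = CtTable(
            sample_id=sid,
            measurements=dict(zip(genes, ct_col)),
            metadata={
                "patient_id": patients[p_idx],
                "preservation": preservation,
                "rqi": f"{rqi:.1f}",
            },
        )
        return flag_unexpressed(table, config.detection_threshold)

    frozen_assays = tuple(
        _assay(p, frozen_ct[:, p], "frozen", rqi_frozen[p]) for p in range(n)
    )
    ffpe_assays = tuple(
        _assay(p, ffpe_ct[:, p], "ffpe", rqi_ffpe[p]) for p in range(n)
    )

    pathway_of = {g: name for name, mem in panel.pathways.items() for g in mem}
    gene_params = pd.DataFrame(
        {
            "pathway": [pathway_of.get(g, "housekeeping") for g in genes],
            "latent_mean": np.concatenate([mu_t, mu_hk]) if config.n_housekeeping else mu_t,
            "intercept": intercepts,
            "is_housekeeping": [g in hk_genes for g in genes],
        },
        index=gene_index,
    )
    pairing = pd.DataFrame(
        {
            "patient_id": patients,
            "frozen": [t.sample_id for t in frozen_assays],
            "ffpe": [t.sample_id for t in ffpe_assays],
            "array": patients,
        }
    )
    return MatchedCohort(
        latent=latent_df,
        array=array_df,
        frozen_assays=frozen_assays,
        ffpe_assays=ffpe_assays,
        pairing=pairing,
        pathway_map=panel,
        gene_params=gene_params,
        ffpe_shifts=pd.Series(shifts, index=patients, name="ffpe_shift"),
        config=config,
    )


# ---------------------------------------------------------------------------
# fixture persistence


def write_fixture(cohort: MatchedCohort, destination: str | Path) -> list[Path]:
    """Write a cohort to disk in the package's text dialects.

    Layout: ``array_matrix.tsv``, ``latent_matrix.tsv``,
    ``pathway_map.tsv``, ``gene_params.tsv``, ``pairing.tsv``,
    ``truth.yaml`` and one ``ct/<sample_id>.tsv`` per assay.  Round-trips
    losslessly through :func:`read_fixture`.
    """
    dest = Path(destination)
    ct_dir = dest / "ct"
    ct_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _put(path: Path) -> Path:
        written.append(path)
        return path

    write_matrix_tsv(cohort.array, _put(dest / "array_matrix.tsv"))
    write_matrix_tsv(cohort.latent, _put(dest / "latent_matrix.tsv"))
    write_pathway_map(cohort.pathway_map, _put(dest / "pathway_map.tsv"))
    gp = cohort.gene_params.reset_index()
    gp.to_csv(_put(dest / "gene_params.tsv"), sep="\t", index=False)
    cohort.pairing.to_csv(_put(dest / "pairing.tsv"), sep="\t", index=False)
    for table in cohort.all_assays:
        write_ct_table(table, _put(ct_dir / f"{table.sample_id}.tsv"))
    truth = {
        "config": cohort.config.to_dict(),
        "ffpe_shifts": {p: float(v) for p, v in cohort.ffpe_shifts.items()},
    }
    with open(_put(dest / "truth.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return written


def read_fixture(source: str | Path) -> MatchedCohort:
    """Rebuild a :class:`MatchedCohort` from a fixture directory."""
    src = Path(source)
    with open(src / "truth.yaml", "r", encoding="utf-8") as fh:
        truth = yaml.safe_load(fh)
    config = SimConfig.from_dict(truth["config"])
    _, array = read_matrix_tsv(src / "array_matrix.tsv")
    _, latent = read_matrix_tsv(src / "latent_matrix.tsv")
    panel = read_pathway_map(src / "pathway_map.tsv")
    gene_params = pd.read_csv(src / "gene_params.tsv", sep="\t", index_col="gene_id")
    pairing = pd.read_csv(src / "pairing.tsv", sep="\t", dtype=str)
    frozen, ffpe = [], []
    for row in pairing.itertuples(index=False):
        f = read_ct_table(src / "ct" / f"{row.frozen}.tsv")
        s = read_ct_table(src / "ct" / f"{row.ffpe}.tsv")
        frozen.append(flag_unexpressed(f, config.detection_threshold))
        ffpe.append(flag_unexpressed(s, config.detection_threshold))
    shifts = pd.Series(truth["ffpe_shifts"], name="ffpe_shift", dtype=float)
    shifts = shifts.reindex(list(pairing["patient_id"]))
    return MatchedCohort(
        latent=latent,
        array=array,
        frozen_assays=tuple(frozen),
        ffpe_assays=tuple(ffpe),
        pairing=pairing,
        pathway_map=panel,
        gene_params=gene_params,
        ffpe_shifts=shifts,
        config=config,
    )
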