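"""End-to-end orchestration of the synthetic-cohort experiments.

One :func:`run_pipeline` call reproduces, on generated data, the three
comparisons the package exists for:

1. platform concordance — housekeeping-normalized, calibrated array
   values vs matched snap-frozen qPCR values, pooled and per sample,
   with LOWESS trend curves;
2. preservation concordance — the all-pairs correlation matrix over
   stacked frozen + FFPE qPCR profiles, summarized as intra- vs
   inter-patient extremes;
3. reference mapping — FFPE qPCR pathway indexes placed within the
   reference cohort's (array-side) pathway distributions, with a KS
   bias check.

The reference cohort shares the study cohort's per-gene parameters (it
is carved from the same seeded draw), mirroring a large external cohort
measured on the array platform.  Stages communicate through files in
the run directory so each is independently inspectable; a manifest
records seed, config hash and row counts for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .arrays import hk_normalize_array
from .calibration import build_calibration_table, write_calibration_table
from .calibration import apply_calibration
from .concordance import (
    DEFAULT_LOWESS_SPAN,
    DEFAULT_MASK_THRESHOLD,
    gene_level_correlation,
    intra_vs_inter_summary,
    per_sample_lowess,
    sample_pair_correlation_matrix,
)
from .errors import ConfigError, PsrpError
from .matrix import ScoreMatrix, write_scores
from .pathways import (
    bias_test,
    build_reference_distribution,
    map_to_reference,
    pathway_index,
    profiles_to_frame,
)
from .qpcr import ct_score, dropout_summary
from .simulate import MatchedCohort, SimConfig, generate_cohort, write_fixture

log = logging.getLogger("psrp")

__all__ = ["RunConfig", "load_run_config", "run_pipeline", "split_cohort"]


@dataclass(frozen=True)
class RunConfig:
    """Settings for one end-to-end synthetic run."""

    simulate: SimConfig = field(default_factory=SimConfig)
    n_reference: int = 200
    lowess_span: float = DEFAULT_LOWESS_SPAN
    mask_threshold: float = DEFAULT_MASK_THRESHOLD
    seed: int | None = None

    def resolved_sim(self) -> SimConfig:
        cfg = self.simulate
        if self.seed is not None:
            cfg = replace(cfg, seed=int(self.seed))
        return cfg

    def to_dict(self) -> dict:
        return {
            "simulate": self.simulate.to_dict(),
            "n_reference": self.n_reference,
            "lowess_span": self.lowess_span,
            "mask_threshold": self.mask_threshold,
            "seed": self.seed,
        }


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"run config not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: run config must be a mapping")
    sim = SimConfig.from_dict(raw.pop("simulate", {}) or {})
    known = {"n_reference", "lowess_span", "mask_threshold", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown setting(s): {sorted(unknown)}")
    return RunConfig(simulate=sim, **raw)


def split_cohort(cohort: MatchedCohort, n_study: int) -> tuple[MatchedCohort, pd.DataFrame]:
    """Split a cohort into a study cohort (first ``n_study`` patients, all
    platforms) and a reference array matrix (remaining patients).

    Both halves share the same per-gene draws, so the reference plays
    the role of a large external cohort assayed with the same panel.
    """
    patients = cohort.patients
    if n_study > len(patients):
        raise ConfigError(
            f"cannot take {n_study} study patients from a {len(patients)}-patient cohort"
        )
    study_p = patients[:n_study]
    ref_p = patients[n_study:]
    study = MatchedCohort(
        latent=cohort.latent[study_p],
        array=cohort.array[study_p],
        frozen_assays=cohort.frozen_assays[:n_study],
        ffpe_assays=cohort.ffpe_assays[:n_study],
        pairing=cohort.pairing.iloc[:n_study].reset_index(drop=True),
        pathway_map=cohort.pathway_map,
        gene_params=cohort.gene_params,
        ffpe_shifts=cohort.ffpe_shifts.loc[study_p],
        config=cohort.config,
    )
    return study, cohort.array[ref_p]


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage; returns the run directory.

    Deterministic given the config (including its seed): rerunning into
    a fresh directory reproduces byte-identical numeric outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.resolved_sim()
    hk = None  # set in the simulate stage
    files: dict[str, int] = {}

    def _write_tsv(df: pd.DataFrame, name: str, index: bool = True) -> None:
        df.to_csv(out / name, sep="\t", index=index, na_rep="NA")
        files[name] = len(df)

    stage = "simulate"
    try:
        combined = generate_cohort(
            replace(sim_cfg, n_patients=sim_cfg.n_patients + config.n_reference)
        )
        study, reference_array = split_cohort(combined, sim_cfg.n_patients)
        hk = tuple(
            g for g in study.gene_params.index[study.gene_params["is_housekeeping"]]
        )
        fixture_files = write_fixture(study, out / "fixture")
        files.update({str(p.relative_to(out)): -1 for p in fixture_files})
        log.info("simulated %d study patients + %d reference samples",
                 sim_cfg.n_patients, config.n_reference)

        stage = "normalize-qpcr"
        qpcr_scores = ct_score(study.all_assays, hk)
        write_scores(qpcr_scores, out / "qpcr_scores.tsv")
        files["qpcr_scores.tsv"] = len(qpcr_scores.genes)
        drops = dropout_summary(study.all_assays)
        _write_tsv(drops, "dropout_summary.tsv")

        stage = "normalize-array"
        array_scores = hk_normalize_array(study.array, hk)
        ref_scores = hk_normalize_array(reference_array, hk)
        write_scores(array_scores, out / "array_scores.tsv")
        write_scores(ref_scores, out / "reference_scores.tsv")
        files["array_scores.tsv"] = len(array_scores.genes)
        files["reference_scores.tsv"] = len(ref_scores.genes)

        stage = "calibrate"
        calib_q = build_calibration_table(qpcr_scores, provenance="study qPCR assays")
        calib_a = build_calibration_table(ref_scores, provenance="reference array cohort")
        write_calibration_table(calib_q, out / "calibration_qpcr.tsv")
        write_calibration_table(calib_a, out / "calibration_array.tsv")
        files["calibration_qpcr.tsv"] = len(calib_q)
        files["calibration_array.tsv"] = len(calib_a)
        z_qpcr = apply_calibration(qpcr_scores, calib_q)
        z_array = apply_calibration(array_scores, calib_a)
        z_ref = apply_calibration(ref_scores, calib_a)
        write_scores(z_qpcr, out / "z_qpcr.tsv")
        write_scores(z_array, out / "z_array.tsv")
        files["z_qpcr.tsv"] = len(z_qpcr.genes)
        files["z_array.tsv"] = len(z_array.genes)

        stage = "score"
        pmap = study.pathway_map
        prof_q = pathway_index(z_qpcr, pmap)
        prof_a = pathway_index(z_array, pmap)
        _write_tsv(profiles_to_frame(prof_q), "profiles_qpcr.tsv", index=False)
        _write_tsv(profiles_to_frame(prof_a), "profiles_array.tsv", index=False)

        stage = "map-reference"
        ref_dist = build_reference_distribution(z_ref, pmap)
        _write_tsv(ref_dist.table, "reference_distribution.tsv")
        ffpe_ids = set(study.pairing["ffpe"])
        placements = {}
        for prof in prof_q:
            if prof.sample_id in ffpe_ids:
                placed = map_to_reference(prof, ref_dist)
                placements[prof.sample_id] = placed["z"]
        placement_wide = pd.DataFrame(placements).T  # samples x pathways
        placement_wide.index.name = "sample_id"
        _write_tsv(placement_wide, "placements.tsv")
        bias = bias_test(placement_wide)
        _write_tsv(bias, "bias_test.tsv")

        stage = "concord"
        # platform comparison: array vs matched frozen qPCR, on the z scale
        frozen_ids = list(study.pairing["frozen"])
        z_frozen = z_qpcr.subset_samples(frozen_ids)
        renamed = ScoreMatrix(
            z_frozen.values.set_axis(list(study.pairing["patient_id"]), axis=1),
            platform="qpcr",
            housekeeping=z_frozen.housekeeping,
        )
        report_rows = []
        for method in ("pearson", "spearman"):
            res = gene_level_correlation(z_array, renamed, method=method)
            report_rows.append(
                {
                    "comparison": "array_vs_frozen_qpcr",
                    "method": method,
                    "pooled_r": res.pooled,
                    "mean_per_sample_r": res.mean_per_sample,
                    "n_pairs": res.n_pairs,
                }
            )
        _write_tsv(pd.DataFrame(report_rows), "concordance_platform.tsv", index=False)

        curves = []
        av, qv = z_array.values, renamed.values
        for patient in renamed.values.columns:
            joint = av[patient].notna() & qv[patient].notna()
            if joint.sum() >= 10:
                curve = per_sample_lowess(
                    av.loc[joint, patient], qv.loc[joint, patient], config.lowess_span
                )
                curve.insert(0, "sample_id", patient)
                curves.append(curve)
        if curves:
            _write_tsv(pd.concat(curves, ignore_index=True), "lowess.tsv", index=False)

        # preservation comparison: all qPCR profiles stacked
        pm = sample_pair_correlation_matrix(
            qpcr_scores, mask_threshold=config.mask_threshold
        )
        _write_tsv(pm.values, "pair_matrix.tsv")
        summary = intra_vs_inter_summary(
            pm, study.pairing[["patient_id", "frozen", "ffpe"]]
        )
        intra = summary.per_patient.rename_axis("patient_id").reset_index()
        _write_tsv(intra, "intra_patient_correlations.tsv", index=False)
        summary_json = {
            "min_intra_patient_r": summary.min_intra,
            "max_inter_patient_r": summary.max_inter,
            "separation": summary.separation,
            "n_inter_pairs": summary.n_inter_pairs,
        }
        with open(out / "intra_inter_summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary_json, fh, indent=2)
        files["intra_inter_summary.json"] = 1
    except PsrpError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc

    manifest = {
        "package": "psrp",
        "version": __version__,
        "seed": sim_cfg.seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "outputs": files,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
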