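"""Cross-platform and cross-preservation agreement measures.

Three views of agreement between two score matrices for the same
samples:

* pooled and per-sample Pearson/Spearman correlations over jointly
  observed (gene, sample) pairs — missing entries are dropped pairwise,
  mirroring the per-assay removal of undetected probes;
* LOWESS trend curves (tricube-weighted local linear regression, no
  robustness iterations) summarizing the relationship per sample;
* the all-pairs sample correlation matrix over stacked profiles
  (frozen and FFPE together), from which intra-patient vs inter-patient
  separation is summarized.

A display mask threshold on the pair matrix (default r < 0.79 hidden)
affects rendering only; every value is retained numerically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .matrix import ScoreMatrix

DEFAULT_MASK_THRESHOLD = 0.79
DEFAULT_LOWESS_SPAN = 2.0 / 3.0

__all__ = [
    "CorrelationResult",
    "gene_level_correlation",
    "per_sample_lowess",
    "PairMatrix",
    "sample_pair_correlation_matrix",
    "IntraInterSummary",
    "intra_vs_inter_summary",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pooled correlation over all joint (gene, sample) pairs, plus the
    per-sample correlations across genes (NaN where a sample has fewer
    than 3 joint observations)."""

    method: str
    pooled: float
    n_pairs: int
    per_sample: pd.Series

    @property
    def mean_per_sample(self) -> float:
        return float(self.per_sample.mean(skipna=True))


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    return float(stats.spearmanr(x, y).statistic)


def gene_level_correlation(
    a: ScoreMatrix, b: ScoreMatrix, method: str = "pearson"
) -> CorrelationResult:
    """Correlate two score matrices over jointly observed entries.

    Matrices are aligned on their shared gene and sample identifiers;
    entries missing on either side are dropped pairwise.  Fewer than 3
    joint pairs overall is an error.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    genes = [g for g in a.values.index if g in set(b.values.index)]
    samples = [s for s in a.values.columns if s in set(b.values.columns)]
    if not genes or not samples:
        raise ValidationError("matrices share no gene/sample identifiers")
    av = a.values.loc[genes, samples].to_numpy(dtype=float)
    bv = b.values.loc[genes, samples].to_numpy(dtype=float)
    joint = ~np.isnan(av) & ~np.isnan(bv)
    n_pairs = int(joint.sum())
    if n_pairs < 3:
        raise ValidationError(f"only {n_pairs} joint pairs; need >= 3")
    pooled = _corr(av[joint], bv[joint], method)
    per_sample = {}
    for j, s in enumerate(samples):
        m = joint[:, j]
        per_sample[s] = _corr(av[m, j], bv[m, j], method) if m.sum() >= 3 else np.nan
    return CorrelationResult(
        method=method,
        pooled=pooled,
        n_pairs=n_pairs,
        per_sample=pd.Series(per_sample, name=f"{method}_r"),
    )


def _tricube(u: np.ndarray) -> np.ndarray:
    w = (1.0 - np.clip(u, 0.0, 1.0) ** 3) ** 3
    return np.where(u >= 1.0, 0.0, w)


def per_sample_lowess(
    x: Sequence[float], y: Sequence[float], span: float = DEFAULT_LOWESS_SPAN
) -> pd.DataFrame:
    """Tricube-weighted local linear smoother (classic LOWESS, 0 robustness
    iterations), evaluated at each observed x in ascending order.

    For each target point the window is the ``ceil(span * n)`` nearest
    neighbours (contiguous in sorted x); weights are tricube in distance
    scaled by the window's largest distance, and a weighted least-squares
    line through the window is evaluated at the target.  Deterministic
    given inputs and span.

    Returns a DataFrame with columns ``x`` and ``smoothed`` (sorted by x).
    """
    if not 0.0 < span <= 1.0:
        raise ValidationError(f"span must be in (0, 1], got {span}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 10:
        raise ValidationError(f"need >= 10 joint points for LOWESS, got {n}")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    r = max(2, int(math.ceil(span * n)))
    r = min(r, n)
    smoothed = np.empty(n)
    for i in range(n):
        lo_min = max(0, i - r + 1)
        lo_max = min(i, n - r)
        best_lo, best_width = lo_min, np.inf
        for lo in range(lo_min, lo_max + 1):
            width = max(xs[i] - xs[lo], xs[lo + r - 1] - xs[i])
            if width < best_width:
                best_width, best_lo = width, lo
        w_x = xs[best_lo : best_lo + r]
        w_y = ys[best_lo : best_lo + r]
        d = np.abs(w_x - xs[i])
        dmax = d.max()
        w = np.ones_like(d) if dmax == 0 else _tricube(d / dmax)
        if w.sum() <= 0:
            w = np.ones_like(d)
        sw = w.sum()
        xb = (w * w_x).sum() / sw
        yb = (w * w_y).sum() / sw
        sxx = (w * (w_x - xb) ** 2).sum()
        if sxx <= 1e-12 * max(1.0, xb * xb):
            smoothed[i] = yb
        else:
            slope = (w * (w_x - xb) * (w_y - yb)).sum() / sxx
            smoothed[i] = yb + slope * (xs[i] - xb)
    return pd.DataFrame({"x": xs, "smoothed": smoothed})


@dataclass(frozen=True)
class PairMatrix:
    """All-pairs Pearson correlation over stacked sample profiles.

    ``labels`` (optional) carries per-sample annotations (patient id,
    preservation method).  ``mask_threshold`` governs display only:
    :meth:`masked` blanks entries below it, the stored values are
    complete.
    """

    values: pd.DataFrame
    mask_threshold: float = DEFAULT_MASK_THRESHOLD
    labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if list(v.index) != list(v.columns):
            raise ValidationError("pair matrix must be square with matching labels")
        arr = v.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, equal_nan=True, atol=1e-12):
            raise ValidationError("pair matrix must be symmetric")

    def masked(self) -> pd.DataFrame:
        """Rendering view: correlations below the mask threshold blanked."""
        return self.values.where(self.values >= self.mask_threshold)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)


def sample_pair_correlation_matrix(
    profiles: ScoreMatrix,
    labels: pd.DataFrame | None = None,
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
    min_overlap: int = 3,
) -> PairMatrix:
    """Pearson correlation between every pair of sample profiles.

    Missing entries are handled by pairwise-complete deletion; a pair
    with fewer than ``min_overlap`` jointly observed genes gets a
    missing entry and a warning.  The diagonal is unity by definition.
    """
    if len(profiles.samples) < 2:
        raise ValidationError("need >= 2 samples for a pair matrix")
    corr = profiles.values.corr(method="pearson", min_periods=max(min_overlap, 2))
    np.fill_diagonal(corr.to_numpy(), 1.0)
    n_bad = int(np.isnan(corr.to_numpy()).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad // 2} sample pair(s) with insufficient gene overlap "
            f"(< {min_overlap}); entries left missing",
            stacklevel=2,
        )
    return PairMatrix(corr, mask_threshold=mask_threshold, labels=labels)


@dataclass(frozen=True)
class IntraInterSummary:
    """Matched-pair vs cross-patient correlation extremes.

    ``separation`` is True when the weakest matched (frozen vs FFPE,
    same patient) correlation still exceeds the strongest cross-patient
    correlation — the qualitative signature that preservation effects
    are smaller than patient-to-patient biology.
    """

    per_patient: pd.Series
    min_intra: float
    max_inter: float
    separation: bool
    n_inter_pairs: int


def intra_vs_inter_summary(
    matrix: PairMatrix, pairing: Mapping[str, tuple[str, str]] | pd.DataFrame
) -> IntraInterSummary:
    """Summarize the pair matrix into matched vs unmatched extremes.

    ``pairing`` maps patient id -> (frozen sample id, ffpe sample id),
    or a DataFrame with columns ``patient_id``, ``frozen``, ``ffpe``.
    Every listed sample must be present in the matrix; a patient with a
    missing profile is an error naming the patient.
    """
    if isinstance(pairing, pd.DataFrame):
        for col in ("patient_id", "frozen", "ffpe"):
            if col not in pairing.columns:
                raise ValidationError(f"pairing frame missing column {col!r}")
        if pairing["patient_id"].duplicated().any():
            dup = pairing.loc[pairing["patient_id"].duplicated(), "patient_id"].tolist()
            raise ValidationError(f"patient(s) listed more than once: {dup}")
        pairing = {
            str(r.patient_id): (str(r.frozen), str(r.ffpe))
            for r in pairing.itertuples(index=False)
        }
    sample_patient: dict[str, str] = {}
    for patient, (frozen, ffpe) in pairing.items():
        for sid in (frozen, ffpe):
            if sid not in matrix.values.index:
                raise ValidationError(
                    f"patient {patient!r}: sample {sid!r} absent from pair matrix"
                )
            sample_patient[sid] = patient
    intra = pd.Series(
        {p: float(matrix.values.loc[f, s]) for p, (f, s) in pairing.items()},
        name="intra_r",
    )
    samples = list(sample_patient)
    inter_vals = []
    for i, si in enumerate(samples):
        for sj in samples[i + 1 :]:
            if sample_patient[si] != sample_patient[sj]:
                inter_vals.append(float(matrix.values.loc[si, sj]))
    if not inter_vals:
        warnings.warn(
            "single patient: no inter-patient pairs; separation is vacuous",
            stacklevel=2,
        )
        max_inter = float("nan")
        separation = True
    else:
        max_inter = float(np.nanmax(inter_vals))
        separation = bool(float(intra.min()) > max_inter)
    return IntraInterSummary(
        per_patient=intra,
        min_intra=float(intra.min()),
        max_inter=max_inter,
        separation=separation,
        n_inter_pairs=len(inter_vals),
    )
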