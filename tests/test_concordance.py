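import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from psrp.concordance import (
    PairMatrix,
    gene_level_correlation,
    intra_vs_inter_summary,
    per_sample_lowess,
    sample_pair_correlation_matrix,
)
from psrp.errors import ValidationError
from psrp.matrix import ScoreMatrix


def _sm(array, genes=None, samples=None, platform="qpcr"):
    array = np.asarray(array, dtype=float)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    samples = samples or [f"s{j}" for j in range(array.shape[1])]
    return ScoreMatrix(
        pd.DataFrame(array, index=pd.Index(genes, name="gene_id"), columns=samples),
        platform=platform,
    )


def _pearson_oracle(x, y):
    """Textbook covariance formula, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


class TestGeneLevelCorrelation:
    def test_self_and_sign_reversal(self):
        a = _sm(np.arange(12.0).reshape(4, 3))
        assert gene_level_correlation(a, a).pooled == pytest.approx(1.0)
        neg = _sm(-np.arange(12.0).reshape(4, 3))
        assert gene_level_correlation(a, neg).pooled == pytest.approx(-1.0)

    def test_four_point_oracle(self):
        a = _sm(np.array([[1.0], [2.0], [3.0], [4.0]]))
        b = _sm(np.array([[1.0], [3.0], [2.0], [4.0]]))
        res = gene_level_correlation(a, b)
        assert res.pooled == pytest.approx(_pearson_oracle([1, 2, 3, 4], [1, 3, 2, 4]), abs=1e-12)
        assert res.pooled == pytest.approx(0.8, abs=1e-12)

    def test_missing_dropped_pairwise(self):
        a = _sm([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]])
        b = _sm([[1.5, np.nan], [3.5, 4.0], [5.5, 6.5]])
        res = gene_level_correlation(a, b)
        assert res.n_pairs == 4

    def test_too_few_joint_pairs(self):
        a = _sm([[1.0], [np.nan], [3.0]])
        b = _sm([[1.0], [2.0], [np.nan]])
        with pytest.raises(ValidationError, match="joint pairs"):
            gene_level_correlation(a, b)

    def test_pooled_matches_brute_force_with_missingness(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            av = rng.normal(size=(8, 5))
            bv = av * 0.5 + rng.normal(size=(8, 5))
            av[rng.random(av.shape) < 0.2] = np.nan
            res = gene_level_correlation(_sm(av), _sm(bv))
            joint = ~np.isnan(av) & ~np.isnan(bv)
            assert res.pooled == pytest.approx(
                _pearson_oracle(av[joint], bv[joint]), abs=1e-12
            )

    @settings(max_examples=40, derandomize=True)
    @given(
        slope=st.floats(0.1, 5.0),
        offset=st.floats(-10.0, 10.0),
    )
    def test_pearson_affine_and_spearman_monotone_invariance(self, slope, offset):
        rng = np.random.default_rng(99)
        av = rng.normal(size=(6, 4))
        bv = av + rng.normal(size=(6, 4))
        a, b = _sm(av), _sm(bv)
        affine = _sm(bv * slope + offset)
        r0 = gene_level_correlation(a, b).pooled
        assert gene_level_correlation(a, affine).pooled == pytest.approx(r0, abs=1e-9)
        mono = _sm(np.exp(bv))  # strictly increasing map
        s0 = gene_level_correlation(a, b, "spearman").pooled
        assert gene_level_correlation(a, mono, "spearman").pooled == pytest.approx(s0, abs=1e-9)


class TestLowess:
    def test_constant_preserved(self):
        x = np.linspace(0, 1, 15)
        out = per_sample_lowess(x, np.full(15, 3.25))
        assert np.allclose(out["smoothed"], 3.25, atol=1e-12)

    def test_line_reproduced(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 10, 30))
        out = per_sample_lowess(x, x, span=0.5)
        assert np.allclose(out["smoothed"], out["x"], atol=1e-6)

    def test_single_point_wls_oracle(self):
        """The smoothed value at a target point equals an independently
        computed tricube-weighted least-squares line through the
        nearest-neighbour window."""
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 5, 20))
        y = np.cos(x) + rng.normal(0, 0.1, 20)
        span = 0.5
        out = per_sample_lowess(x, y, span=span)
        r = int(np.ceil(span * len(x)))
        for i in (0, 7, 19):
            d = np.abs(x - x[i])
            idx = np.sort(np.argsort(d, kind="stable")[:r])
            dd = d[idx]
            w = (1 - (dd / dd.max()) ** 3) ** 3
            w[dd >= dd.max()] = 0.0
            coef = np.polyfit(x[idx], y[idx], 1, w=np.sqrt(w))
            expected = np.polyval(coef, x[i])
            assert out["smoothed"].iloc[i] == pytest.approx(expected, abs=1e-8)

    def test_matches_statsmodels_reference(self):
        sm_lowess = pytest.importorskip(
            "statsmodels.nonparametric.smoothers_lowess"
        ).lowess
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 10, 40))
        y = np.sin(x) + rng.normal(0, 0.2, 40)
        mine = per_sample_lowess(x, y, span=0.5)["smoothed"].to_numpy()
        theirs = sm_lowess(y, x, frac=0.5, it=0, return_sorted=True)[:, 1]
        assert np.allclose(mine, theirs, atol=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValidationError, match=">= 10"):
            per_sample_lowess(np.arange(5.0), np.arange(5.0))

    def test_invalid_span(self):
        with pytest.raises(ValidationError, match="span"):
            per_sample_lowess(np.arange(12.0), np.arange(12.0), span=0.0)


class TestPairMatrix:
    def test_diagonal_and_duplicate_columns(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(10, 3))
        v[:, 2] = v[:, 0]  # duplicate profile
        pm = sample_pair_correlation_matrix(_sm(v))
        assert np.allclose(np.diag(pm.values), 1.0)
        assert pm.values.iloc[0, 2] == pytest.approx(1.0)

    def test_elementwise_brute_force_with_missing(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=(12, 4))
        v[rng.random(v.shape) < 0.15] = np.nan
        pm = sample_pair_correlation_matrix(_sm(v))
        for i in range(4):
            for j in range(i + 1, 4):
                joint = ~np.isnan(v[:, i]) & ~np.isnan(v[:, j])
                expected = _pearson_oracle(v[joint, i], v[joint, j])
                assert pm.values.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_to_float_tolerance(self):
        rng = np.random.default_rng(7)
        pm = sample_pair_correlation_matrix(_sm(rng.normal(size=(15, 6))))
        arr = pm.values.to_numpy()
        assert np.max(np.abs(arr - arr.T)) < 1e-12

    def test_mask_affects_rendering_only(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=(20, 3))
        pm = sample_pair_correlation_matrix(_sm(v), mask_threshold=0.79)
        masked = pm.masked()
        low = pm.values < 0.79
        assert masked[low].isna().all().all()
        assert not pm.values.isna().any().any()  # values retained numerically

    def test_insufficient_overlap_warns(self):
        v = np.full((4, 3), np.nan)
        v[:, 0] = [1.0, 2.0, 3.0, 4.0]
        v[:2, 1] = [1.0, 2.0]
        v[:, 2] = [2.0, 1.0, 4.0, 3.0]
        with pytest.warns(UserWarning, match="overlap"):
            pm = sample_pair_correlation_matrix(_sm(v))
        assert np.isnan(pm.values.iloc[0, 1])


class TestIntraVsInter:
    def _pm_from(self, v, samples):
        return sample_pair_correlation_matrix(_sm(v, samples=samples))

    def test_matched_pairs_dominate(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0, 2, size=(30, 3))  # three patients' profiles
        cols = []
        for p in range(3):
            cols.append(base[:, p] + rng.normal(0, 0.1, 30))  # frozen
            cols.append(base[:, p] + rng.normal(0, 0.1, 30))  # ffpe
        v = np.column_stack(cols)
        samples = ["p1F", "p1S", "p2F", "p2S", "p3F", "p3S"]
        pairing = {"p1": ("p1F", "p1S"), "p2": ("p2F", "p2S"), "p3": ("p3F", "p3S")}
        summ = intra_vs_inter_summary(self._pm_from(v, samples), pairing)
        assert summ.separation
        assert summ.min_intra > summ.max_inter
        assert summ.n_inter_pairs == 12

    def test_scrambled_pairing_breaks_separation(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=(40, 6))  # unrelated profiles
        samples = ["p1F", "p1S", "p2F", "p2S", "p3F", "p3S"]
        pairing = {"p1": ("p1F", "p2S"), "p2": ("p2F", "p3S"), "p3": ("p3F", "p1S")}
        summ = intra_vs_inter_summary(self._pm_from(v, samples), pairing)
        assert not summ.separation

    def test_single_patient_vacuous(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=(20, 2))
        samples = ["p1F", "p1S"]
        with pytest.warns(UserWarning, match="single patient"):
            summ = intra_vs_inter_summary(
                self._pm_from(v, samples), {"p1": ("p1F", "p1S")}
            )
        assert summ.separation
        assert np.isnan(summ.max_inter)

    def test_unmatched_patient_named(self):
        rng = np.random.default_rng(12)
        v = rng.normal(size=(20, 2))
        pm = self._pm_from(v, ["p1F", "p1S"])
        with pytest.raises(ValidationError, match="p2"):
            intra_vs_inter_summary(pm, {"p1": ("p1F", "p1S"), "p2": ("p2F", "p2S")})
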