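import numpy as np
import pandas as pd
import pytest

from psrp.errors import ConfigError, ValidationError
from psrp.matrix import ScoreMatrix
from psrp.pathways import (
    PathwayMap,
    bias_test,
    build_reference_distribution,
    default_pathway_map,
    map_to_reference,
    pathway_index,
    profiles_to_frame,
    read_pathway_map,
    write_pathway_map,
)


def _z(values: dict, samples=None) -> ScoreMatrix:
    df = pd.DataFrame(values, columns=samples).rename_axis("gene_id")
    return ScoreMatrix(df, platform="qpcr")


class TestPathwayMap:
    def test_default_panel_shape(self):
        pmap = default_pathway_map()
        assert len(pmap) == 10
        assert len(pmap.genes) == 91
        assert len(pmap["neurotrophin"]) == 6

    def test_parse_and_sizes(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("pathway\tgene_id\nwnt\tA\nwnt\tB\nnotch\tC\n")
        pmap = read_pathway_map(p)
        assert pmap.sizes == {"wnt": 2, "notch": 1}

    def test_multi_membership_allowed(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("pathway\tgene_id\nwnt\tA\nnotch\tA\nnotch\tB\n")
        pmap = read_pathway_map(p)
        assert "A" in pmap["wnt"] and "A" in pmap["notch"]
        assert pmap.genes == ["A", "B"]

    def test_duplicate_pair_collapsed_with_warning(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("pathway\tgene_id\nwnt\tA\nwnt\tA\nwnt\tB\n")
        with pytest.warns(UserWarning, match="duplicate"):
            pmap = read_pathway_map(p)
        assert pmap["wnt"] == ("A", "B")

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValidationError, match="no member"):
            PathwayMap({"wnt": ()})

    def test_roundtrip(self, tmp_path):
        pmap = default_pathway_map()
        write_pathway_map(pmap, tmp_path / "rt.tsv")
        assert read_pathway_map(tmp_path / "rt.tsv").pathways == pmap.pathways


class TestPathwayIndex:
    def test_symmetry_dropout_and_hand_values(self):
        pmap = PathwayMap({"p1": ("a", "b"), "p2": ("c", "d"), "p3": ("e", "f", "g")})
        z = _z(
            {
                "s": {"a": 1.0, "b": -1.0, "c": 2.0, "d": np.nan,
                      "e": 0.6, "f": 1.2, "g": -0.3}
            }
        )
        (prof,) = pathway_index(z, pmap)
        assert prof.table.loc["p1", "index"] == pytest.approx(0.0)
        # dropout shrinks the denominator instead of dragging the mean
        assert prof.table.loc["p2", "index"] == pytest.approx(2.0)
        assert prof.table.loc["p2", "n_expressed"] == 1
        assert prof.table.loc["p3", "index"] == pytest.approx(0.5)

    def test_all_members_missing_flags_absent(self):
        pmap = PathwayMap({"p": ("a", "b")})
        z = _z({"s": {"a": np.nan, "b": np.nan}})
        (prof,) = pathway_index(z, pmap)
        assert np.isnan(prof.table.loc["p", "index"])
        assert prof.absent == ["p"]

    def test_unknown_gene_is_config_error(self):
        pmap = PathwayMap({"p": ("a", "zzz")})
        z = _z({"s": {"a": 1.0}})
        with pytest.raises(ConfigError, match="zzz"):
            pathway_index(z, pmap)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(7)]
        vals = {f"s{j}": dict(zip(genes, rng.normal(size=7))) for j in range(4)}
        z = _z(vals)
        fwd = pathway_index(z, PathwayMap({"p": tuple(genes)}))
        rev = pathway_index(z, PathwayMap({"p": tuple(reversed(genes))}))
        for a, b in zip(fwd, rev):
            assert a.table.loc["p", "index"] == pytest.approx(b.table.loc["p", "index"], abs=1e-12)

    def test_single_dropout_perturbation_bound(self):
        """Removing one member of a size-k pathway moves the index by at
        most 2*max|z|/(k-1) on bounded scores."""
        rng = np.random.default_rng(3)
        k, bound = 8, 2.5
        vals = rng.uniform(-bound, bound, k)
        genes = [f"g{i}" for i in range(k)]
        full = _z({"s": dict(zip(genes, vals))})
        dropped_vals = dict(zip(genes, vals))
        dropped_vals[genes[0]] = np.nan
        dropped = _z({"s": dropped_vals})
        pmap = PathwayMap({"p": tuple(genes)})
        (a,) = pathway_index(full, pmap)
        (b,) = pathway_index(dropped, pmap)
        delta = abs(a.table.loc["p", "index"] - b.table.loc["p", "index"])
        assert delta <= 2 * bound / (k - 1) + 1e-12

    def test_long_format_view(self):
        pmap = PathwayMap({"p": ("a",)})
        z = _z({"s1": {"a": 1.0}, "s2": {"a": 2.0}})
        frame = profiles_to_frame(pathway_index(z, pmap))
        assert list(frame["sample_id"]) == ["s1", "s2"]
        assert list(frame.columns) == ["sample_id", "pathway", "index", "n_expressed", "n_members"]


class TestReferenceDistribution:
    def test_hand_fit(self):
        pmap = PathwayMap({"p": ("a",)})
        z = _z({"s1": {"a": -1.0}, "s2": {"a": 0.0}, "s3": {"a": 1.0}})
        ref = build_reference_distribution(z, pmap)
        assert ref.table.loc["p", "mean"] == pytest.approx(0.0)
        assert ref.table.loc["p", "sd"] == pytest.approx(1.0)

    def test_two_sample_cohort_insufficient(self):
        pmap = PathwayMap({"p": ("a",)})
        z = _z({"s1": {"a": -1.0}, "s2": {"a": 1.0}})
        with pytest.raises(ValidationError, match="3 samples"):
            build_reference_distribution(z, pmap)

    def test_self_calibrated_reference_centers_indexes(self):
        from psrp.calibration import apply_calibration, build_calibration_table

        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(6)]
        sm = ScoreMatrix(
            pd.DataFrame(
                rng.normal(size=(6, 12)), index=genes,
                columns=[f"s{j}" for j in range(12)],
            ),
            platform="array",
        )
        z = apply_calibration(sm, build_calibration_table(sm))
        ref = build_reference_distribution(z, PathwayMap({"p": tuple(genes)}))
        assert abs(ref.table.loc["p", "mean"]) < 1e-10


class TestMapToReference:
    @pytest.fixture
    def ref(self):
        pmap = PathwayMap({"p": ("a",)})
        z = _z({"s1": {"a": 0.0}, "s2": {"a": 2.0}, "s3": {"a": 4.0}})
        return pmap, build_reference_distribution(z, pmap)  # mean 2, sd 2

    def _profile(self, pmap, value):
        (prof,) = pathway_index(_z({"x": {"a": value}}), pmap)
        return prof

    def test_center_of_distribution(self, ref):
        pmap, dist = ref
        placed = map_to_reference(self._profile(pmap, 2.0), dist)
        assert placed.loc["p", "z"] == pytest.approx(0.0)
        assert placed.loc["p", "percentile"] == pytest.approx(50.0)

    def test_one_sd_above_and_below(self, ref):
        pmap, dist = ref
        up = map_to_reference(self._profile(pmap, 4.0), dist)
        down = map_to_reference(self._profile(pmap, 0.0), dist)
        assert up.loc["p", "percentile"] == pytest.approx(84.134, abs=0.01)
        assert down.loc["p", "percentile"] == pytest.approx(15.866, abs=0.01)

    def test_absent_pathway_skipped_with_warning(self, ref):
        pmap, dist = ref
        (prof,) = pathway_index(_z({"x": {"a": np.nan}}), pmap)
        with pytest.warns(UserWarning, match="no detected members"):
            placed = map_to_reference(prof, dist)
        assert len(placed) == 0

    def test_pathway_missing_from_reference(self, ref):
        pmap, dist = ref
        other = PathwayMap({"q": ("a",)})
        (prof,) = pathway_index(_z({"x": {"a": 1.0}}), other)
        with pytest.raises(ValidationError, match="q"):
            map_to_reference(prof, dist)

    def test_empirical_percentile_fallback(self):
        pmap = PathwayMap({"p": ("a",)})
        z = _z({f"s{i}": {"a": float(i)} for i in range(5)})
        dist = build_reference_distribution(z, pmap, keep_values=True)
        placed = map_to_reference(self._profile(pmap, 2.0), dist, method="empirical")
        assert placed.loc["p", "percentile"] == pytest.approx(50.0)


class TestBiasTest:
    def test_null_acceptance_rate(self):
        """Standard-normal placements should rarely be rejected: the KS
        test holds its level under the null."""
        rng = np.random.default_rng(12)
        accepted = 0
        n_rep = 40
        for _ in range(n_rep):
            placements = pd.DataFrame({"p": rng.standard_normal(200)})
            out = bias_test(placements)
            accepted += out.loc["p", "pvalue"] > 0.05
        assert accepted >= int(0.85 * n_rep)

    def test_gross_bias_detected(self):
        placements = pd.DataFrame({"p": np.full(20, 3.0)})
        out = bias_test(placements)
        assert out.loc["p", "pvalue"] < 1e-6

    def test_empty_and_undersized_input(self):
        assert len(bias_test(pd.DataFrame())) == 0
        with pytest.warns(UserWarning, match="skipped"):
            out = bias_test(pd.DataFrame({"p": [0.1, 0.2]}))
        assert len(out) == 0
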