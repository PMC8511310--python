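"""TPM normalization, expression thresholds and the NB Wald test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicelight.expression_de import (
    ExpressionMatrix,
    bh_adjust,
    compare_de_fraction,
    counts_to_tpm,
    de_summary,
    expressed_mask,
    expression_summary,
    make_design,
    nb_wald_contrast,
    pathway_heatmap_matrix,
    size_factors,
)


def _counts(values, design):
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=[f"f{i}" for i in range(len(values))], columns=design.index),
        design=design,
        kind="counts",
    )


def _nb_matrix(rng, mu, dispersion, shape):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu), size=shape)


class TestTpm:
    def test_single_feature_gets_full_million(self):
        design = make_design(("A",), 2)
        tpm = counts_to_tpm(_counts([[10, 20]], design), {"f0": 100})
        assert np.allclose(tpm.values.to_numpy(), 1e6)

    def test_length_scaling_two_thirds_one_third(self):
        design = make_design(("A",), 1)
        tpm = counts_to_tpm(_counts([[50], [50]], design), {"f0": 100, "f1": 200})
        assert np.allclose(tpm.values["A_1"], [2e6 / 3, 1e6 / 3])

    def test_columns_sum_to_a_million(self, rng):
        design = make_design(("A", "B"), 3)
        X = rng.integers(0, 500, size=(40, 6))
        lengths = {f"f{i}": int(rng.integers(100, 2000)) for i in range(40)}
        tpm = counts_to_tpm(_counts(X, design), lengths)
        assert np.allclose(tpm.values.sum(axis=0), 1e6)

    def test_zero_count_column_warns_and_zeroes(self):
        design = make_design(("A",), 2)
        X = np.array([[5, 0], [3, 0]])
        with pytest.warns(UserWarning, match="zero total counts"):
            tpm = counts_to_tpm(_counts(X, design), {"f0": 100, "f1": 100})
        assert (tpm.values["A_2"] == 0).all()


class TestExpressedMask:
    def test_cutoff_is_strict(self):
        design = make_design(("A",), 1)
        values = pd.DataFrame(
            {"A_1": [1.0, 1.01, 0.0, 1e6 - 2.01]}, index=["a", "b", "c", "d"]
        )
        tpm = ExpressionMatrix(values=values, design=design, kind="tpm")
        assert list(expressed_mask(tpm)["A_1"]) == [False, True, False, True]

    def test_counts_matrix_rejected(self):
        design = make_design(("A",), 1)
        em = _counts([[3]], design)
        with pytest.raises(ValueError, match="TPM"):
            expressed_mask(em)


class TestExpressionSummary:
    def test_median_over_expressed_only(self):
        design = make_design(("A",), 1)
        values = pd.DataFrame({"A_1": [2.0, 4.0, 6.0, 0.5]}, index=list("abcd"))
        tpm = ExpressionMatrix(values=values, design=design, kind="tpm")
        out = expression_summary(tpm, {f: "x" for f in "abcd"})
        row = out.iloc[0]
        assert row["n_expressed"] == 3 and row["median_tpm_expressed"] == 4.0

    def test_no_expressed_features_reports_nan(self):
        design = make_design(("A",), 2)
        values = pd.DataFrame(np.zeros((3, 2)), index=list("abc"), columns=design.index)
        tpm = ExpressionMatrix(values=values, design=design, kind="tpm")
        out = expression_summary(tpm, {f: "x" for f in "abc"})
        assert out.iloc[0]["n_expressed"] == 0
        assert np.isnan(out.iloc[0]["median_tpm_expressed"])

    def test_condition_mean_aggregation(self):
        # replicate means 1.5 and 0.9: only the first feature is expressed
        design = make_design(("A",), 2)
        values = pd.DataFrame(
            {"A_1": [1.0, 0.8], "A_2": [2.0, 1.0]}, index=["hi", "lo"]
        )
        tpm = ExpressionMatrix(values=values, design=design, kind="tpm")
        out = expression_summary(tpm, {"hi": "x", "lo": "x"})
        assert out.iloc[0]["n_expressed"] == 1


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        design = make_design(("A",), 2)
        em = _counts([[10, 10], [30, 30]], design)
        assert np.allclose(size_factors(em), [1.0, 1.0])

    def test_doubled_sample_gives_sqrt2_split(self):
        design = make_design(("A",), 2)
        em = _counts([[10, 20], [30, 60], [7, 14]], design)
        assert np.allclose(size_factors(em), [1 / np.sqrt(2), np.sqrt(2)])

    def test_scaling_one_sample_scales_its_factor(self, rng):
        design = make_design(("A", "B"), 2)
        X = rng.integers(1, 200, size=(50, 4))
        base = size_factors(_counts(X, design))
        X2 = X.copy()
        X2[:, 2] *= 3
        scaled = size_factors(_counts(X2, design))
        ratio = scaled.to_numpy() / base.to_numpy()
        # the tripled sample's factor moves 3x relative to the others
        assert np.isclose(ratio[2] / ratio[0], 3.0)

    def test_upper_quartile_fallback_warns(self):
        design = make_design(("A",), 2)
        # every feature has a zero somewhere
        em = _counts([[0, 10], [10, 0]], design)
        with pytest.warns(UserWarning, match="upper-quartile"):
            s = size_factors(em)
        assert (s > 0).all()


class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_dominates_raw_p_and_matches_closed_form(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            adj = bh_adjust(p)
            assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
            # independent closed form: padj_i = min_{p_(j) >= p_i} p_(j) * n / j
            order = np.argsort(p)
            ranks = np.empty_like(order)
            ranks[order] = np.arange(1, len(p) + 1)
            expected = np.array(
                [
                    min(
                        p[j] * len(p) / ranks[j]
                        for j in range(len(p))
                        if p[j] >= p[i] - 1e-15
                    )
                    for i in range(len(p))
                ]
            )
            assert np.allclose(adj, np.minimum(expected, 1.0))

    def test_nan_propagates_and_is_excluded_from_n(self):
        out = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], [0.02, 0.02])  # n = 2, not 3


class TestChiSquared:
    def test_equal_fractions_give_null(self):
        chi2, p = compare_de_fraction(10, 100, 10, 100)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_pearson_statistic(self):
        chi2, p = compare_de_fraction(20, 100, 10, 100)
        assert chi2 == pytest.approx(3.9216, abs=1e-4)
        assert p == pytest.approx(stats.chi2.sf(3.9216, df=1), abs=1e-4)

    def test_symmetric_under_class_swap(self):
        a = compare_de_fraction(25, 80, 11, 60)
        b = compare_de_fraction(11, 60, 25, 80)
        assert a == pytest.approx(b)

    def test_degenerate_margin(self):
        assert compare_de_fraction(0, 50, 0, 70) == (0.0, 1.0)


class TestNbWald:
    def test_all_zero_feature_is_ns_with_p_one(self, rng):
        design = make_design(("A", "B"), 3)
        X = _nb_matrix(rng, 50.0, 0.1, (20, 6))
        X[0, :] = 0
        res = nb_wald_contrast(_counts(X, design), ("A", "B"))
        row = res.loc["f0"]
        assert row["wald_p"] == 1.0 and row["direction"] == "ns" and row["log2fc"] == 0.0

    def test_null_calibration_small(self, rng):
        design = make_design(("A", "B"), 3)
        X = _nb_matrix(rng, np.full((2000, 6), 80.0), 0.1, None)
        res = nb_wald_contrast(_counts(X, design), ("A", "B"))
        assert (res["padj"] < 0.05).mean() <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / 2000)

    def test_recovers_planted_fold_change(self, rng):
        # 500 planted features at log2fc = 2 embedded in a null majority so
        # size-factor normalization stays anchored on unchanged features
        design = make_design(("A", "B"), 3)
        mu = np.full((2500, 6), 100.0)
        mu[:500, :3] *= 4.0
        X = _nb_matrix(rng, mu, 0.1, None)
        res = nb_wald_contrast(_counts(X, design), ("A", "B"))
        assert abs(res["log2fc"].iloc[:500].mean() - 2.0) <= 0.3

    def test_stable_under_integer_rescaling_of_a_sample(self, rng):
        """Doubling one sample's counts is absorbed by its size factor;
        median-of-ratios leaves normalized counts equal up to one global
        scale, so estimates move only at pseudocount order."""
        design = make_design(("A", "B"), 3)
        X = _nb_matrix(rng, 60.0, 0.1, (100, 6))
        base = nb_wald_contrast(_counts(X, design), ("A", "B"))
        X2 = X.copy()
        X2[:, 0] *= 2
        rescaled = nb_wald_contrast(_counts(X2, design), ("A", "B"))
        assert np.allclose(base["log2fc"], rescaled["log2fc"], atol=0.02)
        assert (base["direction"] == rescaled["direction"]).all()

    def test_missing_condition_rejected(self, rng):
        design = make_design(("A", "B"), 3)
        X = _nb_matrix(rng, 50.0, 0.1, (10, 6))
        with pytest.raises(KeyError):
            nb_wald_contrast(_counts(X, design), ("A", "Z"))


class TestDeSummary:
    def test_planted_directions_recovered(self, rng):
        # six replicates: high-power settings so every strong effect clears BH
        design = make_design(("A", "B"), 6)
        mu = np.full((300, 12), 200.0)
        mu[:30, :6] *= 16.0  # 30 strong up in A
        mu[30:40, :6] /= 16.0  # 10 strong down
        X = _nb_matrix(rng, mu, 0.05, None)
        res = nb_wald_contrast(_counts(X, design), ("A", "B"))
        labels = {f"f{i}": ("IR_isoform" if i < 50 else "non_AS_gene") for i in range(300)}
        summary = de_summary({"A_vs_B": res}, labels)
        ir = summary[summary["class"] == "IR_isoform"].iloc[0]
        assert ir["n_up"] == 30 and ir["n_down"] == 10
        assert (summary["n_up"] + summary["n_down"] <= summary["n_total"]).all()

    def test_no_significance_gives_zeros(self):
        res = pd.DataFrame(
            {
                "log2fc": [0.1, -0.2],
                "padj": [0.9, 0.8],
                "significant": [False, False],
                "direction": ["ns", "ns"],
            },
            index=["f0", "f1"],
        )
        out = de_summary({"c": res}, {"f0": "x", "f1": "x"})
        assert out.iloc[0]["n_up"] == 0 and out.iloc[0]["n_down"] == 0


class TestHeatmap:
    def _ann_two_isoforms(self):
        from splicelight.annotation_io import AnnotationSet, GeneModel, GenomicInterval, TranscriptModel

        ref = TranscriptModel("g1.ref", "g1", (GenomicInterval("chr1", 0, 600, "+"),))
        alt = TranscriptModel("g1.alt", "g1", (GenomicInterval("chr1", 100, 600, "+"),))
        return AnnotationSet(genes={"g1": GeneModel("g1", [ref, alt], "g1.ref")})

    def test_shape_and_ref_flag(self, rng):
        design = make_design(("FR", "R", "B", "WL", "D"), 2)
        values = pd.DataFrame(
            rng.uniform(0, 100, size=(2, 10)),
            index=["g1.ref", "g1.alt"],
            columns=design.index,
        )
        tpm = ExpressionMatrix(values=values, design=design, kind="tpm")
        mat, annot = pathway_heatmap_matrix(tpm, ["g1"], self._ann_two_isoforms())
        assert mat.shape == (2, 5)
        assert annot.set_index("transcript_id")["is_ref"].to_dict() == {
            "g1.ref": True,
            "g1.alt": False,
        }
        assert "g1.ref.ref" in mat.index  # reference rows flagged by suffix

    def test_constant_row_z_scores_to_zero(self):
        design = make_design(("A", "B"), 1)
        values = pd.DataFrame(
            {"A_1": [5.0, 1.0], "B_1": [5.0, 9.0]}, index=["g1.ref", "g1.alt"]
        )
        tpm = ExpressionMatrix(values=values, design=design, kind="tpm")
        mat, _ = pathway_heatmap_matrix(tpm, ["g1"], self._ann_two_isoforms())
        assert np.allclose(mat.loc["g1.ref.ref"], 0.0)

    def test_recompute_from_raw_tpm(self, rng):
        design = make_design(("A", "B", "C"), 2)
        values = pd.DataFrame(
            rng.uniform(0, 50, size=(2, 6)),
            index=["g1.ref", "g1.alt"],
            columns=design.index,
        )
        tpm = ExpressionMatrix(values=values, design=design, kind="tpm")
        mat, _ = pathway_heatmap_matrix(tpm, ["g1"], self._ann_two_isoforms())
        # independent recomputation: condition means of log2(TPM+1), z-scored
        for row_label, feature in (("g1.ref.ref", "g1.ref"), ("g1.alt", "g1.alt")):
            raw = np.log2(
                np.array(
                    [values.loc[feature, [f"{c}_1", f"{c}_2"]].mean() for c in "ABC"]
                )
                + 1
            )
            z = (raw - raw.mean()) / raw.std()
            assert np.allclose(mat.loc[row_label], z)

    def test_missing_gene_warns(self, rng):
        design = make_design(("A",), 1)
        values = pd.DataFrame({"A_1": [1.0]}, index=["g1.ref"])
        tpm = ExpressionMatrix(values=values, design=design, kind="tpm")
        with pytest.warns(UserWarning, match="not in annotation"):
            mat, _ = pathway_heatmap_matrix(tpm, ["nope"], self._ann_two_isoforms())
        assert mat.empty


@pytest.fixture
def rng():
    return np.random.default_rng(31)
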