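import numpy as np
import pandas as pd
import pytest

from lsea.diffab import (
    MedianOfRatiosNormalizer,
    NormalizationError,
    estimate_dispersion,
    normalize,
    rank_metric,
    size_factors,
    vst,
    wald_test,
)

from _oracles import step_up_bh
from conftest import nb_counts


def frame(rows, samples=None):
    arr = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"l{i}" for i in range(arr.shape[0])],
        columns=samples or [f"s{j}" for j in range(arr.shape[1])],
    )


class TestSizeFactors:
    def test_hand_example(self):
        s = size_factors(frame([[2, 4], [6, 12]]))
        np.testing.assert_allclose(
            s.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], atol=1e-9
        )

    def test_identical_columns_give_ones(self):
        s = size_factors(frame([[3, 3, 3], [7, 7, 7]]))
        np.testing.assert_allclose(s.to_numpy(), 1.0, atol=1e-12)

    def test_scale_equivariance_of_factor_ratios(self):
        # scaling one column by c multiplies its size factor by c relative
        # to the others; absolute factors are only defined up to the
        # geometric-mean gauge because the per-lipid geometric means also
        # absorb c^(1/m)
        base = frame(np.random.default_rng(0).uniform(1, 100, (20, 4)))
        s0 = size_factors(base)
        scaled = base.copy()
        scaled.iloc[:, 2] *= 5.0
        s1 = size_factors(scaled)
        np.testing.assert_allclose(
            (s1 / s1.iloc[0]).to_numpy(),
            (s0 * [1, 1, 5, 1] / s0.iloc[0]).to_numpy(),
            rtol=1e-12,
        )

    def test_zero_rows_excluded_from_reference(self):
        df = frame([[2, 4], [6, 12], [0, 5]])
        np.testing.assert_allclose(
            size_factors(df).to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], atol=1e-9
        )

    def test_empty_reference_is_an_error(self):
        with pytest.raises(NormalizationError, match="pseudo-reference"):
            size_factors(frame([[0, 1], [1, 0]]))

    def test_normalization_is_a_fixed_point(self):
        rng = np.random.default_rng(3)
        df = frame(rng.uniform(1, 500, (30, 6)))
        normed = normalize(df)
        np.testing.assert_allclose(
            size_factors(normed).to_numpy(), 1.0, atol=1e-9
        )


class TestNormalizeAndVst:
    def test_columns_equalized_on_hand_example(self):
        out = normalize(frame([[2, 4], [6, 12]]))
        np.testing.assert_allclose(out.iloc[0], 2 * np.sqrt(2), rtol=1e-12)
        np.testing.assert_allclose(out.iloc[1], 6 * np.sqrt(2), rtol=1e-12)

    def test_unit_factors_are_identity_and_zero_stays_zero(self):
        df = frame([[0, 5], [2, 3]])
        out = normalize(df, pd.Series([1.0, 1.0], index=df.columns))
        pd.testing.assert_frame_equal(out, df)
        assert normalize(df).loc["l0", "s0"] == 0.0

    def test_vst_values_and_monotonicity(self):
        df = frame([[0, 3]])
        out = vst(df)
        assert out.loc["l0", "s0"] == 0.0  # log2(0 + 1)
        assert out.loc["l0", "s1"] == 2.0  # log2(3 + 1)
        x = np.sort(np.random.default_rng(1).uniform(0, 1e4, 100))
        v = vst(frame([x])).to_numpy().ravel()
        assert (np.diff(v) > 0).all()

    def test_sklearn_transformer_api(self):
        X = np.random.default_rng(0).uniform(1, 100, (6, 10))
        norm = MedianOfRatiosNormalizer().fit(X)
        out = norm.transform(X)
        assert out.shape == X.shape
        params = norm.get_params()
        assert params == {}  # stateless constructor
        np.testing.assert_allclose(
            MedianOfRatiosNormalizer().fit_transform(X), out
        )


class TestDispersion:
    def test_poisson_counts_give_near_zero_alpha(self):
        rng = np.random.default_rng(10)
        counts = frame(nb_counts(rng, 100.0, 0.0, (200, 100)))
        groups = pd.Series(["A"] * 50 + ["B"] * 50, index=counts.columns)
        assert estimate_dispersion(counts, groups).mean() < 0.05

    def test_nb_alpha_recovered_in_median(self):
        rng = np.random.default_rng(11)
        counts = frame(nb_counts(rng, 100.0, 0.5, (200, 100)))
        groups = pd.Series(["A"] * 50 + ["B"] * 50, index=counts.columns)
        med = estimate_dispersion(counts, groups).median()
        assert 0.3 <= med <= 0.7

    def test_constant_counts_floor_at_zero(self):
        counts = frame([[5, 5, 5, 5]])
        groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        assert estimate_dispersion(counts, groups).iloc[0] == 0.0

    def test_single_replicate_group_rejected(self):
        counts = frame([[5, 5, 5]])
        groups = pd.Series(["A", "A", "B"], index=counts.columns)
        with pytest.raises(ValueError, match="n >= 2"):
            estimate_dispersion(counts, groups)


class TestWald:
    def test_identical_groups_are_null(self):
        df = frame([[10, 20, 10, 20], [5, 8, 5, 8]])
        groups = pd.Series(["A", "A", "B", "B"], index=df.columns)
        res = wald_test(df, groups)
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-12)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(5)
        df = frame(nb_counts(rng, 150.0, 0.2, (40, 8)))
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=df.columns)
        fwd = wald_test(df, groups, level_a="A", level_b="B")
        rev = wald_test(df, groups, level_a="B", level_b="A")
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)

    def test_bh_matches_step_up_oracle(self):
        rng = np.random.default_rng(6)
        df = frame(nb_counts(rng, 150.0, 0.2, (50, 12)))
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=df.columns)
        res = wald_test(df, groups)
        expected = step_up_bh(list(res["p"]))
        np.testing.assert_allclose(res["q"], expected, atol=1e-12)

    def test_all_zero_lipid_untested_and_outside_bh_family(self):
        rng = np.random.default_rng(7)
        arr = nb_counts(rng, 100.0, 0.1, (10, 8))
        arr[3] = 0.0
        df = frame(arr)
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=df.columns)
        res = wald_test(df, groups)
        assert np.isnan(res.loc["l3", "p"]) and np.isnan(res.loc["l3", "q"])
        tested = res["p"].dropna()
        np.testing.assert_allclose(
            res["q"].dropna(), step_up_bh(list(tested)), atol=1e-12
        )

    def test_zero_mean_group_keeps_log2fc_finite(self):
        arr = np.array([[0, 0, 0, 50, 60, 55]], dtype=float)
        df = frame(arr)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=df.columns)
        res = wald_test(df, groups, size_factors=pd.Series(1.0, index=df.columns))
        assert np.isfinite(res["log2fc"].iloc[0])
        assert res["log2fc"].iloc[0] > 5  # ~log2(55 / 0.5)


class TestRankMetric:
    def make_result(self):
        return pd.DataFrame(
            {
                "log2fc": [1.0, -0.5, 1.0, np.nan],
                "wald_z": [2.0, -1.0, 2.0, np.nan],
                "p": [0.04, 0.3, 0.04, np.nan],
            },
            index=pd.Index(["b", "c", "a", "d"], name="lipid"),
        )

    def test_descending_with_lexicographic_ties(self):
        ranks = rank_metric(self.make_result())
        assert list(ranks["lipid"]) == ["a", "b", "c"]
        assert list(ranks["score"]) == [2.0, 2.0, -1.0]

    def test_untested_excluded(self):
        assert "d" not in set(rank_metric(self.make_result())["lipid"])

    def test_alternative_metrics(self):
        res = self.make_result()
        assert list(rank_metric(res, "log2fc")["score"]) == [1.0, 1.0, -0.5]
        signed = rank_metric(res, "signed_logp")
        assert signed["score"].iloc[0] > 0 > signed["score"].iloc[-1]

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            rank_metric(self.make_result(), "foo")
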