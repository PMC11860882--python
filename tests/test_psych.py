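"""Reliability and validity statistics against naive loop-based oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from carescape.errors import ComputationError, ValidationError
from carescape.psych import (
    bartlett_sphericity,
    corrected_item_total,
    cronbach_alpha,
    kmo,
    scale_report,
)
from carescape.scales import DEFAULT_SCALES

from conftest import exact_corr_sample


# ---------------------------------------------------------------------------
# naive oracles written with explicit sums, independent of the implementation

def naive_alpha(X):
    n, k = X.shape
    item_vars = [np.var(X[:, i], ddof=1) for i in range(k)]
    total = X.sum(axis=1)
    return k / (k - 1) * (1 - sum(item_vars) / np.var(total, ddof=1))


def naive_item_total(X, idx):
    item = X[:, idx]
    rest = sum(X[:, j] for j in range(X.shape[1]) if j != idx)
    return float(np.corrcoef(item, rest)[0, 1])


def naive_kmo(X):
    R = np.corrcoef(X, rowvar=False)
    Q = np.linalg.inv(R)
    k = R.shape[0]
    r2 = p2 = 0.0
    for i in range(k):
        for j in range(k):
            if i != j:
                r2 += R[i, j] ** 2
                p2 += (Q[i, j] / math.sqrt(Q[i, i] * Q[j, j])) ** 2
    return r2 / (r2 + p2)


def naive_bartlett(X):
    n, k = X.shape
    R = np.corrcoef(X, rowvar=False)
    chi2 = -(n - 1 - (2 * k + 5) / 6) * math.log(np.linalg.det(R))
    return chi2, k * (k - 1) // 2


class TestCronbachAlpha:
    def test_identical_items_give_one(self):
        x = np.arange(10.0)
        assert cronbach_alpha(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_independent_items_near_zero(self, rng):
        X = rng.standard_normal((20_000, 2))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_compound_symmetry_closed_form(self, rng):
        # three standardized items with all pairwise correlations exactly 0.5
        R = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        X = exact_corr_sample(200, R, rng)
        # k*r / (1 + (k-1)*r) with k=3, r=0.5
        assert cronbach_alpha(X) == pytest.approx(0.75, abs=1e-10)

    def test_matches_naive_oracle(self, rng):
        X = rng.integers(1, 6, size=(50, 5)).astype(float)
        assert cronbach_alpha(X) == pytest.approx(naive_alpha(X), abs=1e-10)

    @given(st.floats(min_value=0.1, max_value=10.0),
           st.floats(min_value=-5.0, max_value=5.0))
    def test_common_rescaling_leaves_alpha_unchanged(self, a, b):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((40, 4)) + rng.standard_normal((40, 1))
        assert cronbach_alpha(a * X + b) == pytest.approx(
            cronbach_alpha(X), rel=1e-9
        )

    def test_standardized_alpha_ignores_per_item_scaling(self, rng):
        X = rng.standard_normal((60, 4)) + rng.standard_normal((60, 1))
        scales = np.array([1.0, 3.0, 0.5, 7.0])
        assert cronbach_alpha(X * scales, standardized=True) == pytest.approx(
            cronbach_alpha(X, standardized=True), abs=1e-10
        )

    def test_zero_variance_signalled(self):
        with pytest.raises(ComputationError):
            cronbach_alpha(np.ones((10, 3)))


class TestCorrectedItemTotal:
    def test_item_equal_to_rest_sum(self, rng):
        rest = rng.standard_normal((100, 2))
        X = np.column_stack([rest.sum(axis=1), rest])
        assert corrected_item_total(X, 0) == pytest.approx(1.0)

    def test_independent_item_near_zero(self, rng):
        X = rng.standard_normal((50_000, 4))
        assert abs(corrected_item_total(X, 0)) < 0.02

    def test_matches_naive_oracle(self, rng):
        X = rng.integers(1, 6, size=(200, 4)).astype(float)
        for idx in range(4):
            assert corrected_item_total(X, idx) == pytest.approx(
                naive_item_total(X, idx), abs=1e-12
            )

    def test_needs_three_items(self, rng):
        with pytest.raises(ValidationError):
            corrected_item_total(rng.standard_normal((10, 2)), 0)


class TestKMO:
    def test_two_items_give_half(self, rng):
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        X = exact_corr_sample(50, R, rng)
        assert kmo(X) == pytest.approx(0.5, abs=1e-10)

    def test_compound_symmetry_closed_form(self, rng):
        # r=0.5, k=3: inverse has q_ii=1.5, q_ij=-0.5 -> partials 1/3,
        # KMO = 6*0.25 / (6*0.25 + 6/9)
        R = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        X = exact_corr_sample(120, R, rng)
        expected = 1.5 / (1.5 + 6.0 / 9.0)
        assert kmo(X) == pytest.approx(expected, abs=1e-10)
        assert kmo(X) == pytest.approx(naive_kmo(X), abs=1e-12)

    def test_matches_naive_oracle_on_likert_data(self, survey):
        X = survey[list(DEFAULT_SCALES[0].item_ids)].to_numpy(float)
        assert kmo(X) == pytest.approx(naive_kmo(X), abs=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            X = rng.standard_normal((30, 5)) + 0.5 * rng.standard_normal((30, 1))
            assert 0.0 <= kmo(X) <= 1.0

    def test_singular_matrix_reported(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, x, rng.standard_normal(30)])
        with pytest.raises(ComputationError, match="singular|collinear"):
            kmo(X)


class TestBartlett:
    def test_exact_identity_correlation_gives_zero(self, rng):
        X = exact_corr_sample(80, np.eye(3), rng)
        chi2, df, p = bartlett_sphericity(X)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 3
        assert p == pytest.approx(1.0)

    def test_closed_form_compound_symmetry(self, rng):
        # n=100, k=3, r=0.5: det R = 0.5, chi2 = -(99 - 11/6) ln 0.5 = 67.35
        R = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        X = exact_corr_sample(100, R, rng)
        chi2, df, _ = bartlett_sphericity(X)
        assert chi2 == pytest.approx(-(99 - 11 / 6) * math.log(0.5), abs=1e-10)
        assert chi2 == pytest.approx(67.35, abs=0.01)
        assert df == 3

    def test_matches_naive_oracle(self, survey):
        X = survey[list(DEFAULT_SCALES[2].item_ids)].to_numpy(float)
        chi2, df, _ = bartlett_sphericity(X)
        exp_chi2, exp_df = naive_bartlett(X)
        assert chi2 == pytest.approx(exp_chi2, abs=1e-10)
        assert df == exp_df

    def test_needs_more_rows_than_items(self, rng):
        with pytest.raises(ValidationError):
            bartlett_sphericity(rng.standard_normal((3, 3)))


class TestScaleReport:
    def test_report_fields_consistent(self, survey):
        for scale, k in zip(DEFAULT_SCALES, (4, 3, 4)):
            rep = scale_report(survey, scale)
            assert rep.bartlett_df == k * (k - 1) // 2
            assert set(rep.item_stats) == set(scale.item_ids)
            assert rep.n == len(survey)
            assert 0.0 <= rep.kmo <= 1.0
            assert rep.alpha <= 1.0

    def test_listwise_deletion(self, survey):
        damaged = survey.copy()
        damaged.loc[damaged.index[:5], "healthcare"] = np.nan
        rep = scale_report(damaged, DEFAULT_SCALES[1])
        assert rep.n == len(survey) - 5

    def test_missing_item_column_rejected(self, survey):
        from carescape.scales import ScaleDefinition
        bogus = ScaleDefinition("bogus", ("healthcare", "not_a_column"))
        with pytest.raises(ValidationError):
            scale_report(survey, bogus)

    def test_cross_check_against_pingouin(self, survey):
        pingouin = pytest.importorskip("pingouin")
        for scale in DEFAULT_SCALES:
            ours = cronbach_alpha(survey[list(scale.item_ids)].to_numpy(float))
            theirs = pingouin.cronbach_alpha(
                data=survey[list(scale.item_ids)]
            )[0]
            assert ours == pytest.approx(theirs, abs=1e-10)
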