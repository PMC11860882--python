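"""Descriptives, price tiers, ANOVA and logistic odds ratios."""

import numpy as np
import pandas as pd
import pytest

from carescape.demand import (
    aging_rates,
    attribute_logistic,
    cluster_prices,
    demand_summary,
    dichotomize_scale,
    distance_demand,
    group_anova,
    overall_mean_from_indicators,
)
from carescape.errors import ComputationError, ValidationError
from carescape.scales import ALL_ITEMS, DEFAULT_SCALES, walk_column


def naive_anova_f(samples):
    """Explicit sums-of-squares oracle for one-way fixed-effects ANOVA."""
    allv = np.concatenate(samples)
    grand = allv.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b = len(samples) - 1
    df_w = len(allv) - len(samples)
    return (ss_between / df_b) / (ss_within / df_w)


class TestDemandSummary:
    def test_published_indicator_means_give_overall(self):
        overall = overall_mean_from_indicators([2.72, 2.86, 3.46], [4, 3, 4])
        assert round(overall, 2) == 3.03

    def test_constant_survey_gives_constant_means(self):
        df = pd.DataFrame({i: [3] * 10 for i in ALL_ITEMS})
        s = demand_summary(df)
        assert all(v == 3.0 for v in s.item_means.values())
        assert s.overall_mean == 3.0

    def test_overall_equals_plain_mean_of_item_means(self, survey):
        s = demand_summary(survey)
        assert s.overall_mean == pytest.approx(
            np.mean(list(s.item_means.values())), abs=1e-12
        )

    def test_overall_invariant_to_scale_ordering(self, survey):
        s1 = demand_summary(survey, DEFAULT_SCALES)
        s2 = demand_summary(survey, tuple(reversed(DEFAULT_SCALES)))
        assert s1.overall_mean == pytest.approx(s2.overall_mean, abs=1e-12)

    def test_empty_survey_rejected(self):
        df = pd.DataFrame({i: [np.nan] for i in ALL_ITEMS})
        with pytest.raises(ValidationError):
            demand_summary(df)


class TestDistanceDemand:
    def test_degenerate_single_category(self):
        df = pd.DataFrame({walk_column("healthcare"): [1] * 20})
        props = distance_demand(df, ["healthcare"])
        assert props["healthcare"] == (1.0, 0.0, 0.0)

    def test_direct_proportions(self):
        codes = [1] * 10 + [2] * 20 + [3] * 70
        df = pd.DataFrame({walk_column("canteen"): codes})
        assert distance_demand(df, ["canteen"])["canteen"] == (0.10, 0.20, 0.70)

    def test_matches_naive_tabulation(self, survey):
        props = distance_demand(survey)
        for item, p in props.items():
            col = survey[walk_column(item)]
            expected = [float((col == c).sum()) / len(col) for c in (1, 2, 3)]
            assert np.allclose(p, expected)
            assert sum(p) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_codes_rejected(self):
        df = pd.DataFrame({walk_column("canteen"): [1, 2, 4]})
        with pytest.raises(ValidationError):
            distance_demand(df, ["canteen"])


class TestClusterPrices:
    def test_separated_clusters_recovered(self):
        prices = np.array([10, 11, 12, 50, 51, 52, 90, 91, 92]) * 1000.0
        pc = cluster_prices(prices, seed=0)
        assert pc.centers == pytest.approx((11_000, 51_000, 91_000))
        assert list(pc.assignments) == ["low"] * 3 + ["medium"] * 3 + ["high"] * 3
        assert pc.boundaries[0] == pytest.approx((12_000 + 50_000) / 2)

    def test_equal_prices_rejected(self):
        with pytest.raises(ValidationError):
            cluster_prices(np.full(20, 40_000.0), seed=0)

    def test_local_optimality_against_random_partitions(self, rng):
        prices = rng.uniform(20_000, 80_000, size=60)
        pc = cluster_prices(prices, seed=1)
        tiers = {t: prices[pc.assignments == t] for t in pc.tier_labels}
        wss = sum(((v - v.mean()) ** 2).sum() for v in tiers.values() if len(v))
        for _ in range(1000):
            labels = rng.integers(0, 3, size=len(prices))
            if len(np.unique(labels)) < 3:
                continue
            alt = sum(
                ((prices[labels == g] - prices[labels == g].mean()) ** 2).sum()
                for g in range(3)
            )
            assert wss <= alt + 1e-9


class TestGroupAnova:
    def test_identical_groups_give_zero_f(self):
        df = pd.DataFrame(
            {"g": ["a"] * 3 + ["b"] * 3 + ["c"] * 3, "item": [1, 2, 3] * 3}
        )
        rep = group_anova(df, "g", items=["item"])
        assert rep.table.loc[0, "F"] == pytest.approx(0.0)
        assert rep.table.loc[0, "p"] == pytest.approx(1.0)

    def test_hand_computed_f(self):
        df = pd.DataFrame(
            {
                "g": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
                "item": [1, 2, 3, 2, 3, 4, 3, 4, 5],
            }
        )
        rep = group_anova(df, "g", items=["item"])
        assert rep.table.loc[0, "F"] == pytest.approx(3.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_sums_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "g": rng.choice(list("abcde"), size=200),
                "item": rng.integers(1, 6, size=200).astype(float),
            }
        )
        rep = group_anova(df, "g", items=["item"])
        samples = [df.loc[df.g == g, "item"].to_numpy() for g in sorted(df.g.unique())]
        assert rep.table.loc[0, "F"] == pytest.approx(
            naive_anova_f(samples), abs=1e-10
        )

    def test_power_under_one_sd_shift(self):
        detected = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "g": ["a"] * 100 + ["b"] * 100,
                    "item": np.concatenate(
                        [rng.normal(0, 1, 100), rng.normal(1.0, 1, 100)]
                    ),
                }
            )
            rep = group_anova(df, "g", items=["item"])
            detected += bool(rep.table.loc[0, "p"] < 0.05)
        assert detected / reps >= 0.95

    def test_small_group_rejected(self):
        df = pd.DataFrame({"g": ["a", "a", "b"], "item": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError, match="b"):
            group_anova(df, "g", items=["item"])


class TestAttributeLogistic:
    @staticmethod
    def _two_by_two():
        rows = (
            [(1, 1)] * 20 + [(1, 0)] * 10 + [(0, 1)] * 10 + [(0, 0)] * 20
        )
        return pd.DataFrame(rows, columns=["x", "y"])

    def test_saturated_or_equals_cross_product_ratio(self):
        df = self._two_by_two()
        rep = attribute_logistic(df, "y", ["x"])
        assert rep.table.loc[0, "OR"] == pytest.approx(4.0, abs=1e-8)

    def test_independent_predictor_or_near_one(self, rng):
        df = pd.DataFrame(
            {"x": rng.integers(0, 2, 20_000), "y": rng.integers(0, 2, 20_000)}
        )
        rep = attribute_logistic(df, "y", ["x"])
        assert rep.table.loc[0, "OR"] == pytest.approx(1.0, abs=0.1)

    def test_wald_columns_consistent(self):
        rep = attribute_logistic(self._two_by_two(), "y", ["x"])
        row = rep.table.loc[0]
        assert row["z"] == pytest.approx(row["coef"] / row["error"], abs=1e-10)
        assert row["OR"] == pytest.approx(np.exp(row["coef"]), abs=1e-10)

    def test_separation_reported(self):
        df = pd.DataFrame({"x": [0] * 10 + [1] * 10, "y": [0] * 10 + [1] * 10})
        with pytest.raises(ComputationError):
            attribute_logistic(df, "y", ["x"])

    def test_dichotomized_scale_outcome(self, survey):
        rep = attribute_logistic(survey, "life_care")
        assert set(rep.table["attribute"]) == {"self_care", "income", "education"}
        assert (rep.table["OR"] > 0).all()

    def test_dichotomize_threshold(self, survey):
        y = dichotomize_scale(survey, DEFAULT_SCALES[0], threshold=3.0)
        means = survey[list(DEFAULT_SCALES[0].item_ids)].mean(axis=1)
        assert ((means >= 3.0).astype(int) == y).all()

    def test_unknown_outcome_rejected(self, survey):
        with pytest.raises(ValidationError):
            attribute_logistic(survey, "not_a_thing")


class TestAgingRates:
    def test_direct_ratio(self):
        df = pd.DataFrame(
            {"community_id": ["c1"], "population": [1000], "older_population": [160]}
        )
        assert aging_rates(df)["aging_rate"].iloc[0] == pytest.approx(0.16)

    def test_zero_older_population(self):
        df = pd.DataFrame(
            {"community_id": ["c1"], "population": [1000], "older_population": [0]}
        )
        assert aging_rates(df)["aging_rate"].iloc[0] == 0.0

    def test_matches_naive_division(self, rng):
        df = pd.DataFrame(
            {
                "community_id": [f"c{i}" for i in range(10)],
                "population": rng.integers(100, 10_000, 10),
                "older_population": rng.integers(0, 100, 10),
            }
        )
        out = aging_rates(df)
        assert np.allclose(
            out["aging_rate"], df["older_population"] / df["population"]
        )

    def test_zero_population_rejected(self):
        df = pd.DataFrame(
            {"community_id": ["c1"], "population": [0], "older_population": [0]}
        )
        with pytest.raises(ValidationError):
            aging_rates(df)
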