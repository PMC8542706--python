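"""Statistics operations, including the published worked examples."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tavrseal.stats import (
    StepwiseModel,
    fisher_exact_2x2,
    group_summary,
    mann_whitney,
    pooled_t,
    pooled_t_from_summary,
    r_squared,
    stepwise_lm,
    univariate_screen,
)


class TestPooledT:
    @pytest.mark.parametrize("g1,g2,expected_p", [
        # total skirt malapposition %, BAV vs TAV
        ((22.7, 10.5, 26), (15.5, 9.8, 17), 0.030),
        # malapposed leaflet area mm^2
        ((71.8, 40.1, 26), (56.8, 30.1, 17), 0.195),
        # apposed leaflet area mm^2
        ((612.4, 154.3, 26), (611.5, 193.6, 17), 0.987),
    ])
    def test_published_summary_statistics(self, g1, g2, expected_p):
        # group summaries are printed to one decimal, so the recomputed p
        # can only be expected to match within half a unit of its last digit
        res = pooled_t_from_summary(*g1, *g2)
        assert res.p_value == pytest.approx(expected_p, abs=6e-4)

    def test_identical_groups(self):
        res = pooled_t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_zero_variance(self):
        assert pooled_t_from_summary(3.0, 0.0, 5, 3.0, 0.0, 5).p_value == 1.0

    def test_summary_form_matches_raw_form(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1.2, 15)
        raw = pooled_t(x, y)
        summ = pooled_t_from_summary(x.mean(), x.std(ddof=1), len(x),
                                     y.mean(), y.std(ddof=1), len(y))
        assert raw.p_value == pytest.approx(summ.p_value)
        assert raw.statistic == pytest.approx(summ.statistic)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_from_summary(1, 1, 1, 2, 1, 5)


class TestMannWhitney:
    def test_symmetric_samples(self):
        assert mann_whitney([1, 2], [1, 2]).p_value == pytest.approx(1.0)

    def test_fully_separated_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.reason == "exact"
        # 2 of C(6,3)=20 labelings are at least as extreme
        assert res.p_value == pytest.approx(0.1)

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=5)
        y = rng.normal(0.8, 1, size=6)
        res = mann_whitney(x, y)
        assert res.reason == "exact"
        pooled = np.concatenate([x, y])
        n1 = len(x)
        u_obs = sum(1 for xi in x for yj in y if xi > yj)
        mu = n1 * len(y) / 2
        count = 0
        total = 0
        for combo in itertools.combinations(range(len(pooled)), n1):
            xs = pooled[list(combo)]
            ys = np.delete(pooled, list(combo))
            u = sum(1 for xi in xs for yj in ys if xi > yj)
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
            total += 1
        assert res.p_value == pytest.approx(count / total)

    def test_exact_and_normal_paths_agree(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=10)
        y = rng.normal(0.3, 1, size=10)
        p_exact = mann_whitney(x, y).p_value
        p_norm = mann_whitney(x, y, exact_limit=0).p_value
        assert abs(p_exact - p_norm) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestFisherExact:
    def test_published_counts(self):
        # moderate-or-worse PVL: 5/26 BAV vs 1/17 TAV
        assert round(fisher_exact_2x2([[5, 21], [1, 16]]).p_value, 3) == 0.376
        # pacemaker implantation: 2/26 vs 2/17
        assert round(fisher_exact_2x2([[2, 24], [2, 15]]).p_value, 3) == 1.000

    def test_degenerate_margin(self):
        assert fisher_exact_2x2([[0, 10], [0, 10]]).p_value == 1.0
        assert fisher_exact_2x2([[0, 0], [0, 0]]).p_value == 1.0

    def test_same_margin_probabilities_sum_to_one(self):
        table = np.array([[5, 21], [1, 16]])
        row1, col1, n = table[0].sum(), table[:, 0].sum(), table.sum()
        probs = [sps.hypergeom.pmf(k, n, row1, col1)
                 for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)]
        assert sum(probs) == pytest.approx(1.0)

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


class TestRSquared:
    def test_definition_consequences(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert r_squared(x, x) == pytest.approx(1.0)
        assert r_squared(x, [-v for v in x]) == pytest.approx(1.0)

    def test_constructed_correlation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= (z @ x) / (x @ x) * x
        z /= z.std()
        y = 0.949 * x + np.sqrt(1 - 0.949**2) * z
        assert r_squared(y, x) == pytest.approx(0.949**2, abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1, 1, 1], [1, 2, 3])


class TestScreenAndStepwise:
    def _table(self, rng, n=43):
        bav = np.array([1] * 26 + [0] * 17)[:n]
        return pd.DataFrame({
            "bav": bav,
            "sizing_index": rng.normal(1.07, 0.09, n),
            "noise": rng.normal(size=n),
        })

    def test_outcome_as_candidate_is_retained(self):
        rng = np.random.default_rng(1)
        t = self._table(rng)
        t["y"] = 2 * t["sizing_index"] + rng.normal(0, 0.01, len(t))
        retained, pvals, _ = univariate_screen(t, "y", ["sizing_index"])
        assert retained == ["sizing_index"]
        assert pvals["sizing_index"] < 1e-6

    def test_constant_candidate_excluded_with_reason(self):
        rng = np.random.default_rng(1)
        t = self._table(rng)
        t["flat"] = 1.0
        t["y"] = rng.normal(size=len(t))
        retained, _, reasons = univariate_screen(t, "y", ["flat"])
        assert retained == []
        assert "constant" in reasons["flat"]

    def test_planted_effect_power(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = self._table(rng)
            t["y"] = t["noise"] + rng.normal(0, 0.5, len(t))
            retained, _, _ = univariate_screen(t, "y", ["noise"])
            hits += retained == ["noise"]
        assert hits >= 49  # slope 1 vs noise SD 0.5 at n=43 is near-certain

    def test_stepwise_recovers_planted_predictors(self):
        rng = np.random.default_rng(13)
        t = self._table(rng)
        t["y"] = (5.0 * t["bav"] - 20.0 * t["sizing_index"]
                  + rng.normal(0, 0.5, len(t)))
        model = stepwise_lm(t, "y", ["bav", "sizing_index", "noise"])
        assert set(model.terms) == {"bav", "sizing_index"}
        assert model.coefficients["bav"] == pytest.approx(5.0, abs=0.5)
        assert model.coefficients["sizing_index"] == pytest.approx(-20.0, abs=2.0)

    def test_stepwise_scaling_invariance(self):
        rng = np.random.default_rng(13)
        t = self._table(rng)
        t["y"] = 5.0 * t["bav"] - 20.0 * t["sizing_index"] + rng.normal(
            0, 0.5, len(t))
        base = stepwise_lm(t, "y", ["bav", "sizing_index", "noise"])
        t2 = t.copy()
        t2["sizing_index"] = t2["sizing_index"] * 1e6
        scaled = stepwise_lm(t2, "y", ["bav", "sizing_index", "noise"])
        assert set(scaled.terms) == set(base.terms)

    def test_no_signal_gives_intercept_only(self):
        rng = np.random.default_rng(3)
        t = self._table(rng)
        t["y"] = rng.normal(size=len(t))
        model = stepwise_lm(t, "y", ["noise"])
        assert isinstance(model, StepwiseModel)
        assert model.terms == []

    def test_perfect_predictor_recovered_within_1pct(self):
        rng = np.random.default_rng(8)
        t = self._table(rng)
        t["y"] = 3.0 * t["sizing_index"]
        model = stepwise_lm(t, "y", ["sizing_index"])
        assert model.terms == ["sizing_index"]
        assert model.coefficients["sizing_index"] == pytest.approx(3.0, rel=0.01)

    def test_collinear_candidate_dropped(self):
        rng = np.random.default_rng(8)
        t = self._table(rng)
        t["twin"] = t["sizing_index"] * 2.0
        t["y"] = 3.0 * t["sizing_index"] + rng.normal(0, 0.1, len(t))
        model = stepwise_lm(t, "y", ["sizing_index", "twin"])
        assert model.terms == ["sizing_index"]


class TestGroupSummary:
    def _table(self, bav_vals, tav_vals, var="x"):
        rows = []
        for i, v in enumerate(bav_vals):
            rows.append({"morphology": "BAV0" if i % 2 else "BAV1", var: v})
        for v in tav_vals:
            rows.append({"morphology": "TAV", var: v})
        return pd.DataFrame(rows)

    def test_identical_groups_give_p_near_one(self):
        vals = list(np.linspace(1, 10, 8))
        report = group_summary(self._table(vals, vals))
        assert report.loc[0, "p_value"] == pytest.approx(1.0, abs=0.05)

    def test_large_shift_is_detected(self):
        rng = np.random.default_rng(6)
        bav = rng.normal(11.1, 5.7, 26)
        tav = rng.normal(5.8, 2.8, 17)
        report = group_summary(self._table(list(bav), list(tav)))
        assert report.loc[0, "p_value"] < 0.05

    def test_categorical_row_uses_fisher(self):
        bav = [1] * 5 + [0] * 21
        tav = [1] * 1 + [0] * 16
        report = group_summary(self._table(bav, tav, var="pvl_high"),
                               categorical=["pvl_high"])
        assert report.loc[0, "test"] == "fisher_exact"
        assert round(report.loc[0, "p_value"], 3) == 0.376

    def test_empty_group_marked_not_computable(self):
        t = self._table([1.0, 2.0, 3.0, 4.0], [])
        report = group_summary(t)
        assert report.loc[0, "test"] == "not_computable"
        assert np.isnan(report.loc[0, "p_value"])
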