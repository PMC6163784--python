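"""Friedman/Wilcoxon tests, expression ratios, fold changes, growth rates."""

import math

import numpy as np
import pandas as pd
import pytest

from stainquant import (
    ExpressionMeasurement,
    compare_conditions,
    fold_change_normalize,
    friedman_test,
    generation_time,
    pfaffl_ratio,
    wilcoxon_signed_rank,
)
from stainquant.stats import exclude_extreme_outliers
from stainquant.synthetic import CohortSpec, simulate_cohort

from conftest import friedman_permutation_oracle, wilcoxon_signflip_oracle


class TestFriedman:
    def test_identical_conditions_no_signal(self):
        data = np.tile([[3.0, 3.0, 3.0]], (7, 1))
        res = friedman_test(data)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_exact_p_matches_permutation_oracle(self, rng):
        for _ in range(5):
            data = rng.normal(size=(7, 3))
            res = friedman_test(data, method="exact")
            oracle = friedman_permutation_oracle(data)
            assert res.pvalue == pytest.approx(oracle, abs=0.005)

    def test_condition_always_last(self, rng):
        data = rng.normal(size=(7, 3))
        data[:, 2] = data[:, :2].min(axis=1) - 1.0  # condition C ranked last
        res = friedman_test(data, method="exact")
        assert res.pvalue == pytest.approx(friedman_permutation_oracle(data), abs=0.005)

    def test_rank_invariance_under_monotone_transform(self, rng):
        data = rng.uniform(0.1, 5.0, size=(7, 4))
        a = friedman_test(data)
        b = friedman_test(np.log(data))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_approx_matches_scipy_on_untied_data(self, rng):
        from scipy.stats import friedmanchisquare

        data = rng.normal(size=(10, 4))
        res = friedman_test(data)
        ref = friedmanchisquare(*data.T)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-9)

    def test_incomplete_blocks_dropped_listwise(self, rng):
        data = rng.normal(size=(8, 3))
        data[2, 1] = np.nan
        with pytest.warns(UserWarning, match="incomplete"):
            res = friedman_test(data)
        assert res.n == 7

    def test_too_few_conditions_rejected(self, rng):
        with pytest.raises(ValueError, match="conditions"):
            friedman_test(rng.normal(size=(7, 2)))


class TestWilcoxon:
    def test_uniform_shift_minimal_one_sided_p(self, rng):
        a = rng.normal(size=7)
        b = a + 1.0
        res = wilcoxon_signed_rank(b, a, alternative="greater")
        assert res.pvalue == pytest.approx(1 / 128)

    def test_sign_flip_oracle_exact_match(self, rng):
        for _ in range(10):
            a = rng.normal(size=7)
            b = rng.normal(size=7)
            res = wilcoxon_signed_rank(a, b)
            assert res.pvalue == pytest.approx(wilcoxon_signflip_oracle(a, b), abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        a = np.arange(1.0, 8.0)
        with pytest.warns(UserWarning, match="all differences zero"):
            res = wilcoxon_signed_rank(a, a)
        assert res.pvalue == 1.0

    def test_rank_invariance_under_monotone_transform(self, rng):
        a = rng.uniform(1, 2, size=9)
        b = rng.uniform(1, 2, size=9)
        p1 = wilcoxon_signed_rank(a, b).pvalue
        # strictly increasing odd transform of the differences preserves
        # signs and |difference| order: apply to d = a - b around b
        d = a - b
        p2 = wilcoxon_signed_rank(b + np.sign(d) * np.abs(d) ** 1.5, b).pvalue
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestPfaffl:
    def test_sample_equals_control_unity(self):
        m = ExpressionMeasurement("SCX", ct_target=22.0, ct_reference=18.0)
        assert pfaffl_ratio(m, m) == pytest.approx(1.0)

    def test_closed_form_doubling(self):
        control = ExpressionMeasurement("SCX", ct_target=23.0, ct_reference=18.0)
        sample = ExpressionMeasurement("SCX", ct_target=22.0, ct_reference=18.0)
        assert pfaffl_ratio(sample, control) == pytest.approx(2.0)

    def test_matches_log_space_oracle(self, rng):
        for _ in range(20):
            et = rng.uniform(1.5, 2.2)
            er = rng.uniform(1.5, 2.2)
            control = ExpressionMeasurement("g", rng.uniform(15, 30), rng.uniform(15, 30))
            sample = ExpressionMeasurement(
                "g", rng.uniform(15, 30), rng.uniform(15, 30),
                efficiency_target=et, efficiency_reference=er)
            expected = math.exp(
                (control.ct_target - sample.ct_target) * math.log(et)
                - (control.ct_reference - sample.ct_reference) * math.log(er)
            )
            assert pfaffl_ratio(sample, control) == pytest.approx(expected, rel=1e-12)

    def test_efficiency_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            ExpressionMeasurement("g", 20.0, 20.0, efficiency_target=2.5)


class TestFoldChange:
    def _frame(self):
        rows = []
        for donor in range(1, 8):
            for cond, val in [("control", 2.0 + donor), ("treated", 2 * (2.0 + donor))]:
                rows.append({"donor": donor, "condition": cond, "day": 1, "value": val})
        return pd.DataFrame(rows)

    def test_control_rows_map_to_one(self):
        out = fold_change_normalize(self._frame(), "control")
        ctrl = out[out.condition == "control"]
        np.testing.assert_allclose(ctrl.fold_change, 1.0)

    def test_doubled_condition_maps_to_two(self):
        out = fold_change_normalize(self._frame(), "control")
        np.testing.assert_allclose(out[out.condition == "treated"].fold_change, 2.0)

    def test_idempotent(self):
        once = fold_change_normalize(self._frame(), "control")
        again = fold_change_normalize(
            once.drop(columns="value").rename(columns={"fold_change": "value"}),
            "control",
        )
        np.testing.assert_allclose(again.fold_change, once.fold_change)

    def test_missing_control_warns_and_nans(self):
        df = self._frame()
        df = df[~((df.condition == "control") & (df.donor == 3))]
        with pytest.warns(UserWarning, match="without a matched control"):
            out = fold_change_normalize(df, "control")
        assert np.isnan(out.loc[(out.condition == "treated") & (out.donor == 3),
                                "fold_change"]).all()

    def test_preserves_within_donor_ordering(self, rng):
        rows = []
        for donor in range(1, 6):
            base = rng.uniform(1, 3)
            for cond in ("control", "a", "b", "c"):
                rows.append({"donor": donor, "condition": cond, "day": 1,
                             "value": base * rng.uniform(0.5, 4.0)})
        df = pd.DataFrame(rows)
        out = fold_change_normalize(df, "control")
        for donor in range(1, 6):
            sub = out[out.donor == donor]
            assert (sub.sort_values("value").condition.to_list()
                    == sub.sort_values("fold_change").condition.to_list())


class TestGenerationTime:
    def test_doubling_in_24h(self):
        assert generation_time(1000, 2000, 24.0) == pytest.approx(24.0)

    def test_quadrupling_in_24h(self):
        assert generation_time(1000, 4000, 24.0) == pytest.approx(12.0)

    def test_matches_log_space_oracle(self, rng):
        for _ in range(20):
            n0 = rng.uniform(1e3, 1e5)
            n1 = n0 * rng.uniform(1.1, 10)
            t = rng.uniform(10, 100)
            expected = t * math.log(2) / math.log(n1 / n0)
            assert generation_time(n0, n1, t) == pytest.approx(expected, rel=1e-12)

    def test_no_growth_undefined(self):
        with pytest.warns(UserWarning, match="no growth"):
            assert math.isnan(generation_time(1000, 900, 24.0))


class TestOutlierDisplayRule:
    def test_extreme_values_removed_for_display_only(self):
        vals = np.array([1.0, 1.1, 0.9, 1.2, 0.8, 1.05, 50.0])
        kept = exclude_extreme_outliers(vals)
        assert 50.0 not in kept and len(kept) == 6


class TestCompareConditions:
    def test_known_effect_flagged(self):
        spec = CohortSpec(condition_effects={"IL1b-high": 3.0}, noise_cv=0.1, seed=3)
        table = compare_conditions(simulate_cohort(spec))
        row = table[(table.comparison == "IL1b-high vs control") & (table.day == 1)]
        assert bool(row.significant.iloc[0])

    def test_null_cohort_mostly_unflagged(self):
        spec = CohortSpec(seed=11)
        table = compare_conditions(simulate_cohort(spec))
        posthoc = table[table.test == "wilcoxon"]
        assert posthoc.significant.mean() <= 0.25

    def test_empty_cohort_rejected(self):
        df = pd.DataFrame(columns=["donor", "condition", "day", "value"])
        with pytest.raises(ValueError):
            compare_conditions(df)
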