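"""Normality battery, ANOVA/Tukey and t-test behavior."""

import itertools

import numpy as np
import pytest
from scipy import stats

from biofilmquant.errors import DataError, ValidationError
from biofilmquant.group_stats import (
    anderson_darling_normal,
    compare_materials,
    compare_trials,
    full_report,
    lilliefors_mc,
    normality_battery,
)


class TestNormalityBattery:
    def test_reports_all_four_tests(self):
        rng = np.random.default_rng(0)
        rep = normality_battery(rng.normal(2, 0.3, 50))
        assert set(rep.tests) == {
            "shapiro_wilk", "kolmogorov_smirnov", "lilliefors", "anderson_darling"
        }
        assert all(0 <= t.p_value <= 1 for t in rep.tests.values())

    def test_calibration_on_normal_samples(self):
        """Joint verdict: each component test holds its ~5% level, so the
        four-test union passes clean normal samples in the vast majority
        of replicates (measured ~90%; the union of four correlated 5%
        tests cannot reach 95%)."""
        rng = np.random.default_rng(42)
        ok = 0
        n_rep = 200
        for _ in range(n_rep):
            ok += normality_battery(rng.normal(2, 0.3, 100)).normal
        assert ok / n_rep >= 0.85

    def test_power_against_exponential(self):
        rng = np.random.default_rng(1)
        flagged = 0
        n_rep = 100
        for _ in range(n_rep):
            flagged += not normality_battery(rng.exponential(1.0, 100)).normal
        assert flagged / n_rep >= 0.90

    def test_constant_sample_is_zero_variance_error(self):
        with pytest.raises(DataError, match="variance"):
            normality_battery([2.0, 2.0, 2.0, 2.0])

    def test_too_small_sample_rejected(self):
        with pytest.raises(DataError):
            normality_battery([1.0, 2.0])

    def test_anderson_darling_p_consistent_with_critical_values(self):
        """Cross-check the p approximation against scipy's 5% critical
        value: rejection by p < 0.05 must agree with A2* exceeding it."""
        rng = np.random.default_rng(3)
        for _ in range(40):
            x = rng.normal(0, 1, 60) if rng.random() < 0.5 else rng.exponential(1, 60)
            res = anderson_darling_normal(x)
            sp = stats.anderson(x, dist="norm")
            crit5 = sp.critical_values[list(sp.significance_level).index(5.0)]
            assert (res.p_value < 0.05) == (res.statistic > crit5 * (1 + 0.75/60 + 2.25/60**2)) \
                or abs(res.p_value - 0.05) < 0.02

    def test_lilliefors_mc_agrees_with_table(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            x = rng.normal(1, 0.2, 40)
            mc = lilliefors_mc(x, n_mc=2000, seed=9)
            table = normality_battery(x, lilliefors_method="table").tests["lilliefors"]
            assert mc.statistic == pytest.approx(table.statistic, abs=1e-12)
            assert mc.p_value == pytest.approx(table.p_value, abs=0.06)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(2, 0.3, 60)
        a = normality_battery(x)
        b = normality_battery(x * 100.0)  # percent vs fraction
        for name in a.tests:
            assert a.tests[name].p_value == pytest.approx(b.tests[name].p_value, rel=1e-9)


class TestCompareTrials:
    def test_identical_groups_give_f_zero_and_tukey_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        cmp_ = compare_trials({"t1": g, "t2": g, "t3": g, "t4": g},
                              check_normality=False)
        assert cmp_.anova_f == pytest.approx(0.0, abs=1e-12)
        assert cmp_.anova_p == pytest.approx(1.0)
        assert (cmp_.tukey["p_adj"] > 0.999).all()
        assert cmp_.max_mean_diff == pytest.approx(0.0)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            groups = {f"t{i}": rng.normal(2.0, 0.3, 10) for i in range(3)}
            rejections += compare_trials(groups, check_normality=False, post_hoc=False).anova_p < 0.05
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.08

    def test_power_against_a_shifted_group(self):
        rng = np.random.default_rng(7)
        detected = 0
        n_rep = 100
        for _ in range(n_rep):
            groups = {
                "a": rng.normal(2.0, 0.3, 30),
                "b": rng.normal(2.0, 0.3, 30),
                "c": rng.normal(2.6, 0.3, 30),
            }
            detected += compare_trials(groups, check_normality=False, post_hoc=False).anova_p < 0.05
        assert detected / n_rep >= 0.90

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValidationError):
            compare_trials({"a": [1, 2], "b": [3, 4]})

    def test_scale_invariance_of_decisions(self):
        rng = np.random.default_rng(8)
        groups = {f"t{i}": rng.normal(2, 0.3, 12) for i in range(3)}
        a = compare_trials(groups, check_normality=False)
        b = compare_trials({k: np.asarray(v) / 100 for k, v in groups.items()},
                           check_normality=False)
        assert a.anova_p == pytest.approx(b.anova_p, rel=1e-9)
        np.testing.assert_allclose(a.tukey["p_adj"], b.tukey["p_adj"], rtol=1e-9)


class TestCompareMaterials:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = compare_materials(g, g)
        assert res.p_value == pytest.approx(1.0)
        assert res.mean_diff == pytest.approx(0.0)

    def test_constant_equal_groups_documented_path(self):
        res = compare_materials([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0
        assert res.mean_diff == 0.0

    def test_doubled_coverage_detected_at_strict_alpha(self):
        rng = np.random.default_rng(9)
        detected, ratios = 0, []
        n_rep = 200
        for _ in range(n_rep):
            glass = rng.normal(2.0, 0.5, 30)
            steel = rng.normal(4.0, 0.5, 30)
            res = compare_materials(steel, glass)
            detected += res.p_value < 0.001
            ratios.append(res.mean_ratio)
        assert detected / n_rep >= 0.90
        assert np.mean(ratios) == pytest.approx(2.0, abs=0.1)

    def test_agrees_with_exact_permutation_oracle_on_small_samples(self):
        """On small random pairs, the Welch t decision at the 5% level
        agrees with an exhaustive permutation test of the mean difference
        in nearly all instances."""
        rng = np.random.default_rng(10)
        n_a = n_b = 6
        agree, total = 0, 100
        splits = list(itertools.combinations(range(n_a + n_b), n_a))
        for _ in range(total):
            shift = rng.choice([0.0, 1.0])
            a = rng.normal(0, 1, n_a) + shift
            b = rng.normal(0, 1, n_b)
            pooled = np.concatenate([a, b])
            obs = abs(a.mean() - b.mean())
            hits = 0
            for idx in splits:
                sel = np.zeros(n_a + n_b, dtype=bool)
                sel[list(idx)] = True
                if abs(pooled[sel].mean() - pooled[~sel].mean()) >= obs - 1e-12:
                    hits += 1
            p_perm = hits / len(splits)
            p_t = compare_materials(a, b).p_value
            agree += (p_perm < 0.05) == (p_t < 0.05)
        assert agree / total >= 0.95

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            rejections += compare_materials(
                rng.normal(2, 0.3, 10), rng.normal(2, 0.3, 10)
            ).p_value < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_tiny_groups_rejected(self):
        with pytest.raises(DataError):
            compare_materials([1.0], [1.0, 2.0])


class TestFullReport:
    def test_two_group_report_has_t_test_and_decisions(self):
        rng = np.random.default_rng(13)
        rep = full_report({"glass": rng.normal(2, 0.3, 10),
                           "steel": rng.normal(4, 0.3, 10)})
        assert "t_test" in rep
        assert set(rep["t_test"]["decisions"]) == {"0.05", "0.001"}
        assert rep["groups"]["glass"]["normal"] in (True, False)

    def test_four_group_report_has_anova_and_tukey(self):
        rng = np.random.default_rng(14)
        rep = full_report({f"t{i}": rng.normal(2, 0.3, 8) for i in range(4)})
        assert "anova" in rep and "tukey" in rep
        assert len(rep["tukey"]) == 6  # 4 choose 2 pairs

    def test_gated_pipeline_type_one_error_bounded(self):
        """Normality gate then ANOVA: false-positive rate of the final
        ANOVA decision stays at/below nominal plus Monte-Carlo slack."""
        rng = np.random.default_rng(15)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            groups = {f"t{i}": rng.normal(2.0, 0.3, 10) for i in range(3)}
            cmp_ = compare_trials(groups, check_normality=True, post_hoc=False)
            rejections += cmp_.anova_p < 0.05
        assert rejections / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)
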