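"""Classification, aspirin adjustment, weighted ROC/DR/AUC, summaries."""

import numpy as np
import pytest
from scipy import stats

from pescreen import (
    CohortSpec,
    auc,
    auc_with_ci,
    aspirin_adjust,
    aspirin_case_weights,
    classify,
    cohort_summary,
    dr_at_fpr,
    evaluate_combination,
    sample_size_for_auc,
    simulate_cohort,
    weighted_roc,
)
from pescreen.errors import DomainError

from oracles import brute_force_dr_at_fpr, brute_force_roc_points


class TestClassify:
    @pytest.mark.parametrize(
        "risk,expected", [(0.0100, "high"), (0.0099, "low"), (1.0, "high"), (0.0, "low")]
    )
    def test_inclusive_boundary_at_one_in_n(self, risk, expected):
        assert classify(risk, 100) == expected

    def test_any_threshold(self):
        assert classify(1.0, 2) == "high"
        assert classify(0.49, 2) == "low"


class TestAspirinAdjust:
    def test_additive_convention_reproduces_study_arithmetic(self):
        """25 observed preterm-PE cases, 19 high risk, 6 on aspirin, effect
        0.6: multiplier 2.5, 15 prevented, 40 total, 34 high risk."""
        c = aspirin_adjust(25, 19, 6, effect=0.6, convention="additive_paper")
        assert c.multiplier == pytest.approx(2.5)
        assert c.prevented_cases == pytest.approx(15.0)
        assert c.adjusted_total_cases == pytest.approx(40.0)
        assert c.adjusted_high_risk_cases == pytest.approx(34.0)

    def test_counterfactual_convention(self):
        c = aspirin_adjust(25, 19, 6, effect=0.6, convention="counterfactual")
        assert c.prevented_cases == pytest.approx(9.0)
        assert c.adjusted_total_cases == pytest.approx(34.0)

    def test_zero_effect_is_identity_under_both_conventions(self):
        for convention in ("additive_paper", "counterfactual"):
            c = aspirin_adjust(25, 19, 6, effect=0.0, convention=convention)
            assert c.prevented_cases == 0.0
            assert c.adjusted_total_cases == 25
            assert c.adjusted_high_risk_cases == 19

    def test_adjusted_never_below_observed(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            total = int(rng.integers(1, 100))
            high = int(rng.integers(0, total + 1))
            asp = int(rng.integers(0, high + 1))
            effect = float(rng.uniform(0, 0.95))
            c = aspirin_adjust(total, high, asp, effect=effect)
            assert c.adjusted_total_cases >= total
            assert c.multiplier == pytest.approx(1 / (1 - effect))

    def test_count_ordering_enforced(self):
        with pytest.raises(DomainError):
            aspirin_adjust(5, 6, 1)
        with pytest.raises(DomainError):
            aspirin_adjust(5, 3, 4)


class TestWeightedROC:
    def test_perfect_separation_passes_through_corner(self):
        roc = weighted_roc([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        assert any(f == 0.0 and t == 1.0 for f, t in zip(roc.fpr, roc.tpr))
        assert auc(roc) == 1.0

    def test_unit_weights_reduce_to_standard_roc(self):
        rng = np.random.default_rng(1)
        s = rng.random(200)
        y = rng.random(200) < 0.3
        unweighted = weighted_roc(s, y)
        weighted = weighted_roc(s, y, np.ones(200))
        np.testing.assert_array_equal(unweighted.fpr, weighted.fpr)
        np.testing.assert_array_equal(unweighted.tpr, weighted.tpr)

    def test_matches_exhaustive_enumeration_with_fractional_weights(self):
        """Toy set with one case at weight 2.5: every operating point must
        match the brute-force threshold enumeration."""
        s = np.array([0.9, 0.7, 0.7, 0.5, 0.3, 0.1])
        y = np.array([True, True, False, False, True, False])
        w = np.array([2.5, 1.0, 1.0, 1.0, 1.0, 1.0])
        roc = weighted_roc(s, y, w)
        got = {(round(f, 12), round(t, 12)) for f, t in zip(roc.fpr, roc.tpr)}
        assert got == brute_force_roc_points(s, y, w)

    def test_ties_move_together(self):
        s = np.array([0.5, 0.5, 0.5, 0.2])
        y = np.array([True, False, True, False])
        roc = weighted_roc(s, y)
        # no operating point splits the tied group at 0.5
        assert (0.5, 1.0) in {(f, t) for f, t in zip(roc.fpr, roc.tpr)}
        assert all(not (0 < t < 1) or f > 0 for f, t in zip(roc.fpr, roc.tpr))

    def test_monotone_step_curve_from_origin_to_corner(self):
        rng = np.random.default_rng(2)
        s = rng.random(500)
        y = rng.random(500) < 0.1
        w = rng.uniform(0.5, 3.0, 500)
        roc = weighted_roc(s, y, w)
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            weighted_roc([0.1, 0.2], [True, True])


class TestDrAtFpr:
    def test_perfect_classifier_detects_everything(self):
        roc = weighted_roc([0.9, 0.8, 0.1], [True, True, False])
        for target in (0.01, 0.1, 0.5):
            dr, _ = dr_at_fpr(roc, target)
            assert dr == 1.0

    def test_chance_level_scores_give_dr_near_fpr(self):
        rng = np.random.default_rng(3)
        s = rng.random(20_000)
        y = rng.random(20_000) < 0.5
        dr, _ = dr_at_fpr(weighted_roc(s, y), 0.10)
        assert dr == pytest.approx(0.10, abs=0.02)

    def test_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            s = np.round(rng.random(20), 2)  # force ties
            y = rng.random(20) < 0.4
            if y.all() or not y.any():
                continue
            w = np.where(y & (rng.random(20) < 0.3), 2.5, 1.0)
            roc = weighted_roc(s, y, w)
            dr, cutoff = dr_at_fpr(roc, 0.25)
            assert dr == pytest.approx(brute_force_dr_at_fpr(s, y, w, 0.25), abs=1e-12)
            # the returned cutoff attains the returned DR with FPR <= target
            pred = s >= cutoff
            assert w[~y & pred].sum() / w[~y].sum() <= 0.25 + 1e-12
            assert w[y & pred].sum() / w[y].sum() == pytest.approx(dr)


class TestAuc:
    def test_chance_level(self):
        rng = np.random.default_rng(5)
        s = rng.random(20_000)
        y = rng.random(20_000) < 0.3
        assert auc(weighted_roc(s, y)) == pytest.approx(0.5, abs=0.02)

    def test_unweighted_equals_mann_whitney_u(self):
        rng = np.random.default_rng(6)
        cases = rng.normal(1.0, 1.0, 80)
        controls = rng.normal(0.0, 1.0, 200)
        s = np.concatenate([cases, controls])
        y = np.concatenate([np.ones(80, bool), np.zeros(200, bool)])
        u = stats.mannwhitneyu(cases, controls).statistic
        assert auc(weighted_roc(s, y)) == pytest.approx(u / (80 * 200), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        s = rng.random(300)
        y = rng.random(300) < 0.25
        w = rng.uniform(0.5, 3.5, 300)
        a = auc(weighted_roc(s, y, w))
        b = auc(weighted_roc(np.log(s + 1.0), y, w))
        assert a == pytest.approx(b, abs=1e-12)

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(8)
        s = np.concatenate([rng.normal(1, 1, 60), rng.normal(0, 1, 400)])
        y = np.concatenate([np.ones(60, bool), np.zeros(400, bool)])
        point, (lo, hi) = auc_with_ci(s, y, n_boot=300, seed=0)
        assert lo < point < hi
        assert hi - lo < 0.3
        point2, (lo2, hi2) = auc_with_ci(s, y, n_boot=300, seed=0)
        assert (point, lo, hi) == (point2, lo2, hi2)  # seeded determinism


class TestEvaluateCombination:
    def test_zero_effect_adjustment_is_identity_on_metrics(self):
        rng = np.random.default_rng(9)
        s = rng.random(2000)
        y = rng.random(2000) < 0.05
        asp = rng.random(2000) < 0.2
        from pescreen import ScreeningConfig

        base = evaluate_combination(
            s, y, np.zeros(2000, bool), ScreeningConfig(aspirin_effect=0.0), n_boot=0
        )
        treated = evaluate_combination(
            s, y, asp, ScreeningConfig(aspirin_effect=0.0), n_boot=0
        )
        assert base.auc == treated.auc
        assert base.dr_at_target_fpr == treated.dr_at_target_fpr
        assert base.adjusted_counts.adjusted_total_cases == y.sum()

    def test_weights_follow_convention(self):
        y = np.array([True, True, False])
        asp = np.array([True, False, True])
        np.testing.assert_allclose(
            aspirin_case_weights(y, asp, 0.6, "additive_paper"), [3.5, 1.0, 1.0]
        )
        np.testing.assert_allclose(
            aspirin_case_weights(y, asp, 0.6, "counterfactual"), [2.5, 1.0, 1.0]
        )


class TestCohortSummary:
    def test_incidences_and_groups(self):
        records = simulate_cohort(CohortSpec(n=4000, seed=11))
        summary = cohort_summary(records)
        n_pe = sum(r.outcome.value != "no_pe" for r in records)
        assert summary.n_pe == n_pe
        assert summary.pe_incidence == pytest.approx(n_pe / 4000)
        assert set(summary.markers["marker"]) == {"MAP", "UtAPI", "PAPPA", "PlGF"}
        assert (summary.markers["anova_p_bonferroni"] >= summary.markers["anova_p"] - 1e-15).all()
        assert "chronic_hypertension" in set(summary.characteristics["characteristic"])
        assert summary.to_markdown()

    def test_identical_groups_give_p_one_for_continuous(self):
        # construct a tiny cohort where PE and no-PE groups share identical ages
        records = simulate_cohort(CohortSpec(n=400, seed=12))
        from pescreen import MaternalProfile

        for r in records[:200]:
            r.outcome = type(r.outcome)("no_pe")
        for i, r in enumerate(records):
            object.__setattr__(r.profile, "age", 30.0 + (i % 5))
        for r in records[200:]:
            r.outcome = type(r.outcome)("term_pe")
            if r.ga_at_delivery < 37.0:
                r.ga_at_delivery = 38.0
        summary = cohort_summary(records)
        age_row = summary.characteristics.query("characteristic == 'age_years'")
        assert age_row["p_value"].iloc[0] == pytest.approx(1.0)

    def test_hand_checked_chi_square(self):
        """2×2 association test agrees with the textbook chi-square with
        Yates continuity correction on the same table."""
        table = np.array([[6, 19], [30, 45]])
        p_scipy = stats.chi2_contingency(table).pvalue
        # textbook formula with continuity correction
        n = table.sum()
        row = table.sum(axis=1)
        col = table.sum(axis=0)
        expected = np.outer(row, col) / n
        chi2 = (((np.abs(table - expected) - 0.5) ** 2) / expected).sum()
        p_hand = stats.chi2.sf(chi2, df=1)
        assert p_scipy == pytest.approx(p_hand, rel=1e-9)


class TestSampleSize:
    def test_tighter_precision_needs_more_cases(self):
        loose = sample_size_for_auc(0.9, 0.05)
        tight = sample_size_for_auc(0.9, 0.01)
        tighter = sample_size_for_auc(0.9, 0.005)
        assert loose.n_cases < tight.n_cases < tighter.n_cases

    def test_doubling_variance_roughly_halves_cases(self):
        se = 0.01
        n1 = sample_size_for_auc(0.85, se).n_cases
        n2 = sample_size_for_auc(0.85, se * np.sqrt(2)).n_cases
        assert 1.6 < n1 / n2 < 2.4

    def test_default_assumptions_reported_with_finite_count(self):
        result = sample_size_for_auc(0.9, 0.05)
        assert result.n_cases >= 2
        assert result.se_achieved <= 0.05
        assert result.assumptions["auc0"] == 0.9
        assert "control_case_ratio" in result.assumptions
        assert 0 < result.power_vs_null <= 1

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(DomainError):
            sample_size_for_auc(0.4, 0.05)
        with pytest.raises(DomainError):
            sample_size_for_auc(0.9, 0.0)
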