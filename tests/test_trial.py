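"""Trial statistics: paired changes, ANCOVA, effect sizes, McNemar,
transition tables, and CV evaluation metrics."""

import numpy as np
import pytest
import scipy.stats as st

import fitrx as fx
from fitrx.trial import evaluate_predictions


class TestWithinGroupChange:
    def test_printed_means_arithmetic(self):
        baseline = np.array([10.2 - 1.0, 10.2 + 1.0])
        post = np.array([14.7 - 0.8, 14.7 + 0.8])
        delta, _ = fx.within_group_change(baseline, post)
        assert delta == pytest.approx(4.5)

    def test_no_change_ci_contains_zero(self):
        x = np.random.default_rng(0).normal(size=30)
        delta, (lo, hi) = fx.within_group_change(x, x)
        assert delta == 0
        assert lo <= 0 <= hi

    def test_constant_shift_degenerate_ci(self):
        x = np.arange(10.0)
        delta, (lo, hi) = fx.within_group_change(x, x + 3.0)
        assert (delta, lo, hi) == (3.0, 3.0, 3.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fx.within_group_change(np.zeros(3), np.zeros(4))


class TestAncova:
    def test_coverage_of_injected_effect(self):
        """95% Wald CI covers a true -2.0 effect in >= 93 of 100 trials."""
        rng = np.random.default_rng(42)
        covered = 0
        for _ in range(100):
            n = 500
            base = rng.normal(30, 2, 2 * n)
            arm = np.repeat([1.0, 0.0], n)
            post = base - 1.0 - 2.0 * arm + rng.normal(0, 1, 2 * n)
            tau, (lo, hi), _ = fx.ancova_group_effect(base, post, arm)
            covered += lo <= -2.0 <= hi
        assert covered >= 93

    def test_null_effect_near_zero(self):
        rng = np.random.default_rng(1)
        base = rng.normal(30, 2, 1000)
        post = base + rng.normal(0, 1, 1000)
        arm = np.repeat([1.0, 0.0], 500)
        tau, _, p = fx.ancova_group_effect(base, post, arm)
        assert abs(tau) < 0.3
        assert p > 0.001

    def test_balanced_baseline_reduces_to_change_comparison(self):
        rng = np.random.default_rng(2)
        base = rng.normal(30, 2, 400)
        base_all = np.concatenate([base, base])  # identical baselines per arm
        arm = np.repeat([1.0, 0.0], 400)
        post = base_all + np.where(arm == 1, -2.0, -0.5) + rng.normal(0, 1, 800)
        tau, _, _ = fx.ancova_group_effect(base_all, post, arm)
        change_diff = (post[arm == 1] - base).mean() - (post[arm == 0] - base).mean()
        assert tau == pytest.approx(change_diff, abs=0.05)

    def test_affine_invariance_of_effect(self):
        rng = np.random.default_rng(3)
        base = rng.normal(30, 2, 600)
        arm = np.repeat([1.0, 0.0], 300)
        post = base - 2.0 * arm + rng.normal(0, 1, 600)
        tau1, _, _ = fx.ancova_group_effect(base, post, arm)
        tau2, _, _ = fx.ancova_group_effect(5.0 * base - 40.0, post, arm)
        assert tau1 == pytest.approx(tau2, abs=1e-9)

    def test_string_arm_labels_accepted(self):
        rng = np.random.default_rng(4)
        base = rng.normal(30, 2, 100)
        post = base + rng.normal(0, 1, 100)
        arm = np.repeat(["intervention", "control"], 50)
        tau, _, _ = fx.ancova_group_effect(base, post, arm)
        assert np.isfinite(tau)

    def test_single_arm_rejected(self):
        with pytest.raises(ValueError):
            fx.ancova_group_effect(np.zeros(4), np.zeros(4), np.ones(4))


class TestCohensD:
    def test_equal_means_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert fx.cohens_d_change(a, a + 0.0) == 0.0

    def test_unit_case(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 1.0, 100000)
        b = rng.normal(0.0, 1.0, 100000)
        assert fx.cohens_d_change(a, b) == pytest.approx(1.0, abs=0.02)

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=37), rng.normal(size=53)
        pooled = np.sqrt(((36 * a.var(ddof=1)) + (52 * b.var(ddof=1))) / 88)
        assert fx.cohens_d_change(a, b) == pytest.approx(
            (a.mean() - b.mean()) / pooled, abs=1e-12
        )

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fx.cohens_d_change(np.ones(5), np.ones(5))


class TestMcNemar:
    def test_symmetric_discordance_null(self):
        # b = c = 15 (>= 25 discordant -> chi-square form), statistic 0, p = 1
        pre = np.array([2] * 15 + [1] * 15 + [1] * 10)
        post = np.array([1] * 15 + [2] * 15 + [1] * 10)
        stat, p = fx.mcnemar_shift(pre, post)
        assert stat == 0
        assert p == pytest.approx(1.0)

    def test_exact_binomial_tail(self):
        # b=10, c=0 -> exact two-sided p = 2 * 0.5^10
        pre = np.array([2] * 10 + [1] * 20)
        post = np.array([1] * 10 + [1] * 20)
        stat, p = fx.mcnemar_shift(pre, post)
        assert p == pytest.approx(2 * 0.5 ** 10)

    def test_no_shift_p_one(self):
        pre = np.array([0, 1, 2, 3] * 5)
        stat, p = fx.mcnemar_shift(pre, pre)
        assert (stat, p) == (0.0, 1.0)

    def test_exact_and_chisquare_agree_for_large_counts(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            b = int(rng.integers(25, 60))
            c = int(rng.integers(25, 60))
            pre = np.array([2] * b + [1] * c + [1] * 50)
            post = np.array([1] * b + [2] * c + [1] * 50)
            _, p_chi = fx.mcnemar_shift(pre, post, exact_below=0)
            _, p_exact = fx.mcnemar_shift(pre, post, exact_below=10_000)
            if 0.01 < p_chi < 0.99:
                assert p_exact == pytest.approx(p_chi, rel=0.10)

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        pre = np.array([2] * 40 + [1] * 28 + [2] * 30 + [1] * 30)
        post = np.array([1] * 40 + [2] * 28 + [2] * 30 + [1] * 30)
        stat, p = fx.mcnemar_shift(pre, post)
        table = [[30, 40], [28, 30]]
        res = sm_mcnemar(table, exact=False, correction=True)
        assert stat == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)


class TestTransitionRates:
    def test_identity_when_static(self):
        pre = np.array([0, 1, 2, 3] * 10)
        assert np.array_equal(fx.transition_rates(pre, pre), np.eye(4))

    def test_overweight_to_normal_rate(self):
        pre = np.array([2] * 1000)
        post = np.array([1] * 683 + [2] * 317)
        rates = fx.transition_rates(pre, post)
        assert rates[2, 1] == pytest.approx(0.683)

    def test_rows_sum_to_one_or_zero(self):
        rng = np.random.default_rng(8)
        pre = rng.integers(0, 3, 200)  # class 3 never occurs
        post = rng.integers(0, 4, 200)
        rates = fx.transition_rates(pre, post)
        sums = rates.sum(axis=1)
        assert np.allclose(sums[:3], 1.0)
        assert sums[3] == 0.0


class TestPercentChange:
    @pytest.mark.parametrize(
        "base,post,kind,expected",
        [
            (32.4, 29.1, "time", 10.2),
            (14.2, 12.8, "time", 9.9),
            (10.0, 10.0, "time", 0.0),
            (10.2, 14.7, "count", 44.1),
        ],
    )
    def test_reported_arithmetic(self, base, post, kind, expected):
        assert fx.percent_change(base, post, kind) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fx.percent_change(0.0, 5.0)


class TestEvaluatePredictions:
    def test_perfect_classifier(self):
        y = np.array([0, 1, 2, 3] * 10)
        proba = np.eye(4)[y]
        m = evaluate_predictions(y, proba)
        assert m["accuracy"] == 1.0
        assert m["macro_f1"] == 1.0
        assert m["macro_auc"] == 1.0

    def test_chance_level_random_predictions(self):
        rng = np.random.default_rng(9)
        y = np.repeat(np.arange(4), 500)
        proba = rng.dirichlet(np.ones(4), size=2000)
        m = evaluate_predictions(y, proba)
        assert m["accuracy"] == pytest.approx(0.25, abs=0.03)
        assert m["macro_auc"] == pytest.approx(0.5, abs=0.03)

    def test_adjacent_confuser_concentrates_near_diagonal(self):
        """Predictions that always err to a neighboring category put all
        off-diagonal confusion mass on the first off-diagonals."""
        from sklearn.metrics import confusion_matrix

        rng = np.random.default_rng(10)
        y = rng.integers(0, 4, 400)
        pred = np.clip(y + rng.choice([-1, 0, 1], 400), 0, 3)
        cm = confusion_matrix(y, pred, labels=[0, 1, 2, 3])
        off = cm.copy()
        np.fill_diagonal(off, 0)
        adjacent_mass = sum(off[i, j] for i in range(4) for j in range(4) if abs(i - j) == 1)
        assert adjacent_mass == off.sum()


class TestAnalyzeTrial:
    @pytest.fixture(scope="class")
    def outcome(self):
        records = fx.generate_trial(n_per_arm=150, seed=17)
        return fx.analyze_trial(records), records

    def test_within_change_consistent_with_means(self, outcome):
        out, _ = outcome
        df = out.metrics
        for _, row in df.iterrows():
            assert row["within_change"] == pytest.approx(
                row["post_mean"] - row["baseline_mean"], abs=1e-9
            )

    def test_intervention_beats_control_on_pull_ups(self, outcome):
        out, _ = outcome
        row = out.metrics.query("metric == 'pull_ups' and group == 'intervention'").iloc[0]
        assert row["ancova_effect"] > 0
        assert row["ancova_p"] < 0.01
        assert np.isfinite(row["cohens_d"])

    def test_completers_only(self, outcome):
        out, records = outcome
        n_completers = sum(r.completed for r in records)
        n_interv = out.metrics.query("group == 'intervention'")["metric"].count()
        assert n_interv == 4  # one row per metric
        itt = fx.analyze_trial(records, completers_only=False)
        assert itt.transitions is not None
        assert out.mcnemar_p <= 1.0 and n_completers < len(records)
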