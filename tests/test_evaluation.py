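"""Metrics, statistical comparisons, the CV harness and the sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from pmtl.evaluation import (
    auprc,
    auroc,
    bootstrap_compare,
    calibration_error,
    crossvalidate,
    delong_test,
    evaluate_scores,
    recall_at_matched_alerts,
    training_fraction_sweep,
    z_test_metric_diff,
)
from pmtl.models import fit_logistic, predict_risk
from pmtl.preprocess import Preprocessor
from pmtl.simulate import SyntheticConfig, feature_columns, generate_cohort


def brute_force_auroc(y, s):
    """Oracle: explicit pair counting with half-credit ties."""
    y = np.asarray(y)
    s = np.asarray(s)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        y = np.array([0, 1, 0, 1])
        assert auroc(y, y.astype(float)) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0, 1, 0, 1], [0.3] * 4) == 0.5

    def test_hand_counted_example(self):
        assert auroc([0, 1, 0, 1], [0.1, 0.9, 0.8, 0.2]) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([1, 1], [0.1, 0.2])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_equals_pair_counting_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 51)
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.random(n), 2)  # coarse grid to exercise ties
        assert auroc(y, s) == pytest.approx(brute_force_auroc(y, s), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        y = rng.integers(0, 2, size=500)
        s = rng.random(500)
        assert auroc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_two_point_perfect(self):
        assert auprc([1, 0], [0.9, 0.1]) == 1.0

    def test_random_scores_approach_prevalence(self, rng):
        y = (rng.random(20000) < 0.2).astype(int)
        s = rng.random(20000)
        assert auprc(y, s) == pytest.approx(0.2, abs=0.02)

    def test_no_cases_errors(self):
        with pytest.raises(ValueError):
            auprc([0, 0], [0.1, 0.2])


class TestCalibration:
    def test_perfectly_binned_scores_give_zero(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        s = np.array([0.0, 0.0, 1.0, 1.0, 0.5, 0.5])
        assert calibration_error(y, s, n_bins=3) == pytest.approx(0.0)

    def test_single_bin_arithmetic(self):
        assert calibration_error([0, 0], [0.5, 0.5], n_bins=1) == pytest.approx(0.25)

    def test_well_calibrated_simulation_is_tiny(self, rng):
        s = rng.random(10000)
        y = (rng.random(10000) < s).astype(int)
        assert calibration_error(y, s) < 0.001

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="fewer bins"):
            calibration_error([0, 1], [0.1, 0.9], n_bins=10)


class TestDelong:
    def test_identical_scores(self):
        y = np.array([0, 1] * 20)
        s = np.linspace(0, 1, 40)
        delta, p = delong_test(y, s, s)
        assert delta == 0.0 and p == 1.0

    def test_antisymmetry(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s1, s2 = rng.random(200), rng.random(200)
        d12, p12 = delong_test(y, s1, s2)
        d21, p21 = delong_test(y, s2, s1)
        assert d12 == pytest.approx(-d21)
        assert p12 == pytest.approx(p21)

    @pytest.mark.parametrize("seed", range(6))
    def test_close_to_permutation_oracle(self, seed):
        """Paired sign-flip permutation test as an independent oracle."""
        rng = np.random.default_rng(seed)
        n = 200
        x = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        s1 = 1 / (1 + np.exp(-(x + rng.normal(0, 1.0, n))))
        s2 = 1 / (1 + np.exp(-(x + rng.normal(0, 1.5, n))))
        delta, p = delong_test(y, s1, s2)
        B = 2000
        obs = abs(delta)
        count = 0
        for _ in range(B):
            swap = rng.random(n) < 0.5
            a = np.where(swap, s2, s1)
            b = np.where(swap, s1, s2)
            count += abs(auroc(y, a) - auroc(y, b)) >= obs - 1e-12
        p_perm = count / B
        assert abs(p - p_perm) < 0.05


class TestBootstrapCompare:
    def test_identical_scores_all_ties(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.random(100)
        res = bootstrap_compare(y, s, s, B=200, seed=0)
        assert res.wins == 0 and res.losses == 0 and res.ties == 200

    def test_strictly_better_model_wins_everything(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s1 = y + rng.normal(0, 0.01, 200)  # nearly perfect
        s2 = rng.random(200)
        res = bootstrap_compare(y, s1, s2, B=300, seed=1)
        assert res.wins == 300

    def test_partition_invariant(self, rng):
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        res = bootstrap_compare(y, rng.random(80), rng.random(80), B=500, seed=2)
        assert res.wins + res.losses + res.ties == res.B == 500

    def test_seed_stability_of_win_rate(self, rng):
        y = rng.integers(0, 2, 300)
        y[:2] = [0, 1]
        signal = y + rng.normal(0, 1.2, 300)
        s1 = signal + rng.normal(0, 0.3, 300)
        s2 = rng.random(300) * 0.3 + 0.5 * signal
        r1 = bootstrap_compare(y, s1, s2, B=5000, seed=10)
        r2 = bootstrap_compare(y, s1, s2, B=5000, seed=11)
        assert abs(r1.wins / r1.B - r2.wins / r2.B) < 0.05

    def test_determinism_under_seed(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s1, s2 = rng.random(60), rng.random(60)
        a = bootstrap_compare(y, s1, s2, B=400, seed=3)
        b = bootstrap_compare(y, s1, s2, B=400, seed=3)
        assert (a.wins, a.losses, a.ties) == (b.wins, b.losses, b.ties)


class TestZTest:
    def test_equal_estimates(self):
        assert z_test_metric_diff(0.7, 0.01, 0.7, 0.01) == pytest.approx(1.0)

    def test_1_96_sigma(self):
        se = 0.01 / np.sqrt(2)
        assert z_test_metric_diff(0.71 + 1.96 * 0.01, se, 0.71, se) == pytest.approx(0.05, abs=1e-3)

    def test_hand_computed(self):
        assert z_test_metric_diff(0.74, 0.01, 0.70, 0.01) == pytest.approx(0.00468, abs=2e-4)

    def test_nonpositive_se_errors(self):
        with pytest.raises(ValueError):
            z_test_metric_diff(0.7, 0.0, 0.6, 0.01)


class TestEvaluateScores:
    def test_report_ranges_and_ci_ordering(self, rng):
        y = rng.integers(0, 2, 400)
        y[:2] = [0, 1]
        s = np.clip(0.3 * y + rng.random(400) * 0.5, 0, 1)
        rep = evaluate_scores(y, s, model="m", n_boot=200, seed=0)
        assert 0 <= rep.auroc <= 1 and 0 <= rep.auprc <= 1
        for metric in ("auroc", "auprc", "calibration_error"):
            lo, hi = rep.ci[metric]
            assert lo <= getattr(rep, metric) <= hi


@pytest.fixture(scope="module")
def cv_cohort():
    cfg = SyntheticConfig(
        n=2500, d=10, n_subgroups=3, n_informative=3, tau=1.0,
        beta_density=0.5, beta_scale=0.5, seed=13,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


class TestCrossvalidate:
    def test_same_seed_reproduces_reports_and_folds(self, cv_cohort):
        cohort, _ = cv_cohort
        X = cohort[feature_columns(cohort)]
        y = cohort["y"].to_numpy()
        kw = dict(models=("global", "subgroup"), folds=3, seed=5, n_boot=50,
                  compare_B=100)
        a = crossvalidate(X, y, subgroups=cohort["subgroup_id"], **kw)
        b = crossvalidate(X, y, subgroups=cohort["subgroup_id"], **kw)
        assert np.array_equal(a.fold, b.fold)
        assert a.reports["global"].auroc == b.reports["global"].auroc
        assert a.scores.equals(b.scores)

    def test_personalized_models_run_and_score_everyone(self, cv_cohort):
        cohort, _ = cv_cohort
        X = cohort[feature_columns(cohort)].head(1200)
        y = cohort["y"].to_numpy()[:1200]
        res = crossvalidate(
            X, y, models=("global", "personalized_tl"), folds=3, seed=1,
            n_boot=0, compare_B=0, min_k=50,
        )
        assert np.isfinite(res.scores["personalized_tl"]).all()
        assert 0.4 < res.reports["personalized_tl"].auroc <= 1.0

    def test_unknown_model_rejected(self, cv_cohort):
        cohort, _ = cv_cohort
        X = cohort[feature_columns(cohort)]
        with pytest.raises(ValueError, match="unknown models"):
            crossvalidate(X, cohort["y"].to_numpy(), models=("global", "deep_net"))

    def test_training_is_isolated_from_test_labels(self, cv_cohort):
        """Corrupting one fold's test labels must not change the scores the
        models assign there (training never saw them)."""
        cohort, _ = cv_cohort
        X = cohort[feature_columns(cohort)].head(1000)
        y = cohort["y"].to_numpy()[:1000].copy()
        base = crossvalidate(X, y, models=("global",), folds=4, seed=2, n_boot=0, compare_B=0)
        fold0 = base.fold == 0
        y2 = y.copy()
        y2[fold0] = 1 - y2[fold0]
        # refit with corrupted fold-0 labels: fold-0 score rows are produced
        # by models trained on the other folds, which are unchanged
        alt = crossvalidate(X, y2, models=("global",), folds=4, seed=2, n_boot=0, compare_B=0)
        same_assignment = np.array_equal(base.fold, alt.fold)
        if same_assignment:
            assert np.allclose(
                base.scores["global"].to_numpy()[fold0],
                alt.scores["global"].to_numpy()[fold0],
            )


class TestTrainingFractionSweep:
    def test_full_fraction_equals_plain_global_fit(self, cv_cohort):
        cohort, _ = cv_cohort
        X = cohort[feature_columns(cohort)].head(1500)
        y = cohort["y"].to_numpy()[:1500]
        tab = training_fraction_sweep(X, y, fractions=(1.0,), repeats=1, seed=3)
        from sklearn.model_selection import train_test_split

        tr, te = train_test_split(np.arange(1500), test_size=0.25, random_state=3, stratify=y)
        prep = Preprocessor()
        Z_tr = prep.fit_transform(X.iloc[tr])
        Z_te = prep.transform(X.iloc[te])
        fit = fit_logistic(Z_tr, y[tr])
        expect = auroc(y[te], predict_risk(fit, Z_te))
        got = tab[tab.model == "global"]["auroc"].iloc[0]
        assert got == pytest.approx(expect, abs=1e-9)

    def test_learning_curve_increases_with_fraction(self, cv_cohort):
        cohort, _ = cv_cohort
        X = cohort[feature_columns(cohort)]
        y = cohort["y"].to_numpy()
        tab = training_fraction_sweep(X, y, fractions=(0.05, 1.0), repeats=5, seed=4)
        m = tab[tab.model == "global"].groupby("fraction")["auroc"].mean()
        assert m[0.05] < m[1.0]

    def test_invalid_fraction_rejected(self, cv_cohort):
        cohort, _ = cv_cohort
        X = cohort[feature_columns(cohort)]
        with pytest.raises(ValueError):
            training_fraction_sweep(X, cohort["y"].to_numpy(), fractions=(0.0,))


class TestRecallAtMatchedAlerts:
    def test_identical_scores_zero_percent(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.random(100)
        pct, _ = recall_at_matched_alerts(y, s, s)
        assert pct == 0.0

    def test_perfect_vs_random_large_gain(self, rng):
        y = (rng.random(5000) < 0.1).astype(int)
        s_perfect = y.astype(float)
        s_random = rng.random(5000)
        pct, table = recall_at_matched_alerts(y, s_perfect, s_random)
        # random captures ~10% of cases at budget=cases; perfect captures all
        assert 500 < pct < 2000
        assert table["captured_1"].iloc[0] == y.sum()

    def test_direction_flips_when_swapped(self, rng):
        y = rng.integers(0, 2, 400)
        y[:2] = [0, 1]
        s1 = y + rng.normal(0, 0.5, 400)
        s2 = rng.random(400)
        p12, _ = recall_at_matched_alerts(y, s1, s2)
        p21, _ = recall_at_matched_alerts(y, s2, s1)
        assert p12 > 0 > p21
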