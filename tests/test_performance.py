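import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

import afscreen as a
from afscreen import model_registry as mr
from afscreen import performance as perf


def brute_force_auc(pred, y):
    """Concordant-pair oracle: ties count one half."""
    pred, y = np.asarray(pred, float), np.asarray(y, float)
    pos, neg = pred[y == 1], pred[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_worked_example(self):
        roc = perf.auroc([0.35, 0.8, 0.1, 0.4], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        roc = perf.auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert roc.auc == 1.0 and roc.ci_high <= 1.0

    def test_all_ties_chance(self):
        roc = perf.auroc([0.3] * 10, [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        assert roc.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            perf.auroc([0.1, 0.2], [1, 1])

    def test_monotone_transform_invariance(self, models, small_cohort):
        lp = mr.linear_predictor(models["CHARGE-AF"], small_cohort)
        y = small_cohort["af_on_ecg"].to_numpy(float)
        assert perf.auroc(lp, y).auc == pytest.approx(perf.auroc(expit(lp), y).auc, rel=1e-12)

    def test_delong_se_sane_against_bootstrap(self):
        rng = np.random.default_rng(4)
        n = 2000
        lp = rng.normal(size=n)
        y = (rng.random(n) < expit(-2 + lp)).astype(float)
        roc = perf.auroc(lp, y)
        boots = []
        for _ in range(200):
            idx = rng.integers(0, n, n)
            if 0 < y[idx].sum() < n:
                boots.append(perf.auroc(lp[idx], y[idx]).auc)
        assert roc.se == pytest.approx(np.std(boots), rel=0.25)


class TestCompareAuroc:
    def test_identical_predictions(self):
        d, p = perf.compare_auroc([0.1, 0.5, 0.9], [0.1, 0.5, 0.9], [0, 1, 1])
        assert d == 0.0 and p == 1.0

    def test_true_model_beats_age_alone(self):
        rng = np.random.default_rng(5)
        n = 50_000
        age = rng.normal(65, 10, n)
        other = rng.normal(size=n)
        lp = 0.08 * (age - 65) + 1.2 * other
        y = (rng.random(n) < expit(-5.0 + lp)).astype(float)
        d, p = perf.compare_auroc(lp, age, y)
        assert d > 0 and p < 0.05

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(6)
        n = 400
        pvals = []
        for _ in range(200):
            x = rng.normal(size=n)
            z = rng.normal(size=n)
            y = np.r_[np.ones(40), np.zeros(n - 40)]
            rng.shuffle(y)
            _, p = perf.compare_auroc(x, z, y)
            pvals.append(p)
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01


class TestCalibrationDeciles:
    def test_ten_distinct_probabilities(self):
        p = np.linspace(0.01, 0.9, 10)
        y = (p > 0.5).astype(float)
        table = perf.calibration_deciles(p, y)
        assert (table["n"] == 1).all()
        assert set(table["observed_prevalence"]) <= {0.0, 1.0}

    def test_partition_and_case_conservation(self, models, small_cohort):
        lp = mr.linear_predictor(models["CHARGE-AF"], small_cohort)
        y = small_cohort["af_on_ecg"].to_numpy(float)
        alpha = mr.recalibrate_intercept(lp, y)
        p = mr.predicted_probability(alpha, lp)
        table = perf.calibration_deciles(p, y)
        assert table["n"].sum() == len(small_cohort)
        assert table["observed_cases"].sum() == y.sum()
        assert (table["mean_predicted"].diff().dropna() >= 0).all()
        # calibration-in-the-large identity after intercept update
        assert (table["mean_predicted"] * table["n"]).sum() == pytest.approx(y.sum(), rel=1e-9)

    def test_all_ties_stable_fill(self):
        p = np.full(25, 0.2)
        y = np.zeros(25)
        table = perf.calibration_deciles(p, y)
        assert table["n"].min() >= 2 and table["n"].max() <= 3

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            perf.calibration_deciles(np.full(5, 0.1), np.zeros(5))

    def test_wilson_cis_cover_diagonal_under_perfect_calibration(self):
        covered_all = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            p = expit(rng.normal(-5.5, 1.0, 50_000))
            y = (rng.random(50_000) < p).astype(float)
            table = perf.calibration_deciles(p, y)
            covered = (
                (table["ci_low"] <= table["mean_predicted"])
                & (table["mean_predicted"] <= table["ci_high"])
            ).sum()
            covered_all.append(covered)
        assert all(c >= 9 for c in covered_all)


class TestSumScoreTable:
    def test_hand_counts(self):
        table = perf.prevalence_by_sum_score([0, 0, 1, 1], [0, 0, 0, 1])
        assert table["score"].tolist() == [0, 1]
        assert table["n"].tolist() == [2, 2]
        assert table["observed_prevalence"].tolist() == [0.0, 0.5]

    def test_single_score_value(self):
        table = perf.prevalence_by_sum_score([2, 2, 2], [0, 1, 0])
        assert len(table) == 1
        assert table.loc[0, "observed_prevalence"] == pytest.approx(1 / 3)

    def test_monotone_when_outcome_generated_from_score(self):
        rng = np.random.default_rng(7)
        s = rng.integers(0, 7, 30_000)
        y = (rng.random(30_000) < expit(-6 + 0.8 * s)).astype(float)
        table = perf.prevalence_by_sum_score(s, y)
        rho, p = spearmanr(table["score"], table["observed_prevalence"])
        assert rho > 0 and p < 0.01


class TestPooledAuroc:
    def test_identical_copies_zero_between(self, models, small_cohort):
        import pandas as pd

        from afscreen.imputation import ImputationConfig, ImputedStack

        mask = pd.DataFrame(False, index=small_cohort.index, columns=small_cohort.columns)
        stack = ImputedStack(
            copies=[small_cohort, small_cohort.copy()],
            missing_mask=mask,
            config=ImputationConfig(m=2, iterations=1, seed=0),
        )
        pooled = perf.pool_auroc(stack, models["CHARGE-AF"])
        single = perf.auroc(
            mr.linear_predictor(models["CHARGE-AF"], small_cohort),
            small_cohort["af_on_ecg"].to_numpy(float),
        )
        assert pooled.point == pytest.approx(single.auc)
        assert pooled.between_variance == 0.0

    def test_matches_rubin_worked_example(self):
        from afscreen.imputation import pool_rubin

        pooled = pool_rubin([0.70, 0.74], [0.01, 0.01])
        assert pooled.total_variance == pytest.approx(1.3e-3)

    def test_exhaustive_small_cohorts_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            n = rng.integers(4, 31)
            pred = np.round(rng.normal(size=n), 1)  # induce ties
            y = np.zeros(n)
            y[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if y.sum() in (0, n):
                continue
            assert perf.auroc(pred, y).auc == pytest.approx(brute_force_auc(pred, y), rel=1e-12)
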