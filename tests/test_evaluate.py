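"""ROC/AUC evaluation: midrank estimator, stratified bootstrap, paired
comparisons (bootstrap + DeLong), stratified splitting, logistic model."""

import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats

from cpca import (
    auc,
    bootstrap_auc_ci,
    compare_paired_roc,
    delong_test,
    fit_logistic_cp,
    odds_percent_change,
    orient_marker,
    train_test_split,
)


def brute_force_auc(scores, status):
    """Pairwise oracle: P(non-case > case) + 1/2 P(tie)."""
    scores = np.asarray(scores, float)
    status = np.asarray(status).astype(bool)
    ctrls, cases = scores[~status], scores[status]
    total = 0.0
    for c in ctrls:
        for d in cases:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (ctrls.size * cases.size)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([3, 4, 1, 2], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert auc(np.ones(10), [0] * 5 + [1] * 5) == 0.5

    def test_mixed_ties_match_pair_oracle(self):
        # controls {1,3}, cases {2,3}: pairs (1,2)=0,(1,3)=0,(3,2)=1,(3,3)=.5
        scores = [1, 3, 2, 3]
        status = [0, 0, 1, 1]
        assert brute_force_auc(scores, status) == 0.375
        assert auc(scores, status) == 0.375

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])

    def test_negation_identity(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        assert auc(-s, y) == pytest.approx(1 - auc(s, y), abs=1e-12)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=80)
        y = rng.integers(0, 2, 80)
        y[0], y[1] = 0, 1
        assert auc(np.exp(s), y) == pytest.approx(auc(s, y), abs=1e-12)

    def test_matches_sklearn_direction_convention(self):
        # independent library oracle: protective AUC = roc_auc_score on -score
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        s = rng.normal(size=200) + rng.integers(0, 2, 200)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        assert auc(s, y) == pytest.approx(roc_auc_score(1 - y, s), abs=1e-12)

    def test_orient_marker_directions(self):
        y = np.array([0] * 5 + [1] * 5)
        risk = np.r_[np.zeros(5), np.ones(5)]   # cases higher -> -1
        assert orient_marker(risk, y) == -1
        assert orient_marker(-risk, y) == 1

    def test_odds_percent_change_printed_value(self):
        assert odds_percent_change(0.419) == pytest.approx(58.1, abs=1e-9)


class TestBootstrapCi:
    def test_degenerate_all_ties(self):
        res = bootstrap_auc_ci(np.ones(20), [0] * 10 + [1] * 10, n_boot=50, seed=0)
        assert (res.ci_low, res.ci_high) == (0.5, 0.5)

    def test_degenerate_perfect_separation(self):
        y = [0] * 10 + [1] * 10
        s = np.r_[np.ones(10), np.zeros(10)]
        res = bootstrap_auc_ci(s, y, n_boot=50, seed=0)
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_ci_low_never_exceeds_high(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            s = rng.normal(size=50)
            y = rng.integers(0, 2, 50)
            y[:2] = [0, 1]
            res = bootstrap_auc_ci(s, y, n_boot=200, seed=seed)
            assert res.ci_low <= res.ci_high

    def test_coverage_of_binormal_truth(self):
        # cases mean -1, controls mean 0, unit variance: AUC = Phi(1/sqrt(2))
        true_auc = stats.norm.cdf(1 / np.sqrt(2))
        rng = np.random.default_rng(4)
        covered = 0
        for i in range(100):
            ctrl = rng.normal(0.0, 1.0, 500)
            case = rng.normal(-1.0, 1.0, 500)
            s = np.r_[ctrl, case]
            y = np.r_[np.zeros(500), np.ones(500)].astype(int)
            res = bootstrap_auc_ci(s, y, n_boot=2000, seed=i)
            covered += res.ci_low <= true_auc <= res.ci_high
        assert covered >= 90


class TestPairedComparison:
    def test_identical_scores_null(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        res = compare_paired_roc(s, s, y, n_boot=200, seed=0)
        assert res.delta == 0.0 and res.p_value == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_paired_roc([1, 2], [1, 2, 3], [0, 1])

    def test_type_one_error_of_bootstrap_test(self):
        rng = np.random.default_rng(6)
        n = 150
        rejections = 0
        runs = 200
        for i in range(runs):
            y = np.r_[np.zeros(n), np.ones(n)].astype(int)
            a = rng.normal(size=2 * n)
            b = rng.normal(size=2 * n)
            res = compare_paired_roc(a, b, y, n_boot=200, seed=i)
            rejections += res.p_value < 0.05
        assert rejections / runs <= 0.10

    def test_power_strong_vs_weak_marker(self):
        rng = np.random.default_rng(7)
        n = 1000
        y = np.r_[np.zeros(n), np.ones(n)].astype(int)
        strong = np.r_[rng.normal(2.0, 1, n), rng.normal(0, 1, n)]
        weak = np.r_[rng.normal(0.5, 1, n), rng.normal(0, 1, n)]
        res = compare_paired_roc(strong, weak, y, n_boot=2000, seed=0)
        assert res.p_value < 1e-6 and res.delta > 0

    def test_bootstrap_and_delong_agree_within_corridor(self):
        rng = np.random.default_rng(8)
        n = 1000
        y = np.r_[np.zeros(n), np.ones(n)].astype(int)
        base = np.r_[rng.normal(0.6, 1, n), rng.normal(0, 1, n)]
        other = 0.6 * base + 0.8 * rng.normal(size=2 * n)
        boot = compare_paired_roc(base, other, y, n_boot=2000, seed=1)
        dl = delong_test(base, other, y)
        lo, hi = sorted([boot.p_value, dl.p_value])
        assert hi <= 3 * lo

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R unavailable")
    def test_delong_matches_pROC(self, tmp_path):
        rng = np.random.default_rng(42)
        n0, n1 = 80, 40
        a = np.r_[rng.normal(1, 1, n0), rng.normal(0, 1, n1)]
        b = 0.5 * a + np.r_[rng.normal(0, 1, n0), rng.normal(0, 1, n1)]
        y = np.r_[np.zeros(n0), np.ones(n1)].astype(int)
        f = tmp_path / "d.tsv"
        import pandas as pd

        pd.DataFrame({"y": y, "a": a, "b": b}).to_csv(f, sep="\t", index=False)
        script = (
            f'suppressMessages(library(pROC)); d <- read.delim("{f}");'
            'ra <- roc(d$y, d$a, direction=">", quiet=TRUE);'
            'rb <- roc(d$y, d$b, direction=">", quiet=TRUE);'
            't <- roc.test(ra, rb, method="delong");'
            'cat(auc(ra), auc(rb), t$p.value)'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True).stdout.split()
        r_auc_a, r_auc_b, r_p = map(float, out)
        res = delong_test(a, b, y)
        assert res.auc_a == pytest.approx(r_auc_a, abs=1e-6)
        assert res.auc_b == pytest.approx(r_auc_b, abs=1e-6)
        assert res.p_value == pytest.approx(r_p, rel=1e-4)


class TestSplit:
    def test_exact_stratification(self):
        y = np.r_[np.ones(100), np.zeros(900)].astype(int)
        tr, te = train_test_split(y, 0.70, seed=0)
        assert y[tr].sum() == 70 and tr.size == 700
        assert y[te].sum() == 30 and te.size == 300

    def test_disjoint_and_exhaustive(self):
        y = np.random.default_rng(9).integers(0, 2, 157)
        y[:2] = [0, 1]
        tr, te = train_test_split(y, 0.70, seed=1)
        assert np.array_equal(np.sort(np.r_[tr, te]), np.arange(157))
        assert np.intersect1d(tr, te).size == 0

    def test_seed_determinism(self):
        y = np.random.default_rng(10).integers(0, 2, 500)
        a = train_test_split(y, 0.70, seed=7)
        b = train_test_split(y, 0.70, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestLogistic:
    @staticmethod
    def _simulate(n, log_or, seed):
        rng = np.random.default_rng(seed)
        cp = rng.normal(size=n)
        age = rng.uniform(40, 70, n)
        sex = rng.integers(0, 2, n)
        eta = -2.0 + log_or * cp + 0.01 * (age - 55) + 0.1 * sex
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return cp, age, sex, y

    def test_null_cp_odds_ratio_near_one(self):
        cp, age, sex, y = self._simulate(10000, 0.0, seed=11)
        res = fit_logistic_cp(cp, y, age, sex)
        assert 0.9 <= res.odds_ratio <= 1.1

    def test_parameter_recovery_of_printed_or(self):
        # log-OR -0.87 per CP unit -> OR exp(-0.87) = 0.419
        cp, age, sex, y = self._simulate(50000, -0.87, seed=12)
        res = fit_logistic_cp(cp, y, age, sex)
        assert abs(res.odds_ratio - 0.419) < 0.05
        assert res.ci_low < res.odds_ratio < res.ci_high
        assert res.converged and not res.separation_flag

    def test_separation_flagged(self):
        n = 200
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        cp = np.r_[np.ones(n // 2), -np.ones(n // 2)] + \
            np.random.default_rng(13).normal(0, 0.01, n)
        age = np.full(n, 50.0)
        sex = np.tile([0, 1], n // 2)
        try:
            res = fit_logistic_cp(cp, y, age, sex)
            assert res.separation_flag
        except RuntimeError:
            pass  # full separation may abort the MLE instead
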