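import itertools

import numpy as np
import pytest
from scipy import stats as sps

from erpmarker.stats import (RocResult, auc_ci_hanley,
                             bonferroni, chi_square_2x2, fisher_ci,
                             gender_balanced_roc, mann_whitney,
                             mann_whitney_z_from_u, pearson_with_ci, roc_auc,
                             select_cutoff)


def brute_force_auc(pos, neg):
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert roc.operating_point.sensitivity == 1.0
        assert roc.operating_point.specificity == 1.0

    def test_constant_scores_give_auc_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == 0.5

    def test_worked_four_subject_example(self):
        # healthy 0.9, 0.8 vs patients 0.7, 0.85: wins 0.9>0.7, 0.9>0.85,
        # 0.8>0.7; loss 0.8<0.85 -> 3 of 4 pairs
        roc = roc_auc([0.9, 0.8, 0.7, 0.85], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(
            brute_force_auc([0.9, 0.8], [0.7, 0.85]))
        assert roc.auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_auc_equals_brute_force_pairwise_count(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = rng.integers(3, 11, size=2)
        scores = np.round(rng.normal(size=n_pos + n_neg), 1)  # force ties
        labels = np.array([1] * n_pos + [0] * n_neg)
        expected = brute_force_auc(scores[:n_pos], scores[n_pos:])
        assert roc_auc(scores, labels).auc == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_auc_of_negated_scores_is_the_complement(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=12)  # continuous, tie-free
        labels = rng.integers(0, 2, size=12)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels).auc
        b = roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_is_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestHanleyCi:
    def test_reproduces_the_reported_auc_interval(self):
        lo, hi = auc_ci_hanley(0.79, n_pos=19, n_neg=30)
        assert round(lo, 2) == 0.65
        assert round(hi, 2) == 0.93

    def test_interval_collapses_for_huge_samples(self):
        lo, hi = auc_ci_hanley(0.5, 10 ** 6, 10 ** 6)
        assert hi - lo < 1e-2

    def test_halfwidth_shrinks_monotonically_with_n(self):
        widths = [np.diff(auc_ci_hanley(0.79, n, n))[0]
                  for n in (5, 10, 20, 40, 80, 160)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_matches_bootstrap_interval_at_study_sizes(self):
        rng = np.random.default_rng(11)
        pos = rng.normal(1.0, 1.0, size=19)
        neg = rng.normal(0.0, 1.0, size=30)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * 19 + [0] * 30)
        auc = roc_auc(scores, labels).auc
        lo, hi = auc_ci_hanley(auc, 19, 30)
        boots = np.empty(10_000)
        for b in range(10_000):
            bp = pos[rng.integers(0, 19, 19)]
            bn = neg[rng.integers(0, 30, 30)]
            boots[b] = (bp[:, None] > bn[None, :]).mean()
        blo, bhi = np.quantile(boots, [0.025, 0.975])
        assert lo == pytest.approx(blo, abs=0.03)
        assert hi == pytest.approx(bhi, abs=0.03)

    def test_degenerate_inputs_are_rejected(self):
        with pytest.raises(ValueError):
            auc_ci_hanley(1.0, 10, 10)
        with pytest.raises(ValueError):
            auc_ci_hanley(0.8, 1, 10)


class TestSelectCutoff:
    def _roc(self, scores, labels):
        return roc_auc(np.asarray(scores), np.asarray(labels))

    def test_cutoff_rule_matches_exhaustive_threshold_search(self):
        scores = np.array([0.95, 0.9, 0.65, 0.6, 0.4, 0.2])
        labels = np.array([1, 0, 1, 1, 0, 0])
        roc = self._roc(scores, labels)
        best = None
        for thr in np.concatenate([[np.inf], np.unique(scores)[::-1]]):
            pred = scores >= thr
            sens = pred[labels == 1].mean()
            spec = (~pred[labels == 0]).mean()
            if spec > 0.5 and (best is None or sens > best[0]
                               or (sens == best[0] and spec > best[1])):
                best = (sens, spec)
        op = roc.operating_point
        assert (op.sensitivity, op.specificity) == pytest.approx(best)

    def test_monotone_score_transforms_keep_the_operating_point(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=14)
        labels = np.array([1] * 7 + [0] * 7)
        a = self._roc(scores, labels).operating_point
        b = self._roc(np.exp(scores), labels).operating_point
        assert a.sensitivity == pytest.approx(b.sensitivity)
        assert a.specificity == pytest.approx(b.specificity)

    def test_no_above_chance_specificity_is_flagged(self):
        roc = RocResult(thresholds=np.array([np.inf, 0.5]),
                        sensitivity=np.array([0.0, 1.0]),
                        specificity=np.array([0.4, 0.2]), auc=0.5)
        op = select_cutoff(roc)
        assert not op.above_chance
        assert op.specificity == 0.4


class TestMannWhitney:
    def test_reproduces_the_reported_z_and_p_from_u(self):
        # normal approximation with continuity correction
        z, p = mann_whitney_z_from_u(120.0, 19, 30)
        assert round(z, 2) == -3.38
        assert float(f"{p:.1g}") == 0.0007

    def test_identical_samples_give_z_zero_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert abs(res.extra["z"]) < 1e-9
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed,n", [(0, 4), (1, 5), (2, 6)])
    def test_normal_approximation_close_to_exact_permutation_p(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.8, 1, size=n)
        y = rng.normal(0.0, 1, size=n)
        res = mann_whitney(x, y)
        combined = np.concatenate([x, y])
        u_obs = res.statistic
        mu = n * n / 2.0
        count = 0
        total = 0
        for idx in itertools.combinations(range(2 * n), n):
            xs = combined[list(idx)]
            ranks = sps.rankdata(combined)
            u = sps.rankdata(combined)[list(idx)].sum() - n * (n + 1) / 2
            if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
                count += 1
            total += 1
        exact_p = count / total
        assert res.p == pytest.approx(exact_p, abs=0.05)

    def test_agrees_with_scipy_asymptotic_p(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.5, 1, size=19)
        y = rng.normal(0.0, 1, size=30)
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        assert res.statistic == ref.statistic
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_tie_correction_matches_scipy_with_ties(self):
        x = [1, 2, 2, 3, 5, 5]
        y = [2, 2, 4, 5, 6]
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_is_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestPearson:
    def test_reproduces_the_reported_motor_score_interval(self):
        lo, hi = fisher_ci(0.70, 19)
        assert (round(lo, 2), round(hi, 2)) == (0.36, 0.88)

    def test_reproduces_the_reported_null_dose_interval(self):
        lo, hi = fisher_ci(0.075, 19)
        assert (round(lo, 2), round(hi, 2)) == (-0.39, 0.51)

    def test_exact_linear_relation_gives_r_one_clipped_ci(self):
        x = np.arange(10.0)
        res = pearson_with_ci(x, x)
        assert res.statistic == pytest.approx(1.0)
        assert res.p < 1e-30
        assert res.ci95[1] == pytest.approx(1.0)

    def test_p_value_matches_scipy(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=19)
        y = 0.6 * x + rng.normal(size=19)
        res = pearson_with_ci(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.statistic == pytest.approx(r_ref)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_p_close_to_large_permutation_null(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=19)
        y = 0.55 * x + rng.normal(size=19)
        res = pearson_with_ci(x, y)
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        n_perm = 100_000
        keys = rng.random((n_perm, 19)).argsort(axis=1)
        perm_r = (yc[keys] @ xc) / denom
        perm_p = (np.abs(perm_r) >= abs(res.statistic) - 1e-12).mean()
        assert res.p == pytest.approx(perm_p, abs=0.005)

    def test_zero_variance_input_is_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci(np.ones(10), np.arange(10.0))


class TestChiSquare:
    def test_balanced_table_has_zero_statistic(self):
        res = chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_gender_table_closed_form(self):
        # n(ad-bc)^2 / (row and column products), uncorrected
        res = chi_square_2x2([[16, 3], [15, 15]])
        n, a, b, c, d = 49, 16, 3, 15, 15
        expected = n * (a * d - b * c) ** 2 / (19 * 30 * 31 * 18)
        assert res.statistic == pytest.approx(expected)
        assert round(res.statistic, 2) == 5.86

    def test_statistic_is_homogeneous_of_degree_one_in_counts(self):
        base = chi_square_2x2([[8, 3], [5, 9]]).statistic
        doubled = chi_square_2x2([[16, 6], [10, 18]]).statistic
        assert doubled == pytest.approx(2 * base)

    def test_yates_correction_flag(self):
        plain = chi_square_2x2([[16, 3], [15, 15]], correction=False)
        yates = chi_square_2x2([[16, 3], [15, 15]], correction=True)
        assert yates.statistic < plain.statistic

    def test_zero_margin_is_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestBonferroni:
    def test_scales_and_clips(self):
        np.testing.assert_allclose(bonferroni([0.005, 0.4], 5), [0.025, 1.0])

    def test_single_comparison_is_identity(self):
        np.testing.assert_allclose(bonferroni([0.3, 0.01], 2)[0], 0.6)
        np.testing.assert_allclose(bonferroni([0.3], 1), [0.3])

    def test_k_below_count_is_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)


class TestGenderBalancedRoc:
    def _cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.concatenate([rng.normal(1, 1, 19),  # patients
                                 rng.normal(0, 1, 30)])  # controls
        labels = np.array([1] * 19 + [0] * 30)
        sex = np.array(["M"] * 16 + ["F"] * 3 + ["M"] * 15 + ["F"] * 15)
        return scores, labels, sex

    def test_taking_all_females_in_one_iteration_equals_full_roc(self):
        scores, labels, sex = self._cohort()
        full = roc_auc(scores, labels).auc
        out = gender_balanced_roc(scores, labels, sex, n_females=15,
                                  n_iter=1, seed=5)
        assert out["mean_auc"] == pytest.approx(full)

    def test_same_seed_reproduces_the_iterations(self):
        scores, labels, sex = self._cohort()
        a = gender_balanced_roc(scores, labels, sex, seed=7)
        b = gender_balanced_roc(scores, labels, sex, seed=7)
        assert a["aucs"] == b["aucs"]

    def test_female_draws_are_disjoint_across_iterations(self):
        scores, labels, sex = self._cohort()
        # 5 iterations x 3 females exactly exhausts the 15 HC females
        out = gender_balanced_roc(scores, labels, sex, n_females=3, n_iter=5,
                                  seed=1)
        assert len(out["aucs"]) == 5

    def test_perfect_separation_survives_every_subsample(self):
        scores = np.array([1.0] * 19 + [0.0] * 30)
        labels = np.array([1] * 19 + [0] * 30)
        sex = np.array(["M"] * 19 + ["M"] * 15 + ["F"] * 15)
        out = gender_balanced_roc(scores, labels, sex, seed=2)
        assert out["aucs"] == [1.0] * 5

    def test_insufficient_females_is_an_error(self):
        scores, labels, sex = self._cohort()
        with pytest.raises(ValueError, match="female"):
            gender_balanced_roc(scores, labels, sex, n_females=4, n_iter=5)
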