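"""Statistical layer against closed forms, enumeration and bootstrap oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from fetcu import (
    compare_paired_auc,
    holm_sidak,
    kruskal_wallis_dunn,
    logistic_accuracy,
    mann_whitney_u,
    roc_delong,
    spearman,
    wilcoxon_signed_rank,
    youden_optimal,
)


def brute_force_auc(scores, labels):
    """Pairwise concordance count with ties at 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, labels, direction="greater"):
    """Exhaustive scan over all distinct operating points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    best_j = -np.inf
    cand = np.concatenate([[-np.inf], np.unique(scores), [np.inf]])
    for t in cand:
        pred = scores >= t if direction == "greater" else scores <= t
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        best_j = max(best_j, sens + spec - 1.0)
    return best_j


class TestDelong:
    def test_known_auc(self):
        res = roc_delong([1, 2, 3, 4], [0, 1, 0, 1])
        assert res.auc == pytest.approx(0.75)
        assert res.n_pos == res.n_neg == 2

    def test_perfect_separation(self):
        res = roc_delong([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.se_auc == 0.0
        assert res.sensitivity == res.specificity == 1.0

    def test_auc_equals_mannwhitney_u_identity(self, rng):
        for _ in range(200):
            n1, n0 = rng.integers(3, 12, size=2)
            scores = np.round(rng.random(n1 + n0) * 10, 1)  # induce ties
            labels = np.r_[np.ones(n1, bool), np.zeros(n0, bool)]
            res = roc_delong(scores, labels, direction="greater")
            u = sps.mannwhitneyu(scores[labels], scores[~labels]).statistic
            assert res.auc == pytest.approx(u / (n1 * n0), abs=1e-12)
            assert res.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_auc_invariant_under_monotone_transforms(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        labels[:2] = True
        labels[-2:] = False
        base = roc_delong(scores, labels).auc
        assert roc_delong(np.exp(scores), labels).auc == pytest.approx(base)
        assert roc_delong(sps.rankdata(scores), labels).auc == pytest.approx(base)

    def test_direction_auto_detection(self, rng):
        scores = np.r_[rng.normal(5, 1, 20), rng.normal(2, 1, 20)]
        labels = np.r_[np.zeros(20, bool), np.ones(20, bool)]  # positives low
        res = roc_delong(scores, labels)
        assert res.direction == "less"
        assert res.auc >= 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_delong([1, 2, 3], [1, 1, 1])


class TestPairedDelong:
    def test_identical_scores_no_difference(self):
        s = [1.0, 4.0, 2.0, 8.0, 3.0, 9.0]
        y = [0, 1, 0, 1, 0, 1]
        delta, se, p = compare_paired_auc(s, s, y)
        assert delta == 0.0
        assert p == 1.0

    def test_antisymmetry(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        y = rng.random(30) < 0.5
        y[:3], y[-3:] = True, False
        d1, se1, p1 = compare_paired_auc(a, b, y)
        d2, se2, p2 = compare_paired_auc(b, a, y)
        assert d1 == pytest.approx(-d2)
        assert se1 == pytest.approx(se2)
        assert p1 == pytest.approx(p2)

    def test_se_matches_subject_bootstrap(self, rng):
        n = 40
        y = np.r_[np.ones(16, bool), np.zeros(24, bool)]
        latent = rng.normal(size=n) + y * 1.2
        a = latent + rng.normal(0, 0.6, n)
        b = latent + rng.normal(0, 1.2, n)
        _, se, _ = compare_paired_auc(a, b, y)
        deltas = []
        pos_idx, neg_idx = np.flatnonzero(y), np.flatnonzero(~y)
        for _ in range(10000):
            bi = np.r_[rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
            deltas.append(
                brute_force_auc(a[bi], y[bi]) - brute_force_auc(b[bi], y[bi])
            )
        boot_se = np.std(deltas, ddof=1)
        assert se == pytest.approx(boot_se, rel=0.25)


class TestYouden:
    def test_separable_example(self):
        thr, sens, spec, acc = youden_optimal([1, 2, 3, 4], [0, 0, 1, 1])
        assert thr == pytest.approx(2.5)
        assert sens == spec == acc == 1.0

    def test_equals_bruteforce_on_random_data(self, rng):
        for _ in range(200):
            n = rng.integers(6, 25)
            scores = np.round(rng.random(n) * 5, 1)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            thr, sens, spec, _ = youden_optimal(scores, labels, direction="greater")
            assert sens + spec - 1.0 == pytest.approx(
                brute_force_youden(scores, labels), abs=1e-12
            )
            # returned threshold actually achieves the reported operating point
            pred = scores >= thr
            assert (pred & labels).sum() / labels.sum() == pytest.approx(sens)

    def test_direction_less_negation_symmetry(self, rng):
        scores = rng.normal(size=20)
        labels = rng.random(20) < 0.5
        labels[:2], labels[-2:] = True, False
        t_g, sens_g, spec_g, _ = youden_optimal(scores, labels, direction="greater")
        t_l, sens_l, spec_l, _ = youden_optimal(-scores, labels, direction="less")
        assert t_l == pytest.approx(-t_g)
        assert (sens_l, spec_l) == (sens_g, spec_g)


class TestMannWhitney:
    def test_exact_small_sample(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic_value == 0
        assert res.p_value == pytest.approx(2 / 6)
        assert res.effect["method"] == "exact"

    def test_null_u_expectation(self, rng):
        us = []
        for _ in range(300):
            x, y = rng.normal(size=8), rng.normal(size=9)
            res = sps.mannwhitneyu(x, y)
            us.append(res.statistic)
        assert np.mean(us) == pytest.approx(8 * 9 / 2, rel=0.05)

    def test_exact_vs_asymptotic_agreement_n12(self, rng):
        for _ in range(30):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            exact = mann_whitney_u(x, y).p_value
            approx = float(
                sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            )
            assert abs(exact - approx) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_all_positive_differences(self):
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 2, 3, 4, 5], tails="one")
        assert res.p_value == pytest.approx(1 / 32)

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([1, 2, 5], [1, 2, 3], tails="one")
        assert res.n == (1,)
        assert res.effect["n_zero_dropped"] == 2

    def test_matches_scipy_exact_enumeration(self, rng):
        for _ in range(30):
            d = rng.normal(size=8)
            x = d + 10.0
            y = np.full(8, 10.0)
            ours = wilcoxon_signed_rank(x, y, tails="two")
            ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestKruskalDunn:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res, table = kruskal_wallis_dunn([g, g, g])
        assert res.p_value > 0.99
        assert all(row["p_adjusted"] == pytest.approx(1.0, abs=0.01) for row in table)

    def test_hand_ranked_example(self):
        # groups (1,2,3), (4,5,6), (7,8,9): mean ranks 2, 5, 8
        # H = 12/(9*10) * 3*((2-5)^2 + 0 + (8-5)^2) * ... = 7.2
        res, _ = kruskal_wallis_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic_value == pytest.approx(7.2)

    def test_chi_square_p_close_to_permutation(self, rng):
        groups = [rng.normal(size=10), rng.normal(0.5, 1, size=10), rng.normal(1.0, 1, size=10)]
        res, _ = kruskal_wallis_dunn(groups)
        pooled = np.concatenate(groups)
        h_obs = res.statistic_value
        count = 0
        n_perm = 10000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            h, _ = sps.kruskal(pooled[:10], pooled[10:20], pooled[20:])
            count += h >= h_obs - 1e-12
        p_perm = count / n_perm
        mc_err = 3 * math.sqrt(max(p_perm * (1 - p_perm), 1e-4) / n_perm)
        assert abs(res.p_value - p_perm) < max(0.02, mc_err + 0.01)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_dunn([[1, 2], [3, 4]])


class TestHolmSidak:
    def test_hand_computed_pair(self):
        adj = holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2)
        assert adj[1] == pytest.approx(0.04)

    def test_degenerate_cases(self):
        assert holm_sidak([0.3]) == pytest.approx([0.3])
        assert np.all(holm_sidak([0.0, 0.0, 0.0]) == 0.0)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(rng.integers(2, 10))
            ours = holm_sidak(p)
            theirs = multipletests(p, method="holm-sidak")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.2])


class TestSpearman:
    def test_monotone_perfect_correlation(self):
        x = [1.0, 2.0, 5.0, 9.0, 12.0]
        assert spearman(x, [2, 3, 7, 8, 20]).statistic_value == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).statistic_value == pytest.approx(-1.0)

    def test_exact_permutation_matches_scipy_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            ours = spearman(x, y)

            def stat(yy):
                return sps.spearmanr(x, yy).statistic

            ref = sps.permutation_test(
                (y,),
                stat,
                permutation_type="pairings",
                n_resamples=np.inf,
                alternative="two-sided",
            )
            assert ours.statistic_value == pytest.approx(float(sps.spearmanr(x, y).statistic))
            assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLogistic:
    def test_perfect_separation_flagged(self):
        intercept, slope, acc, separated = logistic_accuracy(
            [1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]
        )
        assert separated
        assert acc == 1.0

    def test_uninformative_score_accuracy_near_base_rate(self, rng):
        score = rng.normal(size=400)
        labels = np.r_[np.ones(240, bool), np.zeros(160, bool)]
        _, _, acc, separated = logistic_accuracy(score, labels)
        assert not separated
        assert acc == pytest.approx(0.6, abs=0.05)

    def test_loglikelihood_matches_grid_search(self):
        score = np.array([0.1, 0.4, 0.35, 0.8, 0.23, 0.76, 0.55, 0.62, 0.9, 0.05])
        labels = np.array([0, 0, 1, 1, 0, 1, 0, 1, 1, 0])
        intercept, slope, _, separated = logistic_accuracy(score, labels)
        assert not separated

        def loglike(b0, b1):
            eta = b0 + b1 * score
            return float(np.sum(labels * eta - np.log1p(np.exp(eta))))

        ll_fit = loglike(intercept, slope)
        grid = [
            loglike(b0, b1)
            for b0 in np.linspace(intercept - 2, intercept + 2, 60)
            for b1 in np.linspace(slope - 3, slope + 3, 60)
        ]
        assert ll_fit >= max(grid) - 1e-4
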