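"""Malignancy scoring, LOO-CV, ROC/AUC, search, RRS, ROC comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmwi.classify import (
    ClassifierConfig,
    FeatureSource,
    compare_roc,
    confusion_at_cutoff,
    feature_folds,
    fit_learning_curve,
    loocv,
    optimum_point,
    per_class_accuracy,
    reproducibility_variance,
    roc_curve,
    rrs_extrapolate,
    search_pc_combinations,
    train_and_score,
)
from mmwi.synthesis import UWBSignal


def gaussian_features(rng, n_per_class, d=2, sep=3.0):
    X = np.vstack(
        [
            rng.standard_normal((n_per_class, d)),
            rng.standard_normal((n_per_class, d)) + sep / np.sqrt(d),
        ]
    )
    y = np.repeat([0, 1], n_per_class)
    return X, y


class TestTrainAndScore:
    def test_lda_separated_classes_score_sides_of_half(self):
        Xtr = np.array([[-2.0], [-1.5], [-1.0], [1.0], [1.5], [2.0]])
        ytr = np.array([0, 0, 0, 1, 1, 1])
        s = train_and_score(
            ClassifierConfig("LDA", (1,)), Xtr, ytr, np.array([[-1.8], [1.8]])
        )
        assert s[0] < 0.5 < s[1]

    def test_knn_k1_coincident_benign_point_scores_zero(self):
        Xtr = np.array([[0.0, 0.0], [3.0, 3.0]])
        ytr = np.array([0, 1])
        s = train_and_score(
            ClassifierConfig("KNN", (1, 1), k_neighbors=1), Xtr, ytr, [[0.0, 0.0]]
        )
        assert s[0] == 0.0

    def test_lda_posterior_matches_closed_form_bayes(self):
        # two unit-variance Gaussians at -1 and +1: p(mal|x) = 1/(1+exp(-2x));
        # the fitted posterior at n=500/class is averaged over independent
        # draws to suppress the estimator's sampling variance
        n = 500
        xs = np.linspace(-2, 2, 9)[:, None]
        fits = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            Xtr = np.concatenate([rng.normal(-1, 1, n), rng.normal(1, 1, n)])[:, None]
            ytr = np.repeat([0, 1], n)
            fits.append(train_and_score(ClassifierConfig("LDA", (1,)), Xtr, ytr, xs))
        bayes = 1.0 / (1.0 + np.exp(-2.0 * xs.ravel()))
        assert np.max(np.abs(np.mean(fits, axis=0) - bayes)) < 0.02

    @pytest.mark.parametrize(
        "config",
        [
            ClassifierConfig("LDA", (1, 1)),
            ClassifierConfig("KNN", (1, 1), k_neighbors=3),
            ClassifierConfig("LSVM", (1, 1), c=1.0),
            ClassifierConfig("GSVM", (1, 1), c=1.0),
            ClassifierConfig("MLP", (1, 1), mlp_max_iter=300),
        ],
    )
    def test_every_family_scores_in_unit_interval_and_separates(self, config):
        rng = np.random.default_rng(1)
        Xtr, ytr = gaussian_features(rng, 25, d=2, sep=4.0)
        Xte, yte = gaussian_features(rng, 10, d=2, sep=4.0)
        s = train_and_score(config, Xtr, ytr, Xte)
        assert np.all((s >= 0) & (s <= 1))
        assert roc_curve(s, yte).auc > 0.9

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_and_score(
                ClassifierConfig("LDA", (1,)), np.zeros((4, 1)), np.zeros(4), [[0.0]]
            )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ClassifierConfig("KNN", (1, 0))  # missing K
        with pytest.raises(ValueError):
            ClassifierConfig("LSVM", (1,))  # missing C
        with pytest.raises(ValueError):
            ClassifierConfig("LDA", (0, 0))  # empty mask
        with pytest.raises(ValueError):
            ClassifierConfig("LDA", (1,), c=1.0)  # stray hyperparameter


def small_cube_source(rng, n_per_class=6, k_final=3, offset=3.0):
    from tests.test_pca3d import class_cohort

    cubes, labels = class_cohort(rng, n_per_class, offset=offset)
    return FeatureSource(labels=labels, cubes=cubes, k_final=k_final,
                         target_depth_samples=10)


class TestLoocv:
    def test_n_folds_each_lesion_tested_once(self):
        rng = np.random.default_rng(2)
        X, y = gaussian_features(rng, 8)
        src = FeatureSource(labels=y, features=X)
        res = loocv(ClassifierConfig("LDA", (1, 1)), src)
        assert res.scores.shape == (16,)
        assert not np.any(np.isnan(res.scores))
        assert np.array_equal(res.folds, np.arange(16))

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        src = small_cube_source(rng)
        cfg = ClassifierConfig("MLP", (1, 1, 1), mlp_max_iter=200, seed=7)
        a = loocv(cfg, src)
        b = loocv(cfg, src)
        assert np.array_equal(a.scores, b.scores)

    def test_leaky_pca_variant_differs_from_proper_refits(self):
        # weak class separation keeps the posteriors off the 0/1 rails so the
        # leakage of test cubes into the PCA fit is visible in the scores
        rng = np.random.default_rng(4)
        src = small_cube_source(rng, offset=0.02)
        cfg = ClassifierConfig("LDA", (1, 1, 1))
        proper = loocv(cfg, src, refit_per_fold=True)
        leaky = loocv(cfg, src, refit_per_fold=False)
        assert not np.allclose(proper.scores, leaky.scores)

    def test_per_fold_refits_never_see_test_cube(self):
        rng = np.random.default_rng(5)
        src = small_cube_source(rng)
        folds = feature_folds(src)
        # mutating the held-out cube after fold construction must not change
        # any fold's training features (they were derived without it)
        for i, (Xtr, ytr, _) in enumerate(folds):
            assert Xtr.shape[0] == src.n - 1
            assert ytr.size == src.n - 1


class TestConfusionAndROC:
    def test_perfect_two_lesion_case(self):
        counts, sens, spec = confusion_at_cutoff([0.9, 0.1], [1, 0])
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (1, 1, 0, 0)
        assert sens == 1.0 and spec == 1.0

    def test_scores_at_cutoff_are_negative_calls(self):
        counts, sens, spec = confusion_at_cutoff([0.5, 0.5], [1, 0], cutoff=0.5)
        assert counts.tp == 0 and counts.fn == 1 and counts.tn == 1

    def test_counts_match_brute_force_loop(self):
        rng = np.random.default_rng(6)
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        counts, _, _ = confusion_at_cutoff(s, y, 0.4)
        tp = fp = tn = fn = 0
        for si, yi in zip(s, y):
            if si > 0.4:
                tp, fp = tp + (yi == 1), fp + (yi == 0)
            else:
                tn, fn = tn + (yi == 0), fn + (yi == 1)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (tp, fp, tn, fn)
        assert counts.n == 50

    def test_no_positives_reports_missing_sensitivity(self):
        _, sens, spec = confusion_at_cutoff([0.2, 0.8], [0, 0])
        assert sens is None and spec is not None

    def test_perfectly_separated_auc_one(self):
        roc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.auc == 1.0
        assert roc.fpr[0] == 0.0 and roc.tpr[-1] == 1.0

    def test_trapezoid_auc_equals_pairwise_concordance(self):
        rng = np.random.default_rng(7)
        s = rng.random(20)
        s[5] = s[12]  # force a tie
        y = rng.integers(0, 2, 20)
        if y.sum() in (0, 20):
            y[:3] = [0, 1, 0]
        roc = roc_curve(s, y)
        pos, neg = s[y == 1], s[y == 0]
        conc = np.mean(
            [(1.0 if p > n else 0.5 if p == n else 0.0) for p in pos for n in neg]
        )
        assert abs(roc.auc - conc) < 1e-12

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(8)
        n = 2000
        s = rng.random(n)
        y = rng.integers(0, 2, n)
        auc = roc_curve(s, y).auc
        n1, n0 = (y == 1).sum(), (y == 0).sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))  # Hanley-McNeil null SE
        assert abs(auc - 0.5) < 3 * se

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.random(30)
        y = np.concatenate([np.zeros(15, int), np.ones(15, int)])
        rng.shuffle(y)
        a1 = roc_curve(s, y).auc
        a2 = roc_curve(np.exp(3 * s) - 1, y).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.9], [1, 1])


class TestOptimumPoint:
    def test_perfect_classifier_hits_corner(self):
        roc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        _, sens, spec = optimum_point(roc)
        assert sens == 1.0 and spec == 1.0

    def test_tie_broken_toward_higher_sensitivity(self):
        # all scores equal: Youden = 0 everywhere; pick max-sensitivity point
        roc = roc_curve([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        _, sens, _ = optimum_point(roc)
        assert sens == 1.0

    def test_matches_exhaustive_threshold_enumeration(self):
        rng = np.random.default_rng(9)
        s = rng.random(25)
        y = rng.integers(0, 2, 25)
        if y.sum() in (0, 25):
            y[0] = 1 - y[0]
        roc = roc_curve(s, y)
        _, sens, spec = optimum_point(roc)
        best = -1.0
        for t in np.concatenate([[-np.inf], np.sort(s), [np.inf]]):
            _, se, sp = confusion_at_cutoff(s, y, t)
            best = max(best, se + sp - 1)
        assert sens + spec - 1 == pytest.approx(best, abs=1e-12)


class TestSearch:
    def test_planted_signal_pc_recovered_by_every_family(self):
        rng = np.random.default_rng(10)
        n = 30
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 4)) * 0.5
        X[:, 1] += 3.0 * y  # only PC2 carries class signal
        src = FeatureSource(labels=y, features=X)
        table = search_pc_combinations(
            src,
            families=("LDA", "KNN", "LSVM", "GSVM", "MLP"),
            grids={"KNN": (3,), "LSVM": (1.0,), "GSVM": (1.0,)},
            mlp_max_iter=300,
        )
        assert len(table) == 5
        assert set(table["family"]) == {"LDA", "KNN", "LSVM", "GSVM", "MLP"}
        for mask in table["pc_mask"]:
            assert mask[2] == "1"  # PC2 bit inside "[....]"

    def test_mask_enumeration_count(self):
        from mmwi.classify import _all_masks

        masks = list(_all_masks(6))
        assert len(masks) == 63
        assert all(sum(m) >= 1 for m in masks)
        assert len(set(masks)) == 63

    def test_empty_family_list_rejected(self):
        rng = np.random.default_rng(11)
        X, y = gaussian_features(rng, 6)
        with pytest.raises(ValueError):
            search_pc_combinations(FeatureSource(labels=y, features=X), families=())


class TestPerClassAccuracy:
    def test_all_correct_gives_hundred_everywhere(self):
        s = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([1, 1, 0, 0])
        st_ = np.array(["melanoma", "melanoma", "nevus", "nevus"])
        acc = per_class_accuracy(s, y, st_)
        assert acc["melanoma"] == 100 and acc["nevus"] == 100

    def test_seven_of_eight_rounds_to_88(self):
        s = np.array([0.9] * 7 + [0.1])
        y = np.ones(8, int)
        st_ = np.array(["squamous_cell_carcinoma"] * 8)
        acc = per_class_accuracy(s, y, st_)
        assert acc["squamous_cell_carcinoma"] == 88

    def test_matches_brute_force_per_subtype_loop(self):
        rng = np.random.default_rng(12)
        n = 60
        s = rng.random(n)
        subtypes = rng.choice(["a", "b", "c"], n)
        y = (subtypes == "a").astype(int)  # subtype 'a' malignant
        acc = per_class_accuracy(s, y, subtypes, cutoff=0.5)
        for sub in "abc":
            idx = subtypes == sub
            mal = bool(y[idx][0])
            correct = sum(
                (si > 0.5) == mal if mal else (si <= 0.5)
                for si in s[idx]
            )
            expected = int(np.floor(100 * correct / idx.sum() + 0.5))
            assert acc[sub] == expected


class TestRRS:
    def test_recovers_planted_learning_curve_plateau(self):
        rng = np.random.default_rng(13)
        a, b, alpha = 0.10, 0.8, 0.7
        sizes = np.array([20, 40, 80, 160, 320, 640, 1280])
        errors = a + b * sizes ** (-alpha) + rng.normal(0, 0.003, sizes.size)
        a_hat, b_hat, alpha_hat = fit_learning_curve(sizes, errors)
        assert abs(a_hat - a) / a <= 0.20

    def test_flat_curve_plateau_matches_observed_error(self):
        sizes = np.array([20, 40, 80, 160])
        errors = np.full(4, 0.25)
        a_hat, b_hat, _ = fit_learning_curve(sizes, errors)
        assert a_hat == pytest.approx(0.25, abs=0.02)
        assert abs(b_hat) < 0.2

    def test_rrs_deterministic_and_reports_curve(self):
        rng = np.random.default_rng(14)
        X, y = gaussian_features(rng, 30, sep=2.0)
        src = FeatureSource(labels=y, features=X)
        cfg = ClassifierConfig("LDA", (1, 1))
        r1 = rrs_extrapolate(cfg, src, [10, 20, 40], reps=10, seed=5)
        r2 = rrs_extrapolate(cfg, src, [10, 20, 40], reps=10, seed=5)
        assert np.array_equal(r1.mean_errors, r2.mean_errors)
        assert r1.extrapolated_error == r2.extrapolated_error
        assert r1.mean_errors.shape == (3,)

    def test_input_validation(self):
        rng = np.random.default_rng(15)
        X, y = gaussian_features(rng, 10)
        src = FeatureSource(labels=y, features=X)
        cfg = ClassifierConfig("LDA", (1, 1))
        with pytest.raises(ValueError):
            rrs_extrapolate(cfg, src, [5, 10], reps=10)  # too few sizes
        with pytest.raises(ValueError):
            rrs_extrapolate(cfg, src, [5, 10, 30], reps=10)  # size >= cohort
        with pytest.raises(ValueError):
            rrs_extrapolate(cfg, src, [5, 10, 15], reps=5)  # too few reps


class TestCompareROC:
    def test_result_compared_with_itself_p_one(self):
        rng = np.random.default_rng(16)
        s = rng.random(40)
        y = np.repeat([0, 1], 20)
        res = compare_roc(s, y, s, y, n_boot=200, seed=1)
        assert res.p_value == 1.0
        assert res.delta_auc == 0.0

    def test_perfect_vs_null_significant(self):
        rng = np.random.default_rng(17)
        y = np.repeat([0, 1], 25)
        s_perfect = y + rng.normal(0, 0.01, 50)
        s_null = rng.random(50)
        res = compare_roc(s_perfect, y, s_null, y, n_boot=500, seed=2)
        assert res.p_value < 0.01

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(18)
        y = np.repeat([0, 1], 15)
        sa, sb = rng.random(30), rng.random(30)
        r1 = compare_roc(sa, y, sb, y, n_boot=300, seed=9)
        r2 = compare_roc(sa, y, sb, y, n_boot=300, seed=9)
        assert r1.p_value == r2.p_value


class TestSubgroupCompare:
    def test_homogeneous_subgroup_not_significantly_different(self):
        from mmwi.classify import subgroup_compare

        rng = np.random.default_rng(23)
        n = 80
        y = rng.integers(0, 2, n)
        y[:4] = [0, 1, 0, 1]
        s = np.clip(0.5 * y + rng.normal(0.25, 0.2, n), 0, 1)
        sites = rng.choice(["head", "trunk"], n)
        sites[:4] = "head"
        res = subgroup_compare(s, y, sites, "head", n_boot=300, seed=3)
        # the subgroup is drawn from the same score distribution
        assert res.p_value > 0.05

    def test_missing_or_single_class_subgroup_rejected(self):
        from mmwi.classify import subgroup_compare

        s = np.array([0.2, 0.8, 0.4, 0.9])
        y = np.array([0, 1, 0, 1])
        sites = np.array(["trunk", "trunk", "head", "trunk"])
        with pytest.raises(ValueError):
            subgroup_compare(s, y, sites, "scalp")
        with pytest.raises(ValueError):
            subgroup_compare(s, y, sites, "head")


class TestReproducibilityVariance:
    def _repeats(self, rng, noise, n_rep=50, n_f=64):
        f = np.linspace(12, 110, n_f)
        base = 0.6 * np.exp(1j * f / 10)
        return [
            UWBSignal((0, 0), f, base + noise * (rng.standard_normal(n_f)
                      + 1j * rng.standard_normal(n_f)) / np.sqrt(2))
            for _ in range(n_rep)
        ]

    def test_identical_repeats_zero_variance(self):
        rng = np.random.default_rng(19)
        reps = self._repeats(rng, 0.0, n_rep=4)
        out = reproducibility_variance(reps)
        assert out.max_percent == 0.0
        assert np.allclose(out.rel_variance_percent, 0.0)

    def test_known_noise_level_recovered(self):
        # |S + n| for |S| >> sigma: var(|.|) ~ sigma^2 / 2
        rng = np.random.default_rng(20)
        sigma = 0.05
        reps = self._repeats(rng, sigma, n_rep=50)
        out = reproducibility_variance(reps)
        expected = 100.0 * sigma**2 / (2 * 0.6**2)
        mean_rel = out.rel_variance_percent.mean()
        assert mean_rel == pytest.approx(expected, rel=0.35)

    def test_scale_invariance(self):
        rng = np.random.default_rng(21)
        reps = self._repeats(rng, 0.03, n_rep=10)
        doubled = [UWBSignal(r.position, r.freq_ghz, 2.0 * r.values) for r in reps]
        a = reproducibility_variance(reps)
        b = reproducibility_variance(doubled)
        assert np.allclose(a.rel_variance_percent, b.rel_variance_percent)
        assert a.minima_ghz == b.minima_ghz

    def test_fewer_than_two_repeats_rejected(self):
        rng = np.random.default_rng(22)
        with pytest.raises(ValueError):
            reproducibility_variance(self._repeats(rng, 0.0, n_rep=1))
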