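"""Cross-validation metrics, empirical chance, fusion, subsampling,
band t-tests, cross-conditional evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from megstates.evaluate import (ClassifierSpec, band_ttests, build_classifier,
                                cross_condition, crossvalidate,
                                decision_scores, empirical_chance, fuse_scores,
                                subsample_balance)


def separable_data(n=60, d=4, seed=0, gap=6.0):
    rng = np.random.default_rng(seed)
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    X = rng.standard_normal((n, d))
    X[:, 0] += gap * y
    return X, y


class TestCrossvalidate:
    def test_separable_data_near_perfect(self):
        X, y = separable_data()
        res = crossvalidate(X, y, ClassifierSpec(), k=10, seed=0)
        assert res.accuracy > 95
        assert res.sensitivity > 90 and res.specificity > 90

    def test_deterministic(self):
        X, y = separable_data(gap=1.0)
        a = crossvalidate(X, y, ClassifierSpec(), k=10, seed=3)
        b = crossvalidate(X, y, ClassifierSpec(), k=10, seed=3)
        assert a.accuracy == b.accuracy
        np.testing.assert_array_equal(a.predictions, b.predictions)
        np.testing.assert_allclose(a.scores, b.scores)

    def test_null_data_within_binomial_band(self):
        """Random labels on noise: accuracies stay inside the 95% binomial
        band around 50% (Monte-Carlo over seeds)."""
        rng = np.random.default_rng(9)
        accs = []
        for rep in range(20):
            X = rng.standard_normal((80, 6))
            y = rng.permutation(np.r_[np.zeros(40, int), np.ones(40, int)])
            accs.append(crossvalidate(X, y, ClassifierSpec(), k=10,
                                      seed=rep).accuracy)
        lo, hi = stats.binom.ppf([0.025, 0.975], 80 * 20, 0.5) / (80 * 20) * 100
        # mean over runs concentrates ~sqrt(20) tighter than one run
        assert lo - 3 < np.mean(accs) < hi + 3

    def test_confusion_identity_per_fold(self):
        X, y = separable_data(n=80, gap=1.0, seed=2)
        res = crossvalidate(X, y, ClassifierSpec(), k=10, seed=0)
        n1, n0 = int(y.sum()), int((1 - y).sum())
        acc = (res.sensitivity * n1 + res.specificity * n0) / (n1 + n0)
        assert acc == pytest.approx(res.accuracy, abs=1e-9)

    def test_label_swap_swaps_sens_spec(self):
        X, y = separable_data(n=80, gap=2.0, seed=4)
        a = crossvalidate(X, y, ClassifierSpec(), k=10, seed=0)
        b = crossvalidate(X, 1 - y, ClassifierSpec(), k=10, seed=0)
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            crossvalidate(np.ones((3, 2)), np.array([0, 1, 1]), ClassifierSpec())

    def test_ann_matches_architecture(self):
        clf = build_classifier(ClassifierSpec(kind="ann", seed=1))
        assert clf.hidden_layer_sizes == (10,)
        assert clf.activation == "tanh"
        assert clf.tol == 1e-5
        X, y = separable_data()
        res = crossvalidate(X, y, ClassifierSpec(kind="ann"), k=10, seed=0)
        assert res.accuracy > 90

    def test_tuned_svm_runs(self):
        X, y = separable_data(gap=1.5)
        res = crossvalidate(X, y, ClassifierSpec(tune=True), k=5, seed=0)
        assert res.accuracy > 60


class TestEmpiricalChance:
    def test_exact_enumeration_n20(self):
        """Oracle: direct binomial tail enumeration at n = 20."""
        n, alpha = 20, 0.05
        pmf = np.array([stats.binom.pmf(k, n, 0.5) for k in range(n + 1)])
        k_star = next(k for k in range(n + 1) if pmf[k:].sum() < alpha)
        assert empirical_chance(20) == pytest.approx(100 * k_star / n)
        assert empirical_chance(20) == 75.0

    def test_strictly_above_half_and_decreasing(self):
        assert empirical_chance(100) > empirical_chance(1000) > 50.0
        assert empirical_chance(10 ** 6) == pytest.approx(50.0, abs=0.2)

    def test_bad_alpha_rejected(self):
        for alpha in (0.0, 1.0, -1.0):
            with pytest.raises(ValueError):
                empirical_chance(100, alpha)
        with pytest.raises(ValueError):
            empirical_chance(1)

    def test_calibration_under_null(self):
        """Over 50 null runs, the fraction of accuracies exceeding the
        empirical chance level is about alpha or less."""
        rng = np.random.default_rng(21)
        n = 60
        chance = empirical_chance(n)
        exceed = 0
        for rep in range(50):
            X = rng.standard_normal((n, 5))
            y = rng.permutation(np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)])
            res = crossvalidate(X, y, ClassifierSpec(), k=5, seed=rep)
            exceed += res.accuracy > chance
        # binomial(50, ~0.05): allow up to 7 exceedances (p ~ 0.996 quantile)
        assert exceed <= 7


class TestFusion:
    def test_endpoints_reproduce_single_hemisphere(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 100)
        S_l = rng.standard_normal(100) + (2 * y - 1)
        S_r = rng.standard_normal(100) + 0.5 * (2 * y - 1)
        prof = fuse_scores(S_l, S_r, y)
        acc_l = np.mean((S_l > 0).astype(int) == y) * 100
        acc_r = np.mean((S_r > 0).astype(int) == y) * 100
        assert prof.loc[prof.p == 1.0, "accuracy"].item() == acc_l
        assert prof.loc[prof.p == 0.0, "accuracy"].item() == acc_r
        assert len(prof) == 11

    def test_complementary_hemispheres_peak_interior(self):
        """Each hemisphere carries half the samples' information: the fused
        profile peaks strictly inside (0, 1)."""
        rng = np.random.default_rng(6)
        n = 400
        y = rng.integers(0, 2, n)
        half = rng.random(n) < 0.5
        sig = 2 * y - 1.0
        S_l = np.where(half, 3 * sig, 0.0) + 0.8 * rng.standard_normal(n)
        S_r = np.where(~half, 3 * sig, 0.0) + 0.8 * rng.standard_normal(n)
        prof = fuse_scores(S_l, S_r, y)
        best_p = prof.loc[prof.accuracy.idxmax(), "p"]
        assert 0.0 < best_p < 1.0
        inner = prof[(prof.p > 0) & (prof.p < 1)].accuracy.max()
        ends = prof[(prof.p == 0) | (prof.p == 1)].accuracy.max()
        assert inner > ends

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            fuse_scores(np.ones(5), np.ones(4), np.ones(5, int))


class TestSubsampleBalance:
    def test_balanced_input_single_repeat(self):
        X, y = separable_data(n=60, gap=2.0)
        avg, _ = subsample_balance(X, y, ClassifierSpec(), n_repeats=5, seed=0)
        direct = crossvalidate(X, y, ClassifierSpec(), k=10, seed=0)
        assert avg.accuracy == direct.accuracy   # single repeat when balanced

    def test_sevenfold_imbalance_null_near_chance(self):
        rng = np.random.default_rng(8)
        n1 = 30
        X = rng.standard_normal((n1 * 8, 5))
        y = np.r_[np.ones(n1, int), np.zeros(7 * n1, int)]
        avg, _ = subsample_balance(X, y, ClassifierSpec(), n_repeats=20, seed=0,
                                   k=5)
        assert 35 < avg.accuracy < 65

    def test_group_profile_reported(self):
        rng = np.random.default_rng(9)
        n1 = 24
        y = np.r_[np.ones(n1, int), np.zeros(3 * n1, int)]
        X = rng.standard_normal((len(y), 4))
        X[:n1, 0] += 3.0
        groups = np.r_[-np.ones(n1), np.repeat([0, 100, 200], n1)]
        avg, prof = subsample_balance(X, y, ClassifierSpec(), n_repeats=4,
                                      seed=0, k=4, groups=groups)
        assert set(prof.group) == {-1.0, 0.0, 100.0, 200.0}
        assert prof.detection.between(0, 100).all()

    def test_empty_minority_rejected(self):
        with pytest.raises(ValueError):
            subsample_balance(np.ones((4, 2)), np.zeros(4, int))


class TestBandTtests:
    def test_identical_pairs_give_zero_t(self):
        Z = np.random.default_rng(0).random((30, 6))
        df = band_ttests(Z, Z.copy(), list("abcdef"))
        assert np.allclose(df.t.abs(), 0) or df.t.isna().all()
        assert not df.significant.fillna(False).any()

    def test_df_equals_pairs_minus_one(self):
        rng = np.random.default_rng(1)
        df = band_ttests(rng.random((628, 6)), rng.random((628, 6)),
                         list("abcdef"))
        assert (df.df == 627).all()
        assert df.attrs["threshold"] == pytest.approx(0.05 / 6)

    def test_planted_alpha_effect_detected(self):
        """Alpha (and only alpha) band power differs between the paired
        states: only alpha crosses the Bonferroni threshold."""
        rng = np.random.default_rng(2)
        n = 628
        bands = ["delta", "theta", "alpha", "beta", "lower_gamma", "upper_gamma"]
        M = rng.normal(1.0, 0.2, (n, 6))
        T = M + rng.normal(0.0, 0.2, (n, 6))
        T[:, 2] += 0.06
        df = band_ttests(T, M, bands).set_index("band")
        assert df.loc["alpha", "significant"]
        assert not df.loc["delta", "significant"]

    def test_unpaired_shapes_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            band_ttests(np.ones((10, 6)), np.ones((9, 6)), list("abcdef"))


class TestCrossCondition:
    def _by_stim(self, orthogonal=False, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        for i, stim in enumerate(("NC", "SAM", "SFM")):
            n = 80
            y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
            X = rng.standard_normal((n, 6))
            col = i if orthogonal else 0
            X[:, col] += 3 * y
            out[stim] = (X, y)
        return out

    def test_shared_effect_generalizes(self):
        df = cross_condition(self._by_stim(orthogonal=False))
        off = df[df.note != "Training"]
        assert (off.accuracy > 85).all()
        diag = df[df.note == "Training"]
        assert len(diag) == 3 and diag.accuracy.isna().all()

    def test_orthogonal_effects_stay_near_chance(self):
        df = cross_condition(self._by_stim(orthogonal=True))
        off = df[df.note != "Training"]
        assert (off.accuracy < 70).all()

    def test_single_test_sample_defined(self):
        by = self._by_stim()
        X, y = by["SAM"]
        by["SAM"] = (X[:1], y[:1])
        df = cross_condition(by).set_index(["train", "test"])
        acc = df.loc[("NC", "SAM"), "accuracy"]
        assert acc in (0.0, 100.0)

    def test_matrix_shape(self):
        df = cross_condition(self._by_stim())
        assert len(df) == 9
        assert set(df.train) == set(df.test) == {"NC", "SAM", "SFM"}
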