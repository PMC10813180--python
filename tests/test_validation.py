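"""LOOCV, external validation, ROC/AUC and outlier screening."""

import numpy as np
import pytest

from sersdx.chemometrics import osc_fit, plsda_fit, plsda_predict
from sersdx.preprocess import mean_center
from sersdx.spectra import SpectraSet
from sersdx.validation import (
    ValidationReport,
    confusion_counts,
    detect_outliers,
    external_validate,
    loocv,
    remove_outliers,
    roc_auc,
)
from conftest import random_spectra_set


def pair_count_auc(scores, positive):
    """Brute-force Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos = neg)."""
    pos = scores[positive]
    neg = scores[~positive]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        positive = np.array([False, False, True, True])
        _, _, auc, flipped = roc_auc(scores, positive)
        assert auc == 1.0 and not flipped

    def test_all_ties(self):
        scores = np.zeros(6)
        positive = np.array([True, True, True, False, False, False])
        fpr, tpr, auc, _ = roc_auc(scores, positive)
        assert auc == 0.5

    def test_known_three_quarters(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        positive = np.array([False, False, True, True])
        _, _, auc, _ = roc_auc(scores, positive)
        assert np.isclose(auc, 0.75)
        assert np.isclose(pair_count_auc(scores, positive), 0.75)

    def test_auto_flip(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        positive = np.array([True, True, False, False])
        _, _, auc, flipped = roc_auc(-scores, positive)
        assert flipped and auc == 1.0

    def test_matches_pair_counting_oracle(self, rng):
        """Trapezoidal ROC area equals Mann-Whitney pair counting (ties
        one half) on 1,000 random instances to 1e-12."""
        for _ in range(1000):
            n = int(rng.integers(4, 14))
            n_pos = int(rng.integers(1, n))
            positive = np.zeros(n, bool)
            positive[rng.choice(n, n_pos, replace=False)] = True
            # coarse values force frequent ties
            scores = rng.integers(0, 5, size=n).astype(float)
            fpr, tpr, auc, flipped = roc_auc(scores, positive)
            expected = pair_count_auc(scores, positive)
            if flipped:
                expected = pair_count_auc(-scores, positive)
            assert abs(auc - expected) < 1e-12

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(50):
            scores = rng.normal(size=20)
            positive = rng.random(20) > 0.4
            if positive.all() or not positive.any():
                continue
            _, _, auc, flipped = roc_auc(scores, positive)
            ref = roc_auc_score(positive, -scores if flipped else scores)
            assert np.isclose(auc, ref, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.arange(4.0), np.ones(4, bool))


class TestConfusionArithmetic:
    def test_perfect_validation_split_counts(self):
        """15 FM + 13 non-FM all correct -> 100/100/100 (the study's
        external-validation headline)."""
        y = np.r_[np.ones(15), 2 * np.ones(13)]
        rep = _report_from(y, y.astype(float))
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (15, 0, 0, 13)
        assert rep.accuracy == 100.0
        assert rep.sensitivity == 100.0
        assert rep.specificity == 100.0

    def test_one_false_negative(self):
        y = np.r_[np.ones(15), 2 * np.ones(13)]
        yhat = y.copy()
        yhat[0] = 1.9  # one FM called non-FM
        rep = _report_from(y, yhat)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (14, 1, 0, 13)
        assert np.isclose(rep.sensitivity, 93.33, atol=0.01)
        assert rep.specificity == 100.0
        assert np.isclose(rep.accuracy, 96.43, atol=0.01)

    def test_sens_spec_swap_symmetry(self, rng):
        """Swapping labels and predictions together exchanges sensitivity
        and specificity."""
        y = rng.choice([1.0, 2.0], size=30)
        y[:2] = [1.0, 2.0]  # both classes present
        yhat = rng.uniform(0.8, 2.2, size=30)
        rep = _report_from(y, yhat)
        swapped = _report_from(3.0 - y, 3.0 - yhat)
        assert np.isclose(rep.sensitivity, swapped.specificity)
        assert np.isclose(rep.specificity, swapped.sensitivity)


def _report_from(y, yhat):
    from sersdx.validation import _build_report

    return _build_report("external", np.asarray(y, float), np.asarray(yhat, float))


def loocv_oracle(X, y, n_osc, n_lv):
    """From-scratch fold loop: center, OSC, PLS refit per left-out sample."""
    n = len(y)
    yhat = np.empty(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        Xtr = X[keep]
        ytr = y[keep]
        means = Xtr.mean(axis=0)
        osc, Xf = osc_fit(Xtr - means, ytr, n_osc)
        pls = plsda_fit(Xf, ytr, n_lv, x_means=means)
        yhat[i] = plsda_predict(pls, osc, X[i][None, :])[0][0]
    return yhat


def closed_form_1lv_loocv(X, y):
    """Independent closed-form single-LV PLS1 fold loop (no package fit
    code): w = Xc'yc normalized, t = Xc w, b = w q / (p'w)."""
    n = len(y)
    yhat = np.empty(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        Xtr, ytr = X[keep], np.asarray(y, float)[keep]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        Xc, yc = Xtr - xm, ytr - ym
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        q = yc @ t / (t @ t)
        b = w * q / (p @ w)
        yhat[i] = (X[i] - xm) @ b + ym
    return yhat


class TestLoocv:
    def test_secv_matches_closed_form_oracle(self, rng):
        """LOOCV SECV equals an independently coded per-fold closed-form
        recomputation on small toys to 1e-10."""
        for n, p in [(6, 4), (8, 5), (10, 7)]:
            sset = random_spectra_set(rng, n=n, p=p, label_split=n // 2)
            rep = loocv(sset, n_osc=0, n_lv=1)
            yhat = closed_form_1lv_loocv(sset.X, sset.class_codes())
            secv = np.sqrt(np.mean((sset.class_codes() - yhat) ** 2))
            assert abs(rep.sec_like - secv) < 1e-10

    def test_full_chain_matches_fold_oracle(self, rng):
        sset = random_spectra_set(rng, n=10, p=30, label_split=5)
        rep = loocv(sset, n_osc=1, n_lv=2)
        yhat = loocv_oracle(sset.X, sset.class_codes(), 1, 2)
        np.testing.assert_allclose(rep.y_pred, yhat, atol=1e-10)

    def test_mean_model_residuals(self, rng):
        """With 0 LVs every fold predicts its training Y mean; residuals
        follow the balanced-coding closed form |y_i - mean_fold|."""
        sset = random_spectra_set(rng, n=8, p=10, label_split=4)
        rep = loocv(sset, n_osc=0, n_lv=0)
        y = sset.class_codes()
        for i in range(8):
            fold_mean = np.delete(y, i).mean()
            assert np.isclose(abs(y[i] - rep.y_pred[i]), abs(y[i] - fold_mean))

    def test_fold_losing_class_rejected(self, rng):
        sset = random_spectra_set(rng, n=5, p=6, label_split=1)
        with pytest.raises(ValueError, match="loses a class"):
            loocv(sset, n_osc=0, n_lv=1)

    def test_separable_cohort_perfect(self, small_processed):
        rep = loocv(small_processed, n_osc=1, n_lv=5)
        assert rep.accuracy == 100.0
        assert rep.sensitivity == 100.0
        assert rep.specificity == 100.0


class TestExternalValidate:
    def test_training_set_sep_equals_training_rmse(self, rng):
        sset = random_spectra_set(rng, n=12, p=20, label_split=6)
        y = sset.class_codes()
        Xc, means = mean_center(sset.X)
        osc, Xf = osc_fit(Xc, y, 1)
        pls = plsda_fit(Xf, y, 2, x_means=means)
        rep = external_validate(pls, osc, sset)
        yhat, _ = plsda_predict(pls, osc, sset.X)
        assert np.isclose(rep.sec_like, np.sqrt(np.mean((y - yhat) ** 2)), atol=1e-12)

    def test_overlapping_ids_rejected(self, rng):
        sset = random_spectra_set(rng, n=12, p=20, label_split=6)
        y = sset.class_codes()
        Xc, means = mean_center(sset.X)
        osc, Xf = osc_fit(Xc, y, 0)
        pls = plsda_fit(Xf, y, 2, x_means=means)
        with pytest.raises(ValueError, match="overlap"):
            external_validate(pls, osc, sset, train_ids=sset.ids[:3])


class TestOutliers:
    def _fit(self, X, y, n_lv=3):
        Xc, means = mean_center(X)
        osc, Xf = osc_fit(Xc, y, 1)
        return plsda_fit(Xf, y, n_lv, x_means=means), osc

    def test_duplicated_rows_equal_leverage(self, rng):
        X = rng.normal(size=(12, 15))
        X[5] = X[4]
        y = np.r_[np.ones(6), 2 * np.ones(6)]
        pls, osc = self._fit(X, y)
        flags = detect_outliers(pls, X, y, osc=osc)
        assert np.isclose(flags.leverage[4], flags.leverage[5], atol=1e-10)

    def test_leverage_range_and_mean(self, rng):
        X = rng.normal(size=(20, 15))
        y = np.r_[np.ones(10), 2 * np.ones(10)]
        pls, osc = self._fit(X, y)
        flags = detect_outliers(pls, X, y, osc=osc)
        assert np.all(flags.leverage > 0)
        assert np.all(flags.leverage <= 1 + 1e-9)
        # leverages over the score space sum to n_lv + n/n
        assert np.isclose(flags.leverage.sum(), pls.n_lv + 1, atol=1e-8)

    @pytest.mark.parametrize("seed", [3, 7, 11])
    def test_planted_spike_sample_flagged(self, seed):
        """A sample with a 20-sigma spike gets the maximum studentized
        residual and is flagged.

        The diagnostic is exercised on a rank-1 PLS fit: with spare latent
        dimensions the model interpolates a single-sample artifact
        (leverage -> 1, internally studentized residual -> 0), so the
        leverage+residual screen is informative only when the model cannot
        absorb the artifact direction.
        """
        from sersdx.synthetic import SyntheticConfig, generate_cohort
        from sersdx.preprocess import preprocess_set

        cfg = SyntheticConfig(seed=seed, n_fm=14, n_nonfm=10, n_nc=0)
        cohort = generate_cohort(cfg)
        proc = preprocess_set(cohort)
        X = proc.X.copy()
        # 20-sigma corruption of one sample's processed trace
        sigma = X.std(axis=0)
        X[2] = X[2] + 20.0 * sigma * np.sign(np.sin(np.arange(X.shape[1])))
        y = proc.class_codes()
        Xc, means = mean_center(X)
        pls = plsda_fit(Xc, y, 1, x_means=means)
        flags = detect_outliers(pls, X, y, osc=None)
        assert np.argmax(np.abs(flags.studentized)) == 2
        assert flags.flagged[2]

    def test_clean_cohort_flag_rate(self):
        """Clean synthetic cohorts flag at most 3% of samples on average
        across seeds."""
        from sersdx.synthetic import SyntheticConfig, generate_cohort
        from sersdx.preprocess import preprocess_set

        rates = []
        for seed in range(8):
            cfg = SyntheticConfig(seed=seed, n_fm=14, n_nonfm=10, n_nc=0)
            proc = preprocess_set(generate_cohort(cfg))
            y = proc.class_codes()
            pls, osc = self._fit(proc.X, y, n_lv=5)
            flags = detect_outliers(pls, proc.X, y, osc=osc)
            rates.append(flags.n_flagged / len(y))
        assert np.mean(rates) <= 0.03

    def test_removal_capped(self, rng):
        sset = random_spectra_set(rng, n=40, p=10, label_split=20)
        y = sset.class_codes()
        pls, osc = self._fit(sset.X, y)
        flags = detect_outliers(pls, sset.X, y, osc=osc)
        flags.flagged[:] = True  # pretend everything is influential
        curated, removed = remove_outliers(sset, flags, cap_fraction=0.03)
        assert len(removed) == 1  # floor(0.03 * 40)
        assert len(curated) == 39

    def test_report_summary_renders(self, rng):
        sset = random_spectra_set(rng, n=12, p=20, label_split=6)
        rep = loocv(sset, n_osc=0, n_lv=1)
        text = rep.summary()
        assert "SECV" in text and "positive class: FM" in text
        d = rep.to_dict()
        assert d["confusion"]["tp"] + d["confusion"]["fn"] == 6
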