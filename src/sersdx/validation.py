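"""Model assessment: leave-one-out cross-validation, external validation,
ROC/AUC, and leverage/studentized-residual outlier screening.

Conventions
-----------
* FM is the positive class throughout (sensitivity = FM detection rate).
* SECV and SEP are root-mean-square residuals of the coded class variable
  (FM = 1, non-FM = 2) with denominator n.
* R^2 is reported as the squared Pearson correlation between predicted and
  coded class values (the `r2` field); the 1 - SS_res/SS_tot variant is
  computed alongside (`r2_ss`).
* LOOCV refits the entire leak-prone chain per fold: column means, the OSC
  filter and the PLS model are all recomputed on the n-1 retained samples,
  so no statistic of the held-out sample enters its own prediction.
  (Per-spectrum transforms - baseline, normalization, derivative - involve
  no cross-sample statistics and are applied once, upstream.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import CODE_FM, DECISION_THRESHOLD, FM, SpectraSet, encode_labels
from .chemometrics import OSCModel, PLSDAModel, osc_fit, plsda_fit, plsda_predict
from .preprocess import mean_center

__all__ = [
    "ValidationReport",
    "OutlierFlags",
    "confusion_counts",
    "loocv",
    "external_validate",
    "roc_auc",
    "detect_outliers",
    "remove_outliers",
]


@dataclass
class ValidationReport:
    """Figures of merit for one scored set (calibration LOOCV or external).

    Percentages are on the 0-100 scale; `sec_like` is the SECV (LOOCV) or
    SEP (external) in coded-Y units.
    """

    kind: str  # 'loocv' or 'external'
    n: int
    r2: float  # squared Pearson corr(y_hat, y)
    r2_ss: float  # 1 - SS_res / SS_tot
    sec_like: float  # SECV or SEP
    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float  # percent
    sensitivity: float  # percent, FM positive
    specificity: float  # percent
    auc: float
    roc_fpr: np.ndarray = field(repr=False, default=None)  # type: ignore
    roc_tpr: np.ndarray = field(repr=False, default=None)  # type: ignore
    roc_flipped: bool = False
    y_true: np.ndarray = field(repr=False, default=None)  # type: ignore
    y_pred: np.ndarray = field(repr=False, default=None)  # type: ignore

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "positive_class": FM,
            "n": self.n,
            "r2": self.r2,
            "r2_ss": self.r2_ss,
            "secv" if self.kind == "loocv" else "sep": self.sec_like,
            "confusion": {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn},
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "auc": self.auc,
            "roc_flipped": self.roc_flipped,
        }

    def summary(self) -> str:
        """Text table of the figures of merit (positive class: FM)."""
        name = "SECV" if self.kind == "loocv" else "SEP"
        lines = [
            f"Validation report ({self.kind}, n = {self.n}; positive class: FM)",
            "-" * 58,
            f"{name:<14s}{self.sec_like:10.4f}",
            f"{'R2 (corr)':<14s}{self.r2:10.4f}",
            f"{'R2 (1-SS)':<14s}{self.r2_ss:10.4f}",
            f"{'Accuracy%':<14s}{self.accuracy:10.2f}",
            f"{'Specificity%':<14s}{self.specificity:10.2f}",
            f"{'Sensitivity%':<14s}{self.sensitivity:10.2f}",
            f"{'AUC':<14s}{self.auc:10.4f}",
            f"{'Confusion':<14s}TP={self.tp} FN={self.fn} FP={self.fp} TN={self.tn}",
        ]
        return "\n".join(lines)


def _r2_pair(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_ss = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    if np.std(yhat) == 0 or np.std(y) == 0:
        r2 = np.nan
    else:
        r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    return r2, r2_ss


def confusion_counts(y_true: np.ndarray, y_class: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FN, FP, TN) with the FM code (1) as positive."""
    y_true = np.asarray(y_true, dtype=float)
    y_class = np.asarray(y_class, dtype=float)
    pos = y_true == CODE_FM
    pred_pos = y_class == CODE_FM
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    return tp, fn, fp, tn


def _build_report(kind: str, y: np.ndarray, yhat: np.ndarray) -> ValidationReport:
    r2, r2_ss = _r2_pair(y, yhat)
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    y_class = np.where(yhat < DECISION_THRESHOLD, 1.0, 2.0)
    tp, fn, fp, tn = confusion_counts(y, y_class)
    n = y.size
    acc = 100.0 * (tp + tn) / n
    sens = 100.0 * tp / (tp + fn) if tp + fn else np.nan
    spec = 100.0 * tn / (tn + fp) if tn + fp else np.nan
    # Higher score should mean "more FM-like"; FM is coded low (1), so the
    # natural FM score is the negated prediction.
    fpr, tpr, auc, flipped = roc_auc(-yhat, y == CODE_FM)
    return ValidationReport(
        kind=kind,
        n=n,
        r2=r2,
        r2_ss=r2_ss,
        sec_like=rmse,
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        roc_fpr=fpr,
        roc_tpr=tpr,
        roc_flipped=flipped,
        y_true=y,
        y_pred=yhat,
    )


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------


def loocv(sset: SpectraSet, n_osc: int = 1, n_lv: int = 7) -> ValidationReport:
    """Leave-one-out CV of the center->OSC->PLS chain on a processed set.

    ``sset`` must be replicate-averaged, preprocessed, FM/NONFM-labelled
    data.  Every fold refits centering means, the OSC filter and the PLS
    model from scratch on the retained samples.
    """
    y = encode_labels(sset.labels)
    n = y.size
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    yhat = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        y_tr = y[keep]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"fold {i} loses a class entirely")
        Xc, means = mean_center(sset.X[keep])
        osc, Xf = osc_fit(Xc, y_tr, n_osc)
        pls = plsda_fit(Xf, y_tr, n_lv, x_means=means)
        yh, _ = plsda_predict(pls, osc, sset.X[i][None, :])
        yhat[i] = yh[0]
    return _build_report("loocv", y, yhat)


def external_validate(
    model: PLSDAModel,
    osc: OSCModel | None,
    test: SpectraSet,
    train_ids=None,
) -> ValidationReport:
    """Score an unseen set with a fitted model; SEP = RMSE of coded Y."""
    if train_ids is not None:
        overlap = set(map(str, train_ids)) & set(map(str, test.ids))
        if overlap:
            raise ValueError(f"test set overlaps training ids: {sorted(overlap)[:5]}")
    y = encode_labels(test.labels)
    yhat, _ = plsda_predict(model, osc, test.X)
    return _build_report("external", y, yhat)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_auc(scores, positive) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Empirical ROC curve and AUC (ties counted one half).

    Parameters
    ----------
    scores : array
        Continuous scores; by convention higher = more positive-like.
    positive : boolean array
        True for positive-class (FM) samples.

    Returns ``(fpr, tpr, auc, flipped)``; if the computed AUC is below 0.5
    the score orientation is flipped, and the flip reported.

    The AUC equals the Mann-Whitney statistic P(score_pos > score_neg) +
    0.5 P(score_pos = score_neg), which the trapezoidal area under the
    tie-grouped empirical ROC reproduces exactly.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    def _curve(sc):
        order = np.argsort(-sc, kind="stable")
        sc_sorted = sc[order]
        pos_sorted = positive[order].astype(float)
        tp = np.cumsum(pos_sorted)
        fp = np.cumsum(1.0 - pos_sorted)
        # group ties: keep the last index of each run of equal scores
        last = np.r_[np.nonzero(np.diff(sc_sorted))[0], sc_sorted.size - 1]
        tpr = np.r_[0.0, tp[last] / n_pos]
        fpr = np.r_[0.0, fp[last] / n_neg]
        auc = float(np.trapezoid(tpr, fpr))
        return fpr, tpr, auc

    fpr, tpr, auc = _curve(scores)
    flipped = False
    if auc < 0.5:
        fpr, tpr, auc = _curve(-scores)
        flipped = True
    return fpr, tpr, auc, flipped


# ---------------------------------------------------------------------------
# Outlier screening
# ---------------------------------------------------------------------------


@dataclass
class OutlierFlags:
    """Per-sample influence diagnostics on the calibration fit.

    A sample is flagged when BOTH its leverage in the latent-variable score
    space exceeds ``3 (n_lv + 1) / n`` AND its studentized residual exceeds
    3 in magnitude.
    """

    leverage: np.ndarray
    studentized: np.ndarray
    flagged: np.ndarray
    leverage_threshold: float
    residual_threshold: float

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    def to_dict(self) -> dict:
        return {
            "leverage": self.leverage.tolist(),
            "studentized": self.studentized.tolist(),
            "flagged": self.flagged.tolist(),
            "leverage_threshold": self.leverage_threshold,
            "residual_threshold": self.residual_threshold,
        }


def detect_outliers(
    model: PLSDAModel,
    X: np.ndarray,
    Y: np.ndarray,
    osc: OSCModel | None = None,
    residual_threshold: float = 3.0,
) -> OutlierFlags:
    """Leverage and studentized residuals of the calibration samples.

    Leverage: h_i = 1/n + t_i' (T'T)^-1 t_i over the training LV scores.
    Studentized residual: e_i / (RMSE sqrt(1 - h_i)) with e the coded-Y
    training residual.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    T = model.scores
    n = T.shape[0]
    TtT = T.T @ T
    if np.linalg.matrix_rank(TtT) < TtT.shape[0]:
        raise ValueError("score covariance T'T is singular")
    h = 1.0 / n + np.einsum("ij,jk,ik->i", T, np.linalg.inv(TtT), T)
    yhat, _ = plsda_predict(model, osc, X)
    e = Y - yhat
    rmse = float(np.sqrt(np.mean(e**2)))
    denom = np.sqrt(np.clip(1.0 - h, 1e-12, None)) * max(rmse, 1e-300)
    r = e / denom
    lev_thr = 3.0 * (model.n_lv + 1) / n
    flagged = (h > lev_thr) & (np.abs(r) > residual_threshold)
    return OutlierFlags(
        leverage=h,
        studentized=r,
        flagged=flagged,
        leverage_threshold=lev_thr,
        residual_threshold=residual_threshold,
    )


def remove_outliers(
    sset: SpectraSet, flags: OutlierFlags, cap_fraction: float = 0.03
) -> tuple[SpectraSet, list[str]]:
    """Drop flagged samples, worst (largest |studentized|) first, capped.

    At most ``floor(cap_fraction * n)`` samples are removed; returns the
    curated set and the removed sample ids.  This is a one-off curation
    pass before the final calibration fit - never applied inside CV folds.
    """
    n = len(sset)
    cap = int(np.floor(cap_fraction * n))
    idx = np.nonzero(flags.flagged)[0]
    if idx.size == 0 or cap == 0:
        return sset, []
    order = idx[np.argsort(-np.abs(flags.studentized[idx]))][:cap]
    removed = [str(sset.ids[i]) for i in order]
    keep = np.setdiff1d(np.arange(n), order)
    return sset.subset(keep), removed
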