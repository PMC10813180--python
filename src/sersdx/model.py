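"""Statsmodels-style front end: the :class:`OSCPLSDA` model and its
:class:`OSCPLSDAResults`.

`OSCPLSDA` bundles the leak-prone part of the pipeline (mean-centering,
orthogonal signal correction, NIPALS PLS-DA) behind a fit/results API:

>>> from sersdx import synthetic, preprocess, model
>>> cohort = synthetic.generate_cohort(synthetic.SyntheticConfig(seed=7))
>>> processed = preprocess.preprocess_set(cohort.select_labels("FM", "NONFM"))
>>> res = model.OSCPLSDA.from_spectra(processed, n_osc=1, n_lv=7).fit()
>>> print(res.summary())

The results object exposes the regression vector, LV scores, explained
variance, training figures of merit, LOOCV and external validation,
outlier diagnostics and JSON serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import __version__ as _pkg_version
from .spectra import SpectraSet, encode_labels
from .preprocess import mean_center
from .chemometrics import (
    OSCModel,
    PLSDAModel,
    osc_fit,
    plsda_fit,
    plsda_predict,
    regression_vector_report,
)
from .validation import (
    OutlierFlags,
    ValidationReport,
    confusion_counts,
    detect_outliers,
    external_validate,
    loocv as _loocv,
)

__all__ = ["OSCPLSDA", "OSCPLSDAResults"]


class OSCPLSDA:
    """Two-class OSC-filtered PLS-DA model of preprocessed spectra.

    Parameters
    ----------
    X : array (n_samples, n_points)
        Preprocessed (baseline-corrected, normalized, derivatized) spectra.
        Raw, uncentered values: centering happens at fit time and the means
        are stored for prediction.
    y : array of class codes or labels
        FM/NONFM labels or their (1, 2) codes.
    grid : array, optional
        Wavenumber axis, enables band reporting.
    ids : sequence, optional
        Sample identifiers (used to guard external validation).
    n_osc : int
        Orthogonal signal correction components to remove (default 1).
    n_lv : int
        PLS latent variables (default 7).
    """

    def __init__(self, X, y, grid=None, ids=None, n_osc: int = 1, n_lv: int = 7):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if y.dtype.kind in "OU":
            y = encode_labels(y)
        self.y = np.asarray(y, dtype=float).ravel()
        if self.y.size != self.X.shape[0]:
            raise ValueError("X rows and y length differ")
        if len(np.unique(self.y)) < 2:
            raise ValueError("need both classes to fit a discriminant model")
        self.grid = None if grid is None else np.asarray(grid, dtype=float)
        self.ids = (
            np.array([f"s{i}" for i in range(self.X.shape[0])], dtype=object)
            if ids is None
            else np.asarray(ids, dtype=object)
        )
        self.n_osc = int(n_osc)
        self.n_lv = int(n_lv)

    @classmethod
    def from_spectra(cls, sset: SpectraSet, n_osc: int = 1, n_lv: int = 7) -> "OSCPLSDA":
        """Build from a preprocessed, replicate-averaged SpectraSet."""
        return cls(
            X=sset.X,
            y=sset.class_codes(),
            grid=sset.grid,
            ids=sset.ids,
            n_osc=n_osc,
            n_lv=n_lv,
        )

    @classmethod
    def from_dataframe(
        cls, df, label_col: str = "label", id_col: str | None = None,
        n_osc: int = 1, n_lv: int = 7,
    ) -> "OSCPLSDA":
        """Build from a DataFrame whose non-label columns are wavenumbers."""
        drop = [label_col] + ([id_col] if id_col else [])
        Xdf = df.drop(columns=drop)
        grid = np.asarray([float(c) for c in Xdf.columns])
        return cls(
            X=Xdf.to_numpy(dtype=float),
            y=df[label_col].to_numpy(),
            grid=grid,
            ids=None if id_col is None else df[id_col].to_numpy(),
            n_osc=n_osc,
            n_lv=n_lv,
        )

    def fit(self) -> "OSCPLSDAResults":
        Xc, means = mean_center(self.X)
        osc, Xf = osc_fit(Xc, self.y, self.n_osc)
        pls = plsda_fit(Xf, self.y, self.n_lv, x_means=means, grid=self.grid)
        return OSCPLSDAResults(self, osc, pls)


@dataclass
class OSCPLSDAResults:
    """Fit results: estimates, diagnostics, validation and reporting."""

    model: OSCPLSDA
    osc: OSCModel
    pls: PLSDAModel

    # -- estimates ---------------------------------------------------------

    @property
    def regression_vector(self) -> np.ndarray:
        return self.pls.regression_vector

    @property
    def scores(self) -> np.ndarray:
        """Training LV scores T (n x n_lv)."""
        return self.pls.scores

    @property
    def explained_x_variance(self) -> np.ndarray:
        return self.pls.explained_x_variance

    @property
    def explained_y_variance(self) -> np.ndarray:
        return self.pls.explained_y_variance

    @property
    def fittedvalues(self) -> np.ndarray:
        """Continuous training predictions (coded-Y scale)."""
        yhat, _ = plsda_predict(self.pls, self.osc, self.model.X)
        return yhat

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    # -- prediction and validation ----------------------------------------

    def predict(self, X_new) -> tuple[np.ndarray, np.ndarray]:
        """(continuous y_hat, hard class codes) for new preprocessed rows."""
        if isinstance(X_new, SpectraSet):
            X_new = X_new.X
        return plsda_predict(self.pls, self.osc, X_new)

    def loocv(self) -> ValidationReport:
        """Leave-one-out CV, refitting centering/OSC/PLS per fold."""
        m = self.model
        sset = SpectraSet(
            grid=m.grid if m.grid is not None else np.arange(m.X.shape[1], dtype=float),
            X=m.X,
            labels=np.where(m.y == 1.0, "FM", "NONFM").astype(object),
            ids=m.ids,
        )
        return _loocv(sset, n_osc=m.n_osc, n_lv=m.n_lv)

    def validate(self, test: SpectraSet) -> ValidationReport:
        """External validation on an unseen SpectraSet (ids must not overlap)."""
        return external_validate(self.pls, self.osc, test, train_ids=self.model.ids)

    def outliers(self, residual_threshold: float = 3.0) -> OutlierFlags:
        return detect_outliers(
            self.pls, self.model.X, self.model.y, osc=self.osc,
            residual_threshold=residual_threshold,
        )

    def band_report(self, top_k: int = 10, tolerance: float = 8.0):
        """Ranked |regression vector| extrema annotated with known bands."""
        return regression_vector_report(self.pls, top_k=top_k, tolerance=tolerance)

    # -- summary and serialization ----------------------------------------

    def summary(self) -> str:
        m = self.model
        y = m.y
        yhat = self.fittedvalues
        rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
        r = np.corrcoef(y, yhat)[0, 1] if np.std(yhat) > 0 else np.nan
        y_class = np.where(yhat < 1.5, 1.0, 2.0)
        tp, fn, fp, tn = confusion_counts(y, y_class)
        acc = 100.0 * (tp + tn) / y.size
        cum_x = 100 * np.cumsum(self.explained_x_variance)
        cum_y = 100 * np.cumsum(self.explained_y_variance)
        n_fm = int(np.sum(y == 1.0))
        n_nonfm = int(np.sum(y == 2.0))
        lines = [
            "OSC-PLS-DA Results",
            "=" * 64,
            f"Samples:             {y.size}  (FM = {n_fm}, non-FM = {n_nonfm})",
            f"Variables:           {m.X.shape[1]} wavenumber points",
            f"OSC components:      {m.n_osc}",
            f"Latent variables:    {m.n_lv}",
            f"Class coding:        FM = 1, non-FM = 2 (threshold 1.5)",
            "-" * 64,
            "LV   cum. X-variance %   cum. Y-variance %",
        ]
        for a in range(m.n_lv):
            lines.append(f"{a + 1:<5d}{cum_x[a]:>15.1f}{cum_y[a]:>19.1f}")
        lines += [
            "-" * 64,
            f"Training SEC:        {rmse:.4f}",
            f"Training R2 (corr):  {r**2:.4f}",
            f"Training accuracy:   {acc:.2f}%  (TP={tp} FN={fn} FP={fp} TN={tn})",
            "=" * 64,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "package_version": _pkg_version,
            "n_osc": self.model.n_osc,
            "n_lv": self.model.n_lv,
            "ids": [str(i) for i in self.model.ids],
            "osc": self.osc.to_dict(),
            "pls": self.pls.to_dict(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "OSCPLSDAResults":
        """Rehydrate a fitted model for prediction (training X not stored)."""
        with open(path) as fh:
            d = json.load(fh)
        pls = PLSDAModel.from_dict(d["pls"])
        osc = OSCModel.from_dict(d["osc"])
        n = len(d["ids"])
        dummy_X = np.tile(pls.x_means, (n, 1))
        m = OSCPLSDA.__new__(OSCPLSDA)
        m.X = dummy_X
        m.y = np.r_[np.ones(max(n - 1, 1)), 2.0][:n] if n else np.array([1.0, 2.0])
        m.grid = pls.grid
        m.ids = np.asarray(d["ids"], dtype=object)
        m.n_osc = int(d["n_osc"])
        m.n_lv = int(d["n_lv"])
        return cls(m, osc, pls)
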