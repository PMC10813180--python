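"""Orthogonal signal correction (OSC) and NIPALS PLS-DA.

The discriminant workflow marketed as "OPLS-DA" in chemometrics suites is
implemented here as the sequential two-step procedure it is usually run as:

1. **OSC filter** - remove from the (mean-centered) spectral matrix X the
   high-variance direction(s) orthogonal to the coded class variable Y.
   Each component is a triple (w, p, t): a weight vector w defining the
   score t = X w, constrained to be uncorrelated with Y, and a loading p
   used to deflate X <- X - t p'.  This strips inter-individual variation
   that carries no class information (baseline residues, overall intensity
   drifts) before the classifier sees the data.
2. **PLS1 discriminant analysis** - NIPALS partial least squares regression
   of the filtered X against Y coded FM = 1 / non-FM = 2, collapsed to a
   single regression vector b; a continuous prediction y_hat = X b + b0 is
   thresholded at the class-code midpoint (1.5).

This is deliberately *not* the integrated Trygg-Wold O-PLS decomposition;
the sequential OSC-then-PLS form matches the procedure the pipeline
replicates and keeps the two filters separately inspectable.

The OSC variant is the PLS-flavoured one (Sjoblom/Fearn style): the leading
principal direction of X is orthogonalized against Y and re-expressed as an
exact linear function of X (w via least squares), iterating to a fixed
point, so that the same w and p deflate unseen data without touching test
labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import CODE_FM, CODE_NONFM, DECISION_THRESHOLD

__all__ = [
    "OSCComponent",
    "OSCModel",
    "PLSDAModel",
    "osc_fit",
    "osc_apply",
    "plsda_fit",
    "plsda_predict",
    "regression_vector_report",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAXITER = 500


@dataclass
class OSCComponent:
    """One removed component: score t = X w, loading p, deflation t p'."""

    w: np.ndarray
    p: np.ndarray
    t: np.ndarray  # training scores


@dataclass
class OSCModel:
    """Fitted orthogonal-signal-correction filter."""

    components: list[OSCComponent] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "components": [
                {"w": c.w.tolist(), "p": c.p.tolist(), "t": c.t.tolist()}
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OSCModel":
        return cls(
            components=[
                OSCComponent(
                    np.asarray(c["w"]), np.asarray(c["p"]), np.asarray(c["t"])
                )
                for c in d["components"]
            ]
        )


def _project_out(t: np.ndarray, ya: np.ndarray) -> np.ndarray:
    """Component of t orthogonal to the centered class vector ya."""
    return t - ya * (ya @ t) / (ya @ ya)


def osc_fit(
    X: np.ndarray, Y: np.ndarray, n_components: int = 1, tol: float = 1e-10
) -> tuple[OSCModel, np.ndarray]:
    """Fit the OSC filter on centered X and return (model, X_corrected).

    For each component the leading singular direction of the Y-orthogonal
    part of X is iterated to a fixed point t = X w with t orthogonal to
    (centered) Y, then X is deflated by t p' with p = X't/(t't).
    ``n_components = 0`` returns X unchanged.
    """
    X = np.array(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    if X.shape[0] != Y.size:
        raise ValueError("X rows and Y length differ")
    if n_components < 0:
        raise ValueError("n_components must be >= 0")
    model = OSCModel()
    if n_components == 0:
        return model, X

    rank = np.linalg.matrix_rank(X)
    if n_components > rank:
        raise ValueError(f"requested {n_components} OSC components but rank(X)={rank}")

    ya = Y - Y.mean()
    if np.allclose(ya, 0):
        raise ValueError("class vector is constant; OSC needs two classes")

    for _ in range(n_components):
        # start: leading left singular direction of the Y-orthogonal part
        Z = X - np.outer(ya, (ya @ X) / (ya @ ya))
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        t = U[:, 0] * S[0]
        for _it in range(_NIPALS_MAXITER):
            t_orth = _project_out(t, ya)
            w, *_ = np.linalg.lstsq(X, t_orth, rcond=None)
            t_new = X @ w
            if np.linalg.norm(t_new - t) <= tol * max(1.0, np.linalg.norm(t)):
                t = t_new
                break
            t = t_new
        t = X @ w  # exact linear function of X so test data deflate identically
        denom = t @ t
        if denom <= 0:
            raise ValueError("degenerate OSC score (zero variance)")
        p = X.T @ t / denom
        model.components.append(OSCComponent(w=w, p=p, t=t))
        X = X - np.outer(t, p)
    return model, X


def osc_apply(model: OSCModel, X_new: np.ndarray) -> np.ndarray:
    """Deflate new (training-centered) data with the stored w and p only."""
    X = np.array(X_new, dtype=float)
    for c in model.components:
        if X.shape[1] != c.w.size:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {c.w.size}"
            )
        t = X @ c.w
        X = X - np.outer(t, c.p)
    return X


# ---------------------------------------------------------------------------
# NIPALS PLS1 discriminant analysis
# ---------------------------------------------------------------------------


@dataclass
class PLSDAModel:
    """Fitted PLS-DA model (NIPALS PLS1 on the coded class variable).

    ``regression_vector`` collapses all latent variables into one
    coefficient per wavenumber: y_hat = (x - x_means) @ b + y_mean.
    """

    n_lv: int
    x_weights: np.ndarray  # W, p x n_lv
    x_loadings: np.ndarray  # P, p x n_lv
    y_loadings: np.ndarray  # q, n_lv
    regression_vector: np.ndarray  # b, p
    x_means: np.ndarray
    y_mean: float
    scores: np.ndarray  # T, n x n_lv (training)
    explained_x_variance: np.ndarray  # fraction of centered-X SS per LV
    explained_y_variance: np.ndarray  # fraction of centered-Y SS per LV
    grid: np.ndarray | None = None  # wavenumber axis for reporting
    class_codes: tuple[float, float] = (CODE_FM, CODE_NONFM)

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_means @ self.regression_vector)

    def to_dict(self) -> dict:
        d = {
            "n_lv": self.n_lv,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "regression_vector": self.regression_vector.tolist(),
            "x_means": self.x_means.tolist(),
            "y_mean": self.y_mean,
            "scores": self.scores.tolist(),
            "explained_x_variance": self.explained_x_variance.tolist(),
            "explained_y_variance": self.explained_y_variance.tolist(),
            "class_codes": list(self.class_codes),
            "grid": None if self.grid is None else self.grid.tolist(),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PLSDAModel":
        return cls(
            n_lv=int(d["n_lv"]),
            x_weights=np.asarray(d["x_weights"]),
            x_loadings=np.asarray(d["x_loadings"]),
            y_loadings=np.asarray(d["y_loadings"]),
            regression_vector=np.asarray(d["regression_vector"]),
            x_means=np.asarray(d["x_means"]),
            y_mean=float(d["y_mean"]),
            scores=np.asarray(d["scores"]),
            explained_x_variance=np.asarray(d["explained_x_variance"]),
            explained_y_variance=np.asarray(d["explained_y_variance"]),
            class_codes=tuple(d["class_codes"]),
            grid=None if d.get("grid") is None else np.asarray(d["grid"]),
        )


def plsda_fit(
    X: np.ndarray,
    Y: np.ndarray,
    n_lv: int = 7,
    x_means: np.ndarray | None = None,
    y_mean: float | None = None,
    grid: np.ndarray | None = None,
) -> PLSDAModel:
    """NIPALS PLS1 fit of centered X against the coded class vector.

    Parameters
    ----------
    X : array (n, p)
        Centered (post-OSC) spectral matrix.
    Y : array (n,)
        Class codes (1 = FM, 2 = non-FM); centered internally.
    n_lv : int
        Number of latent variables; must not exceed rank(X).
        ``n_lv = 0`` yields the null model predicting the training Y mean.
    x_means, y_mean
        Centering constants of the *raw* data, stored for prediction. If
        omitted, X is assumed already centered and Y's mean is used.
    """
    X = np.array(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    n, p = X.shape
    if Y.size != n:
        raise ValueError("X rows and Y length differ")
    if len(np.unique(Y)) < 2:
        raise ValueError("degenerate single-class Y")
    if n_lv < 0:
        raise ValueError("n_lv must be >= 0")
    if n_lv > 0 and n_lv > np.linalg.matrix_rank(X):
        raise ValueError(f"n_lv={n_lv} exceeds rank(X)={np.linalg.matrix_rank(X)}")

    ym = float(Y.mean()) if y_mean is None else float(y_mean)
    xm = np.zeros(p) if x_means is None else np.asarray(x_means, dtype=float)
    y = Y - Y.mean()

    ss_x_total = float(np.sum(X**2))
    ss_y_total = float(np.sum(y**2))

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    evx = np.zeros(n_lv)
    evy = np.zeros(n_lv)

    Xd, yd = X.copy(), y.copy()
    for a in range(n_lv):
        # NIPALS inner loop; for a single y column it converges in one pass
        # but is run to tolerance for form's sake.
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 0:
            raise ValueError(f"PLS component {a + 1} is degenerate (zero weight)")
        w /= nw
        for _ in range(_NIPALS_MAXITER):
            t = Xd @ w
            qa = (yd @ t) / (t @ t)
            w_new = Xd.T @ (yd * qa)
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) <= _NIPALS_TOL:
                w = w_new
                break
            w = w_new
        t = Xd @ w
        tt = t @ t
        if tt <= 1e-300:
            raise ValueError(f"PLS component {a + 1} has zero score variance")
        pa = Xd.T @ t / tt
        qa = (yd @ t) / tt
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
        evx[a] = tt * (pa @ pa) / ss_x_total if ss_x_total > 0 else 0.0
        evy[a] = tt * qa**2 / ss_y_total if ss_y_total > 0 else 0.0
        Xd = Xd - np.outer(t, pa)
        yd = yd - t * qa

    if n_lv > 0:
        b = W @ np.linalg.solve(P.T @ W, q)
    else:
        b = np.zeros(p)

    return PLSDAModel(
        n_lv=n_lv,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        regression_vector=b,
        x_means=xm,
        y_mean=ym,
        scores=T,
        explained_x_variance=evx,
        explained_y_variance=evy,
        grid=None if grid is None else np.asarray(grid, dtype=float),
    )


def plsda_predict(
    model: PLSDAModel,
    osc: OSCModel | None,
    X_new: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict (continuous y_hat, hard class codes) for preprocessed spectra.

    Centers with *training* means, applies the trained OSC deflation, then
    y_hat = Xc b + y_mean.  Class 1 (FM) when y_hat < 1.5, else class 2;
    exact ties go to class 2.
    """
    X = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X.shape[1] != model.x_means.size:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.x_means.size} "
            "(grid mismatch?)"
        )
    Xc = X - model.x_means
    if osc is not None:
        Xc = osc_apply(osc, Xc)
    y_cont = Xc @ model.regression_vector + model.y_mean
    c1, c2 = model.class_codes
    y_class = np.where(y_cont < DECISION_THRESHOLD, c1, c2)
    return y_cont, y_class


# ---------------------------------------------------------------------------
# Regression-vector report
# ---------------------------------------------------------------------------


def regression_vector_report(
    model: PLSDAModel,
    top_k: int = 10,
    band_table: list | None = None,
    tolerance: float = 8.0,
):
    """Rank local extrema of |b| and annotate with nearest known bands.

    Returns a pandas DataFrame with columns (wavenumber, coefficient, rank,
    band, mode, assignment); `band` is the nearest entry of the
    band-assignment table within ``tolerance`` cm^-1, or empty.
    """
    import pandas as pd

    if model.grid is None:
        raise ValueError("model carries no wavenumber grid to report on")
    b = model.regression_vector
    absb = np.abs(b)
    # strict local maxima of |b| (flat coefficient vectors yield none)
    interior = np.arange(1, b.size - 1)
    is_max = (absb[interior] > absb[interior - 1]) & (
        absb[interior] >= absb[interior + 1]
    ) & (absb[interior] > 0)
    peaks = interior[is_max]
    order = peaks[np.argsort(absb[peaks])[::-1]][:top_k]

    if band_table is None:
        from .synthetic import default_band_table

        band_table = default_band_table()

    rows = []
    for rank, i in enumerate(order, start=1):
        wn = float(model.grid[i])
        nearest = min(band_table, key=lambda bs: abs(bs.position - wn))
        if abs(nearest.position - wn) <= tolerance:
            band, mode, assign = nearest.position, nearest.mode, nearest.assignment
        else:
            band, mode, assign = np.nan, "", ""
        rows.append(
            {
                "wavenumber": wn,
                "coefficient": float(b[i]),
                "rank": rank,
                "band": band,
                "mode": mode,
                "assignment": assign,
            }
        )
    return pd.DataFrame(rows, columns=["wavenumber", "coefficient", "rank", "band", "mode", "assignment"])
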