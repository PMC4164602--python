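"""NIPALS PLS1 calibration of elemental composition on spectra, with
leave-one-out cross-validation and chemometric reporting.

For each analyte y and spectral matrix X (samples x wavenumber points),
the model is fit by the classic NIPALS sequence on mean-centred data:

    w = X'y / ||X'y||      (weights)
    t = X w                (scores)
    p = X't / t't          (x-loadings)
    q = y't / t't          (y-loading)
    X <- X - t p',  y <- y - q t   (deflation)

repeated per component.  Cross-validation leaves each sample out in turn
and reports, at the RMSECV-minimising component count:

* R^2 (%): squared Pearson correlation between CV predictions and
  reference values, times 100;
* RMSECV: root mean squared CV error, in the analyte's units;
* bias: mean(predicted - reference);
* RPD: SD(reference) / SECV, where SECV is the standard deviation of the
  bias-corrected CV residuals.  RPD > 3 marks a useful calibration.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["PLSModel", "PLSCVResult", "fit_pls", "predict", "cross_validate"]


@dataclasses.dataclass
class PLSModel:
    """A fitted NIPALS PLS1 model (centred-space factors plus means)."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray     # variables x components
    x_loadings: np.ndarray  # variables x components
    y_loadings: np.ndarray  # components

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression vector b with y ~ (x - x_mean) . b + y_mean."""
        k = self.n_components if n_components is None else n_components
        if not (1 <= k <= self.n_components):
            raise ValueError(f"n_components must be in [1, {self.n_components}]")
        W = self.weights[:, :k]
        P = self.x_loadings[:, :k]
        q = self.y_loadings[:k]
        # b = W (P'W)^-1 q ; P'W is upper triangular and well conditioned
        return W @ np.linalg.solve(P.T @ W, q)


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a PLS1 model by NIPALS on mean-centred X and y.

    Stops early (with fewer components) if X or y is fully deflated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("y length must match the number of rows of X")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}], "
            f"got {n_components}")
    if np.std(y) == 0:
        raise ValueError("y has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    k_used = 0
    for k in range(n_components):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-14:  # X or y exhausted
            break
        w /= norm
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-28:
            break
        pk = Xc.T @ t / tt
        qk = float(yc @ t) / tt
        Xc = Xc - np.outer(t, pk)
        yc = yc - qk * t
        W[:, k] = w
        P[:, k] = pk
        q[k] = qk
        k_used += 1
    if k_used == 0:
        raise ValueError("no PLS component could be extracted")
    return PLSModel(n_components=k_used, x_mean=x_mean, y_mean=y_mean,
                    weights=W[:, :k_used], x_loadings=P[:, :k_used],
                    y_loadings=q[:k_used])


def predict(model: PLSModel, X: np.ndarray,
            n_components: int | None = None) -> np.ndarray:
    """Predict responses for new rows; optionally with fewer components."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"{X.shape[1]} variables but model was fit with "
            f"{model.x_mean.size}")
    b = model.coefficients(n_components)
    return (X - model.x_mean) @ b + model.y_mean


@dataclasses.dataclass
class PLSCVResult:
    """Cross-validation report for one analyte."""

    analyte: str
    r2_percent: float
    rmsecv: float
    bias: float
    rpd: float
    n_components_selected: int
    cv_predictions: np.ndarray | None = None


def cross_validate(X: np.ndarray, y: np.ndarray, max_components: int = 10,
                   analyte: str = "") -> PLSCVResult:
    """Leave-one-out cross-validation with RMSECV-based component choice.

    Every candidate component count up to ``max_components`` (capped by
    the fold sample count) is evaluated from the same per-fold NIPALS
    fits; the count minimising RMSECV is selected and all metrics are
    reported at that count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("cross-validation needs at least 3 samples")
    if np.std(y) == 0:
        raise ValueError("y has zero variance")
    kmax = min(max_components, n - 2, p)

    preds = np.full((n, kmax), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_pls(X[mask], y[mask], kmax)
        for k in range(1, model.n_components + 1):
            preds[i, k - 1] = predict(model, X[i], n_components=k)[0]
        # folds that deflated early: reuse the deepest available component
        for k in range(model.n_components + 1, kmax + 1):
            preds[i, k - 1] = preds[i, model.n_components - 1]

    rmse_k = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    best_k = int(np.argmin(rmse_k)) + 1
    yhat = preds[:, best_k - 1]

    residuals = yhat - y
    bias = float(residuals.mean())
    rmsecv = float(rmse_k[best_k - 1])
    secv = float(np.std(residuals - bias, ddof=1))
    sd = float(np.std(y, ddof=1))
    r = float(np.corrcoef(yhat, y)[0, 1]) if np.std(yhat) > 0 else 0.0
    return PLSCVResult(
        analyte=analyte,
        r2_percent=100.0 * r * r,
        rmsecv=rmsecv,
        bias=bias,
        rpd=sd / secv if secv > 0 else float("inf"),
        n_components_selected=best_k,
        cv_predictions=yhat,
    )
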