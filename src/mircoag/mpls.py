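"""Modified partial least-squares (mPLS) regression with 15-fold cross-validation.

The estimator implements single-response PLS1 by NIPALS with the
Shenk--Westerhaus modification: after each latent factor is extracted, the
X-residuals at every wavelength are divided by the standard deviation of the
residuals at that wavelength before the next factor is computed.  Scaling the
residuals re-weights wavelengths so that later factors are not dominated by a
few high-variance regions; with ``standardize_residuals=False`` the estimator
reduces exactly to conventional PLS1.

Composite regression coefficients are accumulated for every factor count, so
out-of-fold predictions for all candidate model sizes come from a single fit
per fold.  The cross-validation statistics follow NIRS conventions:

``SEC``
    sqrt(RSS / (N - LF - 1)) on calibration residuals.
``SECV``
    sqrt(pooled out-of-fold RSS / N).
``R2_CrV``
    squared Pearson correlation between pooled out-of-fold predictions and the
    reference values (an ``1 - RSS/TSS`` variant is available via
    ``r2_method="variance"``).

The number of latent factors is the smallest factor count whose SECV lies
within a relative band (default 2%) of the global SECV minimum, capped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "MPLSRegression",
    "CvResult",
    "fit_mpls",
    "cross_validate",
    "select_latent_factors",
    "sec_from_residuals",
    "save_model",
    "load_model",
]


class MPLSRegression(RegressorMixin, BaseEstimator):
    """Shenk--Westerhaus modified PLS1 regression.

    Parameters
    ----------
    n_components : int
        Maximum number of latent factors to extract (may be truncated on
        rank-deficient data, with a warning).
    standardize_residuals : bool
        Apply the per-wavelength X-residual standardization after each factor
        (the "modified" in mPLS).  ``False`` gives conventional NIPALS PLS1.
    scale_floor : float
        Relative floor applied to residual standard deviations to keep the
        scaling vectors strictly positive.

    Attributes
    ----------
    x_mean_, y_mean_ : centring terms of the calibration set.
    x_weights_, x_loadings_ : (n_features, k) per-factor weight/loading vectors
        (expressed in the running rescaled residual space).
    y_loadings_ : (k,) per-factor regression of y on the factor scores.
    residual_scales_ : (n_features, k) strictly positive per-factor scaling
        vectors (all ones when standardization is off).
    rotations_ : (n_features, k) projection such that scores = Xc @ rotations_.
    coef_path_ : (n_features, k) composite coefficients for every factor count.
    coef_ : coefficients at the full ``n_components_``.
    scores_ : (n_samples, k) calibration factor scores.
    n_components_ : number of factors actually extracted.
    """

    def __init__(self, n_components: int = 16, standardize_residuals: bool = True,
                 scale_floor: float = 1e-12):
        self.n_components = n_components
        self.standardize_residuals = standardize_residuals
        self.scale_floor = scale_floor

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError(f"X has {n} rows but y has {y.shape[0]} values")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite (no missing values)")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if np.ptp(y) == 0:
            raise ValueError("y is constant; nothing to regress")
        if n < self.n_components + 2:
            raise ValueError(
                f"need at least n_components + 2 = {self.n_components + 2} samples, got {n}"
            )

        self.n_features_in_ = p
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xr = X - self.x_mean_
        yr = y - self.y_mean_

        max_k = min(self.n_components, n - 1, p)
        x_scale = float(np.abs(Xr).max()) or 1.0
        y_scale = float(np.abs(yr).max()) or 1.0
        tol = 1e-13

        W = np.zeros((p, max_k))
        P = np.zeros((p, max_k))
        Q = np.zeros(max_k)
        S = np.ones((p, max_k))
        R = np.zeros((p, max_k))      # rotations: scores = Xc @ R
        B = np.zeros((p, max_k))      # composite coefficients per factor count
        T = np.zeros((n, max_k))

        M = np.eye(p)                 # running map: residual_k = Xc @ M
        b = np.zeros(p)
        k = 0
        for k_iter in range(max_k):
            w = Xr.T @ yr
            wnorm = float(np.linalg.norm(w))
            if wnorm <= tol * x_scale * y_scale * np.sqrt(p):
                break
            w /= wnorm
            t = Xr @ w
            tt = float(t @ t)
            if tt <= (tol * x_scale) ** 2 * n:
                break
            pvec = Xr.T @ t / tt
            q = float(yr @ t / tt)

            rot = M @ w
            b = b + q * rot
            Xr = Xr - np.outer(t, pvec)
            yr = yr - q * t
            M = M - np.outer(rot, pvec)
            if self.standardize_residuals:
                s = Xr.std(axis=0, ddof=1)
                floor = self.scale_floor * (float(s.max()) if s.max() > 0 else 1.0)
                if floor == 0:
                    floor = self.scale_floor
                s = np.maximum(s, floor)
                Xr = Xr / s
                M = M / s  # divides each column j of M by s[j]
            else:
                s = np.ones(p)

            W[:, k_iter] = w
            P[:, k_iter] = pvec
            Q[k_iter] = q
            S[:, k_iter] = s
            R[:, k_iter] = rot
            B[:, k_iter] = b
            T[:, k_iter] = t
            k = k_iter + 1

        if k == 0:
            raise ValueError("no latent factor could be extracted (X'y ~ 0)")
        if k < self.n_components:
            warnings.warn(
                f"rank-deficient data: extracted {k} of {self.n_components} "
                "requested latent factors",
                stacklevel=2,
            )
        self.x_weights_ = W[:, :k]
        self.x_loadings_ = P[:, :k]
        self.y_loadings_ = Q[:k]
        self.residual_scales_ = S[:, :k]
        self.rotations_ = R[:, :k]
        self.coef_path_ = B[:, :k]
        self.scores_ = T[:, :k]
        self.n_components_ = k
        self.coef_ = self.coef_path_[:, k - 1]
        return self

    # -- prediction ---------------------------------------------------------

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns; the model was trained on a "
                f"{self.n_features_in_}-point axis"
            )
        return X

    def predict(self, X, n_components: int | None = None):
        """Predict the trait: ``y_mean + (X - x_mean) @ coef`` at a factor count."""
        if not hasattr(self, "coef_path_"):
            raise ValueError("model is not fitted")
        k = self.n_components_ if n_components is None else int(n_components)
        if not 1 <= k <= self.n_components_:
            raise ValueError(f"n_components must be in [1, {self.n_components_}]")
        X = self._check_X(X)
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_path_[:, k - 1]

    def predict_path(self, X):
        """(n_samples, n_components_) predictions for every factor count."""
        if not hasattr(self, "coef_path_"):
            raise ValueError("model is not fitted")
        X = self._check_X(X)
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_path_

    def transform(self, X):
        """Project onto the factor scores (the space used for Global-H)."""
        if not hasattr(self, "rotations_"):
            raise ValueError("model is not fitted")
        X = self._check_X(X)
        return (X - self.x_mean_) @ self.rotations_

    def training_sec(self, y, n_components: int | None = None) -> float:
        """Standard error of calibration sqrt(RSS / (N - LF - 1)) on training data."""
        k = self.n_components_ if n_components is None else int(n_components)
        y = np.asarray(y, dtype=float).ravel()
        fitted = self.y_mean_ + self.scores_[:, :k] @ self.y_loadings_[:k]
        return sec_from_residuals(y - fitted, k)


def sec_from_residuals(residuals: np.ndarray, n_factors: int) -> float:
    residuals = np.asarray(residuals, dtype=float).ravel()
    dof = residuals.size - n_factors - 1
    if dof < 1:
        raise ValueError(f"not enough residuals ({residuals.size}) for {n_factors} factors")
    return float(np.sqrt(np.sum(residuals**2) / dof))


def fit_mpls(X, y, n_factors: int, standardize_residuals: bool = True) -> MPLSRegression:
    """Functional wrapper: fit an :class:`MPLSRegression` with ``n_factors``."""
    return MPLSRegression(
        n_components=n_factors, standardize_residuals=standardize_residuals
    ).fit(X, y)


# ---------------------------------------------------------------------------
# cross-validation and factor selection
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Cross-validation summary for one trait/preprocessing combination."""

    secv: np.ndarray                  # SECV for factor counts 1..len(secv)
    n_factors: int                    # chosen LF
    folds: list[np.ndarray]           # index arrays partitioning the samples
    sec: float                        # SEC at the chosen LF (training residuals)
    r2_crv: float                     # squared correlation of pooled OOF predictions
    oof_predictions: np.ndarray       # pooled out-of-fold predictions at chosen LF
    model: MPLSRegression             # full-data fit (n_components_ >= chosen LF)

    @property
    def secv_at_selected(self) -> float:
        return float(self.secv[self.n_factors - 1])


def select_latent_factors(secv: np.ndarray, cap: int = 16, rel_band: float = 0.02) -> int:
    """Smallest factor count whose SECV is within ``rel_band`` of the minimum.

    Candidates are limited to ``1..cap``.
    """
    secv = np.asarray(secv, dtype=float).ravel()
    if secv.size == 0:
        raise ValueError("empty SECV curve")
    limit = min(int(cap), secv.size)
    candidates = secv[:limit]
    best = float(candidates.min())
    within = np.flatnonzero(candidates <= (1.0 + rel_band) * best)
    return int(within[0]) + 1


def make_folds(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded random partition into folds whose sizes differ by at most one."""
    if n_folds > n:
        raise ValueError(f"{n_folds} folds for {n} samples")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, n_folds)]


def cross_validate(
    X,
    y,
    n_folds: int = 15,
    max_factors: int = 16,
    seed: int | np.random.Generator = 0,
    standardize_residuals: bool = True,
    lf_cap: int | None = None,
    lf_band: float = 0.02,
    r2_method: str = "correlation",
) -> CvResult:
    """Seeded k-fold cross-validation of mPLS over all candidate factor counts.

    Each fold model is a full mPLS refit; SECV at each factor count pools the
    out-of-fold squared errors over all folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = make_folds(n, n_folds, rng)

    largest_fold = -(-n // n_folds)
    max_factors = min(max_factors, n - largest_fold - 2, X.shape[1])
    if max_factors < 1:
        raise ValueError("too few samples per fold for even one latent factor")

    oof = np.full((n, max_factors), np.nan)
    k_eff = max_factors
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank truncation inside folds is handled here
        for test_idx in folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            model = MPLSRegression(
                n_components=max_factors, standardize_residuals=standardize_residuals
            ).fit(X[train_mask], y[train_mask])
            path = model.predict_path(X[test_idx])
            k_fold = model.n_components_
            k_eff = min(k_eff, k_fold)
            oof[test_idx, :k_fold] = path
            if k_fold < max_factors:  # carry the last available factor forward
                oof[test_idx, k_fold:] = path[:, [k_fold - 1]]

    secv = np.sqrt(np.mean((oof - y[:, None]) ** 2, axis=0))[:k_eff]
    lf = select_latent_factors(secv, cap=lf_cap if lf_cap is not None else max_factors,
                               rel_band=lf_band)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = MPLSRegression(
            n_components=max_factors, standardize_residuals=standardize_residuals
        ).fit(X, y)
    lf = min(lf, full.n_components_)
    sec = full.training_sec(y, n_components=lf)
    pred = oof[:, lf - 1]
    if r2_method == "correlation":
        r2 = float(np.corrcoef(pred, y)[0, 1] ** 2) if np.ptp(pred) > 0 else 0.0
    elif r2_method == "variance":
        r2 = float(1.0 - np.sum((pred - y) ** 2) / np.sum((y - y.mean()) ** 2))
    else:
        raise ValueError(f"unknown r2_method {r2_method!r}")
    return CvResult(
        secv=secv,
        n_factors=lf,
        folds=folds,
        sec=sec,
        r2_crv=r2,
        oof_predictions=pred,
        model=full,
    )


# ---------------------------------------------------------------------------
# model serialization (lossless JSON round-trip)
# ---------------------------------------------------------------------------

def save_model(model: MPLSRegression, path: str | Path, metadata: dict | None = None) -> None:
    """Serialize a fitted model (centring, coefficients, factors) to JSON."""
    if not hasattr(model, "coef_path_"):
        raise ValueError("model is not fitted")
    payload = {
        "format": "mircoag-mpls-model",
        "version": 1,
        "params": {
            "n_components": model.n_components,
            "standardize_residuals": model.standardize_residuals,
            "scale_floor": model.scale_floor,
        },
        "n_components_": model.n_components_,
        "n_features_in_": model.n_features_in_,
        "x_mean_": model.x_mean_.tolist(),
        "y_mean_": model.y_mean_,
        "x_weights_": model.x_weights_.tolist(),
        "x_loadings_": model.x_loadings_.tolist(),
        "y_loadings_": model.y_loadings_.tolist(),
        "residual_scales_": model.residual_scales_.tolist(),
        "rotations_": model.rotations_.tolist(),
        "coef_path_": model.coef_path_.tolist(),
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[MPLSRegression, dict]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "mircoag-mpls-model":
        raise ValueError(f"{path}: not a serialized mPLS model")
    model = MPLSRegression(**payload["params"])
    model.n_components_ = int(payload["n_components_"])
    model.n_features_in_ = int(payload["n_features_in_"])
    model.x_mean_ = np.array(payload["x_mean_"], dtype=float)
    model.y_mean_ = float(payload["y_mean_"])
    model.x_weights_ = np.array(payload["x_weights_"], dtype=float)
    model.x_loadings_ = np.array(payload["x_loadings_"], dtype=float)
    model.y_loadings_ = np.array(payload["y_loadings_"], dtype=float)
    model.residual_scales_ = np.array(payload["residual_scales_"], dtype=float)
    model.rotations_ = np.array(payload["rotations_"], dtype=float)
    model.coef_path_ = np.array(payload["coef_path_"], dtype=float)
    model.coef_ = model.coef_path_[:, model.n_components_ - 1]
    return model, payload.get("metadata", {})
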