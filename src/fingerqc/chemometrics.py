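"""Latent-variable regression of activity on fingerprint areas, plus a PCA
outlier screen.

The regression is an iteratively-deflated (NIPALS-style) partial
least-squares fit of a single response on centered/scaled peak areas; the
orthogonal-filtered variant first removes response-orthogonal variation
from X and then fits one predictive component.  Validation follows the
usual conventions: R2/RMSEE on the training set, Q2/RMSECV by seeded
k-fold cross-validation, RMSEP on an external test set, and per-coefficient
95% intervals by leave-one-out jack-knifing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import ComputationError, DegenerateInputError, DimensionError, ValidationError

DEFAULT_CV_FOLDS = 7


# ---------------------------------------------------------------------------
# scaling

@dataclass
class Scaler:
    """Column centering plus unit-variance ('uv'), 'pareto', or no scaling."""

    mode: str = "uv"
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
        if self.mode == "uv":
            scale = sd
        elif self.mode == "pareto":
            scale = np.sqrt(sd)
        elif self.mode == "center":
            scale = np.ones_like(sd)
        else:
            raise ValidationError(f"unknown scaling mode {self.mode!r}")
        zero = scale == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} constant column(s) given zero weight")
            scale = np.where(zero, 1.0, scale)
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


# ---------------------------------------------------------------------------
# models

@dataclass
class LatentModel:
    """A fitted latent-variable regression in raw-area coordinates.

    ``coefficients``/``intercept`` express predictions as
    ``intercept + areas @ coefficients`` regardless of the internal scaling.
    """

    kind: str  # "pls" or "opls"
    n_predictive: int
    n_orthogonal: int
    scaler: Scaler
    y_mean: float
    y_scale: float
    weights: np.ndarray  # W (n x A), scaled space
    loadings: np.ndarray  # P (n x A)
    y_loadings: np.ndarray  # q (A,)
    ortho_weights: np.ndarray | None  # OPLS orthogonal filter (n x n_orth)
    ortho_loadings: np.ndarray | None
    coefficients: np.ndarray  # raw-area scale
    intercept: float
    r2: float = np.nan
    q2: float = np.nan
    rmsee: float = np.nan
    rmsecv: float = np.nan
    rmsep: float = np.nan
    jackknife_ci: np.ndarray | None = None  # (n, 2)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_predictive": self.n_predictive,
            "n_orthogonal": self.n_orthogonal,
            "intercept": float(self.intercept),
            "coefficients": self.coefficients.tolist(),
            "r2": float(self.r2),
            "q2": float(self.q2),
            "rmsee": float(self.rmsee),
            "rmsecv": float(self.rmsecv),
            "rmsep": float(self.rmsep),
            "jackknife_ci": None if self.jackknife_ci is None else self.jackknife_ci.tolist(),
        }


@dataclass
class PCAResult:
    scores: np.ndarray  # B x k
    loadings: np.ndarray  # n x k
    explained_variance_pct: np.ndarray  # (k,)
    outlier_flags: np.ndarray  # (B,) bool
    t2: np.ndarray  # (B,) Hotelling score distance
    t2_limit: float


def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise DimensionError("X must be 2-D")
    if X.shape[0] != y.shape[0]:
        raise DimensionError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant response")
    return X, y


def _nipals_pls(Xs: np.ndarray, ys: np.ndarray, n_components: int):
    """Single-response NIPALS: returns (W, P, q) in the scaled space."""
    E, f = Xs.copy(), ys.copy()
    n = Xs.shape[1]
    W = np.zeros((n, n_components))
    P = np.zeros((n, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            # residual X carries no covariance with y; stop early
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        w /= norm
        t = E @ w
        tt = t @ t
        if tt < 1e-12:
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        p = E.T @ t / tt
        qa = f @ t / tt
        E = E - np.outer(t, p)
        f = f - qa * t
        W[:, a], P[:, a], q[a] = w, p, qa
    return W, P, q


def _pls_coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def _fit_core(X: np.ndarray, y: np.ndarray, n_components: int, n_orthogonal: int,
              scale: str, kind: str) -> LatentModel:
    scaler = Scaler(scale).fit(X)
    Xs = scaler.transform(X)
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1)) if y.size > 1 else 1.0
    y_scale = y_sd if y_sd > 0 else 1.0
    ys = (y - y_mean) / y_scale

    Wo = Po = None
    Xf = Xs
    if n_orthogonal > 0:
        Wo = np.zeros((Xs.shape[1], n_orthogonal))
        Po = np.zeros((Xs.shape[1], n_orthogonal))
        E = Xs.copy()
        w = E.T @ ys
        w /= np.linalg.norm(w)
        for a in range(n_orthogonal):
            t = E @ w
            p = E.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            norm = np.linalg.norm(w_o)
            if norm < 1e-12:
                Wo, Po = Wo[:, :a], Po[:, :a]
                break
            w_o /= norm
            t_o = E @ w_o
            p_o = E.T @ t_o / (t_o @ t_o)
            E = E - np.outer(t_o, p_o)
            Wo[:, a], Po[:, a] = w_o, p_o
        Xf = E

    W, P, q = _nipals_pls(Xf, ys, n_components)
    b_scaled = _pls_coefficients(W, P, q)
    if Wo is not None and Wo.shape[1] > 0:
        # fold the orthogonal filter into the linear form: Xf = Xs (I - Wo Po^T ...)
        F = np.eye(Xs.shape[1])
        for a in range(Wo.shape[1]):
            F = F @ (np.eye(Xs.shape[1]) - np.outer(Wo[:, a], Po[:, a]))
        b_scaled = F @ b_scaled
    coef = y_scale * b_scaled / scaler.scale_
    intercept = y_mean - float(scaler.mean_ @ coef)

    model = LatentModel(kind=kind, n_predictive=W.shape[1],
                        n_orthogonal=0 if Wo is None else Wo.shape[1],
                        scaler=scaler, y_mean=y_mean, y_scale=y_scale,
                        weights=W, loadings=P, y_loadings=q,
                        ortho_weights=Wo, ortho_loadings=Po,
                        coefficients=coef, intercept=intercept)
    resid = y - model.predict(X)
    ss_tot = float(((y - y_mean) ** 2).sum())
    rss = float((resid**2).sum())
    model.r2 = 1.0 - rss / ss_tot
    model.rmsee = float(np.sqrt(rss / max(1, y.size - model.n_predictive - 1)))
    return model


def _kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [order[k::folds] for k in range(folds)]


def _cross_validate(X, y, folds, seed, refit: Callable[[np.ndarray, np.ndarray], LatentModel]):
    folds = min(folds, y.size)
    press = 0.0
    for test_idx in _kfold_indices(y.size, folds, seed):
        train = np.setdiff1d(np.arange(y.size), test_idx)
        sub = refit(X[train], y[train])
        press += float(((y[test_idx] - sub.predict(X[test_idx])) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / ss_tot
    rmsecv = float(np.sqrt(press / y.size))
    return q2, rmsecv


def fit_pls(X, y, n_components: int = 2, cv_folds: int = DEFAULT_CV_FOLDS,
            seed: int = 0, scale: str = "uv", cross_validate: bool = True) -> LatentModel:
    """NIPALS partial least squares of a single response on peak areas."""
    X, y = _validate_xy(X, y)
    if not (1 <= n_components < X.shape[0]):
        raise DimensionError(f"need 1 <= n_components < n_samples, got {n_components}")
    model = _fit_core(X, y, n_components, 0, scale, "pls")
    if cross_validate and cv_folds >= 2:
        model.q2, model.rmsecv = _cross_validate(
            X, y, cv_folds, seed,
            lambda Xi, yi: _fit_core(Xi, yi, min(n_components, Xi.shape[0] - 1), 0, scale, "pls"),
        )
    return model


def fit_opls(X, y, n_orthogonal: int = 1, cv_folds: int = DEFAULT_CV_FOLDS,
             seed: int = 0, scale: str = "uv", cross_validate: bool = True) -> LatentModel:
    """Orthogonal-filtered PLS: remove y-orthogonal variation, then one
    predictive component.  With ``n_orthogonal=0`` this is 1-component PLS."""
    X, y = _validate_xy(X, y)
    if X.shape[0] <= n_orthogonal + 1:
        raise DimensionError("need more samples than orthogonal components + 1")
    model = _fit_core(X, y, 1, n_orthogonal, scale, "opls")
    if cross_validate and cv_folds >= 2:
        model.q2, model.rmsecv = _cross_validate(
            X, y, cv_folds, seed,
            lambda Xi, yi: _fit_core(Xi, yi, 1, min(n_orthogonal, Xi.shape[0] - 2), scale, "opls"),
        )
    return model


def jackknife_ci(fit: Callable[[np.ndarray, np.ndarray], LatentModel], X, y,
                 level: float = 0.95) -> np.ndarray:
    """Per-coefficient confidence intervals from leave-one-out refits.

    Interval = full-fit coefficient +/- t-quantile x jackknife SE, where
    SE^2 = (n-1)/n * sum((b_i - b_mean)^2) over the LOO replicates.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 5:
        raise ValidationError("jackknife needs at least 5 samples")
    full = fit(X, y)
    reps = np.empty((n, X.shape[1]))
    for i in range(n):
        keep = np.arange(n) != i
        try:
            reps[i] = fit(X[keep], y[keep]).coefficients
        except Exception as exc:  # propagate with replicate index
            raise ComputationError(f"jackknife replicate {i} failed: {exc}") from exc
    se = np.sqrt((n - 1) / n * ((reps - reps.mean(axis=0)) ** 2).sum(axis=0))
    tq = stats.t.ppf(0.5 + level / 2.0, n - 1)
    ci = np.column_stack([full.coefficients - tq * se, full.coefficients + tq * se])
    return ci


def evaluate_on_test(model: LatentModel, X_test, y_test) -> tuple[float, np.ndarray]:
    """External validation: RMSEP and per-sample relative errors (percent)."""
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_test = np.asarray(y_test, dtype=float).ravel()
    if X_test.shape[1] != model.coefficients.shape[0]:
        raise DimensionError("test matrix width does not match model")
    if X_test.shape[0] != y_test.size:
        raise DimensionError("test X and y lengths differ")
    pred = model.predict(X_test)
    rmsep = float(np.sqrt(np.mean((y_test - pred) ** 2)))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (pred - y_test) / y_test * 100.0
    return rmsep, rel


def pca(matrix, k: int = 2, confidence: float = 0.95, scale: str = "uv") -> PCAResult:
    """Mean-centered (optionally scaled) SVD with a Hotelling-T2 outlier flag."""
    X = np.asarray(matrix, dtype=float)
    B, n = X.shape
    if B < 3:
        raise ValidationError("PCA needs at least 3 batches")
    if not (1 <= k <= min(B - 1, n)):
        raise DimensionError(f"need 1 <= k <= min(B-1, n), got k={k}")
    Xs = Scaler(scale).fit(X).transform(X)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    var = s**2 / (B - 1)
    explained = var[:k] / var.sum() * 100.0
    score_var = scores.var(axis=0, ddof=1)
    score_var = np.where(score_var == 0, 1.0, score_var)
    t2 = ((scores**2) / score_var).sum(axis=1)
    limit = (k * (B - 1) / (B - k)) * stats.f.ppf(confidence, k, B - k)
    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance_pct=explained,
                     outlier_flags=t2 > limit, t2=t2, t2_limit=float(limit))


def train_test_split(n: int, n_test: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random split returning (train_idx, test_idx)."""
    if not (0 < n_test < n):
        raise ValidationError("n_test must be in (0, n)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return np.sort(order[n_test:]), np.sort(order[:n_test])
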