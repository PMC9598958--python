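"""Per-gene penalized regression of expression on cis methylation.

The model for one gene is the elastic net

    (1/2N) * sum_i (y_i - b0 - sum_j b_j x_ij)^2
        + lambda * alpha * ||b||_1 + lambda * (1 - alpha) / 2 * ||b||_2^2

with alpha = 1 the lasso, alpha = 0 ridge, and 0 < alpha < 1 the mixture.
Features are z-scored internally (training-fold statistics only during CV),
the response is centered, the intercept is unpenalized, and coefficients are
returned on the original data scale.

Model selection follows the usual path strategy: for each alpha on a grid,
100 log-spaced lambda values from lambda_max = max_j |X_j'(y - ybar)| / N /
max(alpha, 1e-3) down to 1e-3 * lambda_max are scored by k-fold
cross-validation with shared fold assignments; the (alpha, lambda) with the
minimal pooled held-out MSE wins (ties: larger lambda, then larger alpha),
and the winner is refit on all samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.linear_model import ElasticNet, enet_path

DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))
ALPHA_FLOOR = 1e-3  # lambda_max guard for the ridge end of the grid


@dataclass(frozen=True)
class PenaltySpec:
    """Elastic-net penalty: L1/L2 mixing weight alpha and strength lam."""

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")


@dataclass(frozen=True)
class Metrics:
    mse: float
    rmse: float
    mae: float
    r2: float  # NaN when var(y_real) == 0


@dataclass
class GeneFit:
    gene_id: str
    probe_ids: list[str]
    intercept: float
    coefficients: np.ndarray  # original data scale, len == n cis probes
    spec: PenaltySpec
    cv: Metrics | None
    n: int
    p: int
    cv_predictions: np.ndarray | None = None  # pooled held-out predictions


def score(y_real, y_pred) -> Metrics:
    """MSE, RMSE, MAE and R2 (R2 against the mean of y_real).

    R2 is undefined for a constant y_real and reported as NaN.
    """
    y = np.asarray(y_real, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    if y.shape != yh.shape:
        raise ValueError("y_real and y_pred must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations to score")
    resid = y - yh
    mse = float(np.mean(resid**2))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return Metrics(mse=mse, rmse=float(np.sqrt(mse)), mae=mae, r2=r2)


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Xs = np.zeros_like(X, dtype=float)
    ok = sd > 0
    Xs[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return Xs, mu, sd, ok


def _ridge_path(Xs: np.ndarray, yc: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Closed-form ridge solutions (standardized scale) for every lambda.

    Solves (X'X/N + lam I) b = X'y/N via one eigendecomposition.
    Returns shape (p, n_lams).
    """
    n = Xs.shape[0]
    G = Xs.T @ Xs / n
    b = Xs.T @ yc / n
    w, V = np.linalg.eigh(G)
    vb = V.T @ b
    denom = w[:, None] + np.asarray(lams)[None, :]
    denom[denom <= 0] = np.inf  # zero-variance directions at lam == 0
    return V @ (vb[:, None] / denom)


def fit_penalized(
    X,
    y,
    spec: PenaltySpec,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> tuple[float, np.ndarray]:
    """Fit the elastic net at a fixed penalty; returns (intercept, coefs).

    Coefficients are on the original data scale; zero-variance features get
    coefficient 0. alpha = 0 uses the ridge closed form, alpha > 0 sklearn's
    coordinate descent on the standardized problem.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if len(y) != n:
        raise ValueError("X and y are misaligned")
    Xs, mu, sd, ok = _standardize(X)
    ybar = y.mean()
    yc = y - ybar
    if spec.alpha == 0.0:
        bs = _ridge_path(Xs, yc, np.array([spec.lam]))[:, 0]
    else:
        model = ElasticNet(
            alpha=max(spec.lam, np.finfo(float).tiny),
            l1_ratio=spec.alpha,
            fit_intercept=False,
            max_iter=max_iter,
            tol=tol,
        )
        model.fit(Xs, yc)
        bs = model.coef_.copy()
    coefs = np.zeros(p)
    coefs[ok] = bs[ok] / sd[ok]
    intercept = ybar - float(coefs @ mu)
    return intercept, coefs


def lambda_path(
    X, y, alpha: float, n_lambda: int = 100, lambda_min_ratio: float = 1e-3
) -> np.ndarray:
    """Descending log-spaced lambda path from the data-driven lambda_max."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xs, _, _, _ = _standardize(X)
    yc = y - y.mean()
    lam_max = np.max(np.abs(Xs.T @ yc)) / len(y) / max(alpha, ALPHA_FLOOR)
    if lam_max <= 0:
        lam_max = 1.0  # y constant or X all zero-variance; any path works
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def _fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def cross_validate(
    X,
    y,
    *,
    gene_id: str = "",
    probe_ids: Sequence[str] | None = None,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    n_folds: int = 5,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-4,
    max_iter: int = 20_000,
) -> GeneFit:
    """Grid-search (alpha, lambda) by k-fold CV and refit on all samples.

    Held-out predictions are pooled across folds before computing the CV
    metrics, and the same fold assignment (derived from ``seed``) is reused
    for every grid point so comparisons are paired.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} samples for {n_folds}-fold CV")
    folds = _fold_indices(n, n_folds, seed)

    candidates = []  # (mse, -lam, -alpha, alpha, lam, preds column)
    for alpha in alpha_grid:
        path = lambda_path(X, y, alpha, n_lambda, lambda_min_ratio)
        preds = np.empty((n, n_lambda))
        for te in folds:
            tr = np.setdiff1d(np.arange(n), te)
            Xtr, ytr = X[tr], y[tr]
            Xs, mu, sd, ok = _standardize(Xtr)
            ytr_bar = ytr.mean()
            yc = ytr - ytr_bar
            if alpha == 0.0:
                coefs = _ridge_path(Xs, yc, path)
            else:
                _, coefs, _ = enet_path(
                    Xs, yc, l1_ratio=alpha, alphas=path, tol=tol, max_iter=max_iter
                )
            Xte = np.zeros((len(te), p))
            Xte[:, ok] = (X[np.ix_(te, np.where(ok)[0])] - mu[ok]) / sd[ok]
            preds[te] = Xte @ coefs + ytr_bar
        mse = ((preds - y[:, None]) ** 2).mean(axis=0)
        for j, lam in enumerate(path):
            candidates.append((mse[j], -lam, -alpha, alpha, lam, preds[:, j]))

    best = min(candidates, key=lambda c: (c[0], c[1], c[2]))
    spec = PenaltySpec(alpha=best[3], lam=best[4])
    pooled = best[5]
    cv = score(y, pooled)
    intercept, coefs = fit_penalized(X, y, spec, tol=tol, max_iter=max_iter)
    return GeneFit(
        gene_id=gene_id,
        probe_ids=list(probe_ids) if probe_ids is not None else [str(j) for j in range(p)],
        intercept=intercept,
        coefficients=coefs,
        spec=spec,
        cv=cv,
        n=n,
        p=p,
        cv_predictions=pooled,
    )


def objective(X, y, intercept: float, coefs, spec: PenaltySpec) -> float:
    """Value of the penalized objective on the standardized scale.

    Used by local-optimality checks: the penalty applies to the coefficients
    as fitted internally (standardized features), so original-scale
    coefficients are rescaled by the feature sd before evaluating.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    resid = y - intercept - X @ np.asarray(coefs)
    sd = X.std(axis=0)
    bs = np.asarray(coefs) * np.where(sd > 0, sd, 1.0)
    return float(
        (resid @ resid) / (2 * n)
        + spec.lam * spec.alpha * np.abs(bs).sum()
        + spec.lam * (1 - spec.alpha) / 2 * (bs @ bs)
    )
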