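"""L1-penalized logistic regression with cross-validated penalty selection.

The fitted objective is

    f(beta0, beta) = -(1/n) * loglik(beta0, beta) + lambda * ||beta||_1

with an unpenalized intercept, solved by cyclic coordinate descent on a
majorized quadratic approximation (the logistic Hessian is bounded by 1/4, so
each coordinate step ``beta_j <- S(beta_j - 4*g_j, 4*lambda)`` on standardized
columns monotonically decreases the objective).  Solutions along a decreasing
lambda path are warm-started; convergence is declared when the KKT
stationarity residual falls below ``tol``:

    beta_j = 0:  |g_j| <= lambda + tol
    beta_j != 0: |g_j + lambda * sign(beta_j)| <= tol

where g is the gradient of the negative mean log-likelihood.  Variables are
standardized (population sd) before penalized fitting so the penalty is
scale-equivariant; coefficients are reported on both scales and odds ratios
refer to one unit of the original variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

VARIABLE_BLOCK_NAMES = ("voc", "parental_history", "wbc", "atopic_flag")


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to reach KKT stationarity within max_iter."""


@dataclass
class DesignMatrix:
    """Samples x variables matrix with names, block tags and scaling state."""

    X: np.ndarray
    variable_names: list
    variable_block: dict = field(default_factory=dict)
    standardization: dict | None = None  # name -> (mean, sd), set by standardize()
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.variable_names):
            raise ValueError("X shape does not match variable_names")

    def subset_rows(self, idx) -> "DesignMatrix":
        return DesignMatrix(
            self.X[idx], list(self.variable_names), dict(self.variable_block),
            self.standardization, list(self.dropped),
        )


@dataclass
class LassoModel:
    lambda_: float
    intercept: float  # original scale
    beta: np.ndarray  # original scale, aligned with variable_names
    beta_standardized: np.ndarray
    intercept_standardized: float
    variable_names: list
    standardization: dict  # name -> (mean, sd)
    class_labels: tuple = ("case", "control")
    n_iter: int = 0

    @property
    def selected(self) -> list:
        return [
            name
            for name, b in zip(self.variable_names, self.beta_standardized)
            if b != 0.0
        ]

    @property
    def odds_ratios(self) -> dict:
        return odds_ratios(self)


@dataclass
class CvLambdaResult:
    lambda_grid: np.ndarray  # decreasing
    per_lambda_cv_metric: np.ndarray
    chosen_lambda: float
    folds: list  # list of held-out index arrays
    seed: int
    metric: str


def standardize(dm: DesignMatrix) -> DesignMatrix:
    """Center and scale every column to mean 0, population sd 1.

    Zero-variance columns cannot enter penalized fitting and are dropped with
    a warning; the returned design records per-variable (mean, sd) so fitted
    coefficients can be mapped back to the original scale exactly.
    """
    X = dm.X
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd
    keep = sd > 0
    dropped = [n for n, k in zip(dm.variable_names, keep) if not k]
    if dropped:
        logger.warning("dropping zero-variance variables: %s", dropped)
    names = [n for n, k in zip(dm.variable_names, keep) if k]
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    standardization = {
        n: (float(m), float(s))
        for n, m, s in zip(names, mean[keep], sd[keep])
    }
    return DesignMatrix(
        Xs,
        names,
        {n: b for n, b in dm.variable_block.items() if n in set(names)},
        standardization,
        dropped,
    )


def lambda_max(X, y) -> float:
    """Smallest lambda at which the penalized solution is all-zero.

    Computed on internally standardized columns: max_j |x_j^T (y - ybar)| / n.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    r = y - y.mean()
    return float(np.max(np.abs(Xs.T @ r)) / len(y))


@njit(cache=True)
def _objective(Xs, y, b0, beta, lam):  # pragma: no cover - jitted
    n = Xs.shape[0]
    obj = 0.0
    for i in range(n):
        eta = b0
        for j in range(Xs.shape[1]):
            eta += Xs[i, j] * beta[j]
        # -loglik, numerically stable log(1 + e^eta)
        if eta > 0.0:
            obj += eta + np.log1p(np.exp(-eta)) - y[i] * eta
        else:
            obj += np.log1p(np.exp(eta)) - y[i] * eta
    obj /= n
    for j in range(beta.shape[0]):
        obj += lam * abs(beta[j])
    return obj


@njit(cache=True)
def _cd_path(Xs, y, lambdas, tol, max_iter):  # pragma: no cover - jitted
    """Warm-started coordinate-descent path over decreasing lambdas.

    Outer loop: quadratic (IRLS) approximation of the logistic loss at the
    current iterate; inner loop: cyclic coordinate descent with
    soft-thresholding on the penalized weighted least squares, iterating the
    active set between full sweeps.  A step-halving safeguard keeps the
    true penalized objective monotone.  Stops when the true-gradient KKT
    residual is <= tol.  Returns (intercepts, betas[L, p], outer iters[L],
    converged[L]).
    """
    n, p = Xs.shape
    L = lambdas.shape[0]
    wmin = 1e-5
    out_b0 = np.zeros(L)
    out_beta = np.zeros((L, p))
    n_iters = np.zeros(L, dtype=np.int64)
    conv = np.zeros(L, dtype=np.bool_)
    ybar = y.mean()
    beta = np.zeros(p)
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    prob = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)  # weighted working residual (z - current linear predictor)
    wcolsq = np.empty(p)
    beta_old = np.empty(p)
    for l in range(L):
        lam = lambdas[l]
        converged = False
        it = 0
        obj = _objective(Xs, y, b0, beta, lam)
        while it < max_iter:
            it += 1
            for i in range(n):
                prob[i] = 1.0 / (1.0 + np.exp(-eta[i]))
            # KKT stationarity residual of the true objective
            g0 = 0.0
            for i in range(n):
                g0 -= y[i] - prob[i]
            g0 /= n
            resid = abs(g0)
            for j in range(p):
                gj = 0.0
                for i in range(n):
                    gj -= Xs[i, j] * (y[i] - prob[i])
                gj /= n
                if beta[j] == 0.0:
                    rj = abs(gj) - lam
                    if rj < 0.0:
                        rj = 0.0
                else:
                    sj = 1.0 if beta[j] > 0.0 else -1.0
                    rj = abs(gj + lam * sj)
                if rj > resid:
                    resid = rj
            if resid <= tol:
                converged = True
                break
            # IRLS quadratic at the current iterate
            for i in range(n):
                wi = prob[i] * (1.0 - prob[i])
                if wi < wmin:
                    wi = wmin
                w[i] = wi
                r[i] = y[i] - prob[i]  # = w * (z - eta)
            wsum = 0.0
            for i in range(n):
                wsum += w[i]
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * Xs[i, j] * Xs[i, j]
                wcolsq[j] = s / n
            for j in range(p):
                beta_old[j] = beta[j]
            b0_old = b0
            # inner CD on the weighted quadratic; r tracks w * residual
            inner_tol = min(tol, 1e-7)
            for sweep in range(200):
                full = sweep % 5 == 0  # full sweep every 5th, else active set
                maxd = 0.0
                rsum = 0.0
                for i in range(n):
                    rsum += r[i]
                d0 = rsum / wsum
                if d0 != 0.0:
                    b0 += d0
                    for i in range(n):
                        r[i] -= d0 * w[i]
                    if abs(d0) > maxd:
                        maxd = abs(d0)
                for j in range(p):
                    if not full and beta[j] == 0.0:
                        continue
                    dot = 0.0
                    for i in range(n):
                        dot += Xs[i, j] * r[i]
                    rho = dot / n + wcolsq[j] * beta[j]
                    if rho > lam:
                        new = (rho - lam) / wcolsq[j]
                    elif rho < -lam:
                        new = (rho + lam) / wcolsq[j]
                    else:
                        new = 0.0
                    d = new - beta[j]
                    if d != 0.0:
                        beta[j] = new
                        for i in range(n):
                            r[i] -= d * w[i] * Xs[i, j]
                        if abs(d) > maxd:
                            maxd = abs(d)
                if full and maxd <= inner_tol:
                    break
            # step-halving safeguard: the IRLS step must not increase the
            # true penalized objective
            new_obj = _objective(Xs, y, b0, beta, lam)
            halvings = 0
            while new_obj > obj + 1e-14 and halvings < 30:
                b0 = 0.5 * (b0 + b0_old)
                for j in range(p):
                    beta[j] = 0.5 * (beta[j] + beta_old[j])
                new_obj = _objective(Xs, y, b0, beta, lam)
                halvings += 1
            obj = new_obj
            for i in range(n):
                e = b0
                for j in range(p):
                    if beta[j] != 0.0:
                        e += Xs[i, j] * beta[j]
                eta[i] = e
        out_b0[l] = b0
        out_beta[l] = beta
        n_iters[l] = it
        conv[l] = converged
    return out_b0, out_beta, n_iters, conv


def _fit_path_standardized(Xs, y, lambdas, tol, max_iter):
    b0, beta, n_iters, conv = _cd_path(
        np.ascontiguousarray(Xs, dtype=float),
        np.asarray(y, dtype=float),
        np.asarray(lambdas, dtype=float),
        tol,
        max_iter,
    )
    return b0, beta, n_iters, conv


def fit_lasso_lr(
    dm: DesignMatrix,
    y,
    lambda_: float,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    class_labels: tuple = ("case", "control"),
) -> LassoModel:
    """Fit the penalized logistic model at one lambda.

    ``dm`` must be a standardized design (see :func:`standardize`).  Raises
    :class:`ConvergenceError` when KKT stationarity is not reached within
    ``max_iter`` sweeps.
    """
    if dm.standardization is None:
        raise ValueError("design must be standardized before fitting")
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    b0, beta, n_iters, conv = _fit_path_standardized(
        dm.X, y, np.array([lambda_]), tol, max_iter
    )
    if not conv[0]:
        raise ConvergenceError(
            f"no KKT stationarity at lambda={lambda_:g} within {max_iter} sweeps "
            f"(tol={tol:g}); the unpenalized MLE may not exist (separable data)"
        )
    return _to_model(
        dm, float(lambda_), float(b0[0]), beta[0], int(n_iters[0]), class_labels
    )


def _to_model(dm, lam, b0_std, beta_std, n_iter, class_labels):
    means = np.array([dm.standardization[n][0] for n in dm.variable_names])
    sds = np.array([dm.standardization[n][1] for n in dm.variable_names])
    beta_orig = beta_std / sds
    intercept_orig = b0_std - float(beta_orig @ means)
    return LassoModel(
        lambda_=lam,
        intercept=intercept_orig,
        beta=beta_orig,
        beta_standardized=np.asarray(beta_std, dtype=float).copy(),
        intercept_standardized=b0_std,
        variable_names=list(dm.variable_names),
        standardization=dict(dm.standardization),
        class_labels=class_labels,
        n_iter=n_iter,
    )


def kkt_residual(model: LassoModel, dm: DesignMatrix, y) -> float:
    """Max KKT stationarity residual of a fitted model on its training design."""
    y = np.asarray(y, dtype=float)
    eta = model.intercept_standardized + dm.X @ model.beta_standardized
    prob = 1.0 / (1.0 + np.exp(-eta))
    g = -(dm.X.T @ (y - prob)) / len(y)
    resid = abs(float((y - prob).mean()))
    for j, b in enumerate(model.beta_standardized):
        if b == 0.0:
            resid = max(resid, max(0.0, abs(g[j]) - model.lambda_))
        else:
            resid = max(resid, abs(g[j] + model.lambda_ * np.sign(b)))
    return resid


def lambda_grid(X, y, n_lambda: int = 50, ratio: float = 1e-3) -> np.ndarray:
    """Decreasing log-spaced grid from lambda_max down to lambda_max * ratio."""
    lmax = lambda_max(X, y)
    return np.geomspace(lmax, lmax * ratio, n_lambda)


def stratified_folds(y, k: int, rng) -> list:
    """Deterministic stratified k-fold partition; returns held-out index arrays.

    Indices are shuffled within each class and dealt round-robin, so every
    fold contains both classes whenever each class has at least k members or,
    failing that, as evenly as possible.
    """
    y = np.asarray(y)
    folds = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        for pos, i in enumerate(idx):
            folds[(offset + pos) % k].append(int(i))
        offset += idx.size  # stagger classes across folds
    out = [np.sort(np.array(f, dtype=int)) for f in folds]
    for f in out:
        if f.size == 0:
            raise ValueError(f"cannot build {k} non-empty stratified folds")
    return out


def _binomial_deviance(y, prob) -> float:
    eps = 1e-12
    p = np.clip(prob, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def cv_select_lambda(
    dm: DesignMatrix,
    y,
    k: int = 5,
    n_lambda: int = 50,
    seed: int = 0,
    metric: str = "deviance",
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> CvLambdaResult:
    """Choose lambda by stratified k-fold cross-validation.

    The grid runs from lambda_max (computed on the full data) down three
    decades; the per-lambda metric is the mean held-out binomial deviance
    (or 1 - AUC with ``metric="auc"``) and the chosen lambda is the grid
    minimizer, ties resolved toward the larger (more parsimonious) lambda.
    """
    from .evaluation import auc as _auc  # local import to avoid a cycle

    if k < 2:
        raise ValueError("k must be >= 2")
    if metric not in ("deviance", "auc"):
        raise ValueError(f"unknown metric {metric!r}")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    grid = lambda_grid(dm.X, y, n_lambda=n_lambda)
    folds = stratified_folds(y, k, rng)
    losses = np.zeros((k, grid.size))
    all_idx = np.arange(len(y))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        if len(np.unique(y[test_idx])) < 2 and metric == "auc":
            raise ValueError("a fold contains one class; cannot score AUC")
        dtrain = standardize(dm.subset_rows(train_idx))
        b0, beta, _, conv = _fit_path_standardized(
            dtrain.X, y[train_idx], grid, tol, max_iter
        )
        if not conv.all():
            raise ConvergenceError("path fit did not converge inside CV")
        # score on the held-out samples, using the fold's scaling
        name_to_col = {n: i for i, n in enumerate(dm.variable_names)}
        cols = [name_to_col[n] for n in dtrain.variable_names]
        mu = np.array([dtrain.standardization[n][0] for n in dtrain.variable_names])
        sd = np.array([dtrain.standardization[n][1] for n in dtrain.variable_names])
        Xtest = (dm.X[np.ix_(test_idx, cols)] - mu) / sd
        eta = b0[None, :] + Xtest @ beta.T  # test samples x lambdas
        prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        for l in range(grid.size):
            if metric == "deviance":
                losses[f, l] = _binomial_deviance(y[test_idx], prob[:, l])
            else:
                losses[f, l] = 1.0 - _auc(prob[:, l], y[test_idx])
    mean_loss = losses.mean(axis=0)
    chosen = float(grid[int(np.argmin(mean_loss))])  # first minimum = largest lambda
    return CvLambdaResult(
        lambda_grid=grid,
        per_lambda_cv_metric=mean_loss,
        chosen_lambda=chosen,
        folds=folds,
        seed=seed,
        metric=metric,
    )


def predict_prob(model: LassoModel, X_new, variable_names=None) -> np.ndarray:
    """Predicted case probabilities 1 / (1 + exp(-(b0 + X beta)))."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if variable_names is not None and list(variable_names) != model.variable_names:
        raise ValueError("variable names do not match the fitted model")
    if X_new.shape[1] != len(model.variable_names):
        raise ValueError(
            f"expected {len(model.variable_names)} variables, got {X_new.shape[1]}"
        )
    eta = model.intercept + X_new @ model.beta
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))


def odds_ratios(model: LassoModel) -> dict:
    """exp(original-scale beta) per selected variable (per 1 original unit)."""
    return {
        name: float(np.exp(b))
        for name, b, bs in zip(
            model.variable_names, model.beta, model.beta_standardized
        )
        if bs != 0.0
    }
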