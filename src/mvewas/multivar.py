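"""L1-penalized multivariate regression with joint sparse precision estimation.

Stage 2, multivariate arm. For one gene cluster with standardized residual
matrix X (n x m) and phenotype matrix Y (n x 3), the model jointly estimates
the coefficient matrix and the inverse covariance of the phenotype residuals
by minimizing

    (1/n) tr[(Y - W Gamma_w - X Gamma3^T)^T (Y - W Gamma_w - X Gamma3^T) Theta]
        - log det Theta + lambda ||Gamma3||_1 + rho ||Theta||_{1,offdiag}

over Gamma_w (unpenalized covariate block: intercept, diagnosis, APOE4),
Gamma3 (penalized probe block, q x m) and symmetric positive definite Theta
(q x q). The trace term is n-normalized so the likelihood part does not grow
with sample size.

The solver alternates
  (a) a Theta-step: graphical lasso on the current residual covariance with
      off-diagonal penalty rho (diagonal unpenalized), and
  (b) a Gamma-step: cyclic coordinate descent with closed-form
      soft-threshold updates (exact for the quadratic-plus-L1 subproblem),
until the relative objective change drops below tolerance. Each step solves
its subproblem, so the objective is nonincreasing across outer iterations.

Penalties are tuned on a log-spaced (lambda, rho) grid by BIC (default) or
k-fold cross-validation on the held-out Gaussian negative log-likelihood,
warm-starting along decreasing lambda. Phenotypes are deliberately NOT
re-centered or re-scaled inside the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold


@dataclass
class PenalizedProblem:
    """One cluster's data plus penalty levels."""

    Y: np.ndarray  # n x q phenotypes
    W: np.ndarray  # n x c unpenalized design (intercept, DX coding, APOE4)
    X: np.ndarray  # n x m standardized probe residuals
    lam: float = 0.0
    rho: float = 0.0

    def __post_init__(self):
        self.Y = np.ascontiguousarray(self.Y, dtype=float)
        self.W = np.ascontiguousarray(self.W, dtype=float)
        self.X = np.ascontiguousarray(self.X, dtype=float)
        n, q = self.Y.shape
        if self.W.shape[0] != n or self.X.shape[0] != n:
            raise ValueError("Y, W, X must share the sample dimension")
        if n <= q:
            raise ValueError("need more samples than phenotypes")
        if self.lam < 0 or self.rho < 0:
            raise ValueError("penalties must be nonnegative")
        for name, arr in (("Y", self.Y), ("W", self.W), ("X", self.X)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")


@dataclass
class PenalizedFit:
    """Converged (or best-iterate) solution of one penalized problem."""

    Gamma_w: np.ndarray  # c x q unpenalized coefficients
    Gamma3: np.ndarray  # q x m penalized probe coefficients
    Theta: np.ndarray  # q x q precision matrix
    lam: float
    rho: float
    objective: float
    n_iter: int
    converged: bool
    residuals: np.ndarray  # n x q
    objective_history: list = field(default_factory=list)
    bic: float | None = None
    cv_error: float | None = None

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.Gamma3))


@njit(cache=False)
def _cd_sweep(G, B, U, Theta, lam, n, c):
    """One cyclic coordinate-descent sweep over all coefficients.

    G = Z^T Z, U = Z^T (Y - Z B) (maintained incrementally), B is the
    stacked (c+m) x q coefficient matrix with the first c rows unpenalized.
    Returns the largest absolute coefficient change of the sweep.
    """
    p, q = B.shape
    max_delta = 0.0
    for j in range(p):
        gjj = G[j, j]
        if gjj <= 0.0:
            continue
        for k in range(q):
            tkk = Theta[k, k]
            ut = 0.0
            for l in range(q):
                ut += U[j, l] * Theta[l, k]
            denom = gjj * tkk
            bstar = B[j, k] + ut / denom
            if j >= c:
                thr = 0.5 * n * lam / denom
                if bstar > thr:
                    bnew = bstar - thr
                elif bstar < -thr:
                    bnew = bstar + thr
                else:
                    bnew = 0.0
            else:
                bnew = bstar
            delta = bnew - B[j, k]
            if delta != 0.0:
                B[j, k] = bnew
                for i in range(p):
                    U[i, k] -= G[i, j] * delta
                ad = abs(delta)
                if ad > max_delta:
                    max_delta = ad
    return max_delta


def _theta_step(S: np.ndarray, rho: float) -> np.ndarray:
    """Solve min_Theta tr(S Theta) - logdet Theta + rho ||Theta||_1,offdiag."""
    q = S.shape[0]
    if rho == 0.0:
        w = np.linalg.eigvalsh(S)
        if w.min() <= 1e-12 * max(w.max(), 1.0):
            raise np.linalg.LinAlgError(
                "singular residual covariance with rho=0; increase rho or n"
            )
        return np.linalg.inv(S)
    with warnings.catch_warnings():
        # the duality gap can stall around 1e-5 on near-singular inputs;
        # that accuracy is ample here and the outer loop monitors the
        # objective, so the solver's convergence warning is noise
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        _, prec = graphical_lasso(
            S, alpha=rho, tol=1e-8, enet_tol=1e-10, max_iter=500
        )
    return (prec + prec.T) / 2.0


def objective_value(
    Y: np.ndarray,
    W: np.ndarray,
    X: np.ndarray,
    Gamma_w: np.ndarray,
    Gamma3: np.ndarray,
    Theta: np.ndarray,
    lam: float,
    rho: float,
) -> float:
    """The penalized negative-log-likelihood objective (n-normalized trace)."""
    n = Y.shape[0]
    R = Y - W @ Gamma_w - X @ Gamma3.T
    S = R.T @ R / n
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        return np.inf
    pen = lam * np.abs(Gamma3).sum()
    pen += rho * (np.abs(Theta).sum() - np.abs(np.diag(Theta)).sum())
    return float(np.trace(S @ Theta) - logdet + pen)


def fit_penalized(
    problem: PenalizedProblem,
    tol: float = 1e-4,
    max_outer: int = 100,
    inner_tol: float = 1e-10,
    max_sweeps: int = 1000,
    warm_B: np.ndarray | None = None,
) -> PenalizedFit:
    """Alternating solver for one (lambda, rho) point.

    ``warm_B`` optionally seeds the stacked coefficient matrix (used along
    penalty paths). Hitting ``max_outer`` returns the best iterate flagged
    ``converged=False``.
    """
    Y, W, X, lam, rho = problem.Y, problem.W, problem.X, problem.lam, problem.rho
    n, q = Y.shape
    c = W.shape[1]
    Z = np.ascontiguousarray(np.hstack([W, X]))
    p = Z.shape[1]
    G = Z.T @ Z
    V = Z.T @ Y

    if warm_B is not None:
        B = np.ascontiguousarray(warm_B, dtype=float).copy()
        if B.shape != (p, q):
            raise ValueError("warm start has wrong shape")
    else:
        B = np.zeros((p, q))
        B[:c], *_ = np.linalg.lstsq(W, Y, rcond=None)
    U = V - G @ B

    # Theta-step first: with Gamma3 = 0 this reproduces the covariates-only
    # precision, making the lambda_max KKT bound exact.
    R = Y - Z @ B
    Theta = _theta_step(R.T @ R / n, rho)

    obj = objective_value(Y, W, X, B[:c], B[c:].T, Theta, lam, rho)
    history = [obj]
    converged = False
    it = 0
    for it in range(1, max_outer + 1):
        for _ in range(max_sweeps):
            if _cd_sweep(G, B, U, Theta, lam, float(n), c) < inner_tol:
                break
        R = Y - Z @ B
        Theta = _theta_step(R.T @ R / n, rho)
        new_obj = objective_value(Y, W, X, B[:c], B[c:].T, Theta, lam, rho)
        history.append(new_obj)
        if new_obj > obj + 1e-8:
            warnings.warn("objective increased beyond tolerance", stacklevel=2)
        if abs(obj - new_obj) <= tol * max(1.0, abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if not converged:
        warnings.warn(
            f"alternating solver hit max_outer={max_outer}; returning best iterate",
            stacklevel=2,
        )
    return PenalizedFit(
        Gamma_w=B[:c].copy(),
        Gamma3=B[c:].T.copy(),
        Theta=Theta,
        lam=lam,
        rho=rho,
        objective=obj,
        n_iter=it,
        converged=converged,
        residuals=R,
        objective_history=history,
    )


def make_grid(
    Y: np.ndarray,
    W: np.ndarray,
    X: np.ndarray,
    n_lambda: int = 20,
    n_rho: int = 10,
    min_fraction: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced penalty grids anchored at the full-shrinkage points.

    lambda_max is the smallest lambda at which the probe block is entirely
    zero at the covariates-only solution — by the KKT condition of the
    n-normalized objective, (2/n) max |X^T R Theta0| with R the
    covariates-only residuals and Theta0 the corresponding precision.
    rho_max is the largest absolute off-diagonal residual covariance (the
    graphical-lasso full-sparsity point). Grids are returned in decreasing
    order for warm-started paths.
    """
    Y = np.asarray(Y, dtype=float)
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    if not np.any(X != 0):
        raise ValueError("X is entirely zero; no penalized block to tune")
    n = Y.shape[0]
    Gw, *_ = np.linalg.lstsq(W, Y, rcond=None)
    R = Y - W @ Gw
    S = R.T @ R / n
    Theta0 = _theta_step(S, 0.0)
    # tiny safety factor so coordinates at exact KKT equality round to zero
    lam_max = 2.0 / n * np.abs(X.T @ R @ Theta0).max() * (1.0 + 1e-8)
    off = np.abs(S - np.diag(np.diag(S)))
    rho_max = max(off.max(), 1e-8)
    lam_grid = np.geomspace(lam_max, min_fraction * lam_max, n_lambda)
    rho_grid = np.geomspace(rho_max, min_fraction * rho_max, n_rho)
    return lam_grid, rho_grid


def compute_bic(fit: PenalizedFit, n: int, zero_tol: float = 1e-10) -> float:
    """BIC = n [tr(S_res Theta) - logdet Theta] + ln(n) df.

    df counts nonzero probe coefficients plus nonzero upper off-diagonal
    precision entries; explicitly stored zeros do not contribute.
    """
    S_res = fit.residuals.T @ fit.residuals / n
    sign, logdet = np.linalg.slogdet(fit.Theta)
    q = fit.Theta.shape[0]
    iu = np.triu_indices(q, 1)
    df = int(np.count_nonzero(np.abs(fit.Gamma3) > zero_tol))
    df += int(np.count_nonzero(np.abs(fit.Theta[iu]) > zero_tol))
    return float(n * (np.trace(S_res @ fit.Theta) - logdet) + np.log(n) * df)


def _path_fits(Y, W, X, lam_grid, rho_grid, tol, max_outer):
    """Warm-started fits over the penalty grid (decreasing lambda within
    each rho); yields (fit) for every grid point."""
    c = W.shape[1]
    p = c + X.shape[1]
    q = Y.shape[1]
    for rho in rho_grid:
        warm = None
        for lam in lam_grid:
            fit = fit_penalized(
                PenalizedProblem(Y, W, X, lam=float(lam), rho=float(rho)),
                tol=tol,
                max_outer=max_outer,
                warm_B=warm,
            )
            warm = np.vstack([fit.Gamma_w, fit.Gamma3.T])
            assert warm.shape == (p, q)
            yield fit


def tune_by_bic(
    Y: np.ndarray,
    W: np.ndarray,
    X: np.ndarray,
    lam_grid: np.ndarray,
    rho_grid: np.ndarray,
    tol: float = 1e-4,
    max_outer: int = 100,
) -> tuple[PenalizedFit, pd.DataFrame]:
    """Minimize BIC over the grid; returns the winning fit and the surface."""
    n = Y.shape[0]
    best = None
    rows = []
    for fit in _path_fits(Y, W, X, lam_grid, rho_grid, tol, max_outer):
        fit.bic = compute_bic(fit, n)
        rows.append((fit.lam, fit.rho, fit.bic, fit.n_nonzero))
        if best is None or fit.bic < best.bic:
            best = fit
    surface = pd.DataFrame(rows, columns=["lam", "rho", "bic", "n_nonzero"])
    return best, surface


def cross_validate(
    Y: np.ndarray,
    W: np.ndarray,
    X: np.ndarray,
    lam_grid: np.ndarray,
    rho_grid: np.ndarray,
    k: int = 5,
    seed: int = 0,
    tol: float = 1e-4,
    max_outer: int = 100,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """k-fold CV on the held-out Gaussian negative log-likelihood.

    Per grid point, the error is the fold-mean of
    tr(S_test Theta_hat) - logdet Theta_hat with training-set estimates.
    Fold assignment is deterministic given ``seed``. Returns the (lambda,
    rho) minimizer and the error surface.
    """
    n = Y.shape[0]
    if n < 2 * k:
        raise ValueError("need at least 2k samples for k-fold CV")
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(Y))
    n_pts = len(lam_grid) * len(rho_grid)
    errs = np.zeros(n_pts)
    for train, test in folds:
        for col in range(Y.shape[1]):
            if Y[train, col].std() == 0 or Y[test, col].std() == 0:
                raise ValueError("a CV fold has a zero-variance phenotype")
        fits = _path_fits(
            Y[train], W[train], X[train], lam_grid, rho_grid, tol, max_outer
        )
        for i, fit in enumerate(fits):
            R = Y[test] - W[test] @ fit.Gamma_w - X[test] @ fit.Gamma3.T
            S_te = R.T @ R / len(test)
            _, logdet = np.linalg.slogdet(fit.Theta)
            errs[i] += (np.trace(S_te @ fit.Theta) - logdet) / k
    grid_pts = [(float(l), float(r)) for r in rho_grid for l in lam_grid]
    surface = pd.DataFrame(grid_pts, columns=["lam", "rho"])
    surface["cv_error"] = errs
    best_i = int(np.argmin(errs))
    return grid_pts[best_i], surface


def tune_penalized(
    Y: np.ndarray,
    W: np.ndarray,
    X: np.ndarray,
    criterion: str = "bic",
    n_lambda: int = 20,
    n_rho: int = 10,
    cv_folds: int = 5,
    seed: int = 0,
    tol: float = 1e-4,
    max_outer: int = 100,
) -> PenalizedFit:
    """Grid construction + tuning + (for CV) a final full-data refit."""
    lam_grid, rho_grid = make_grid(Y, W, X, n_lambda=n_lambda, n_rho=n_rho)
    if criterion == "bic":
        best, _ = tune_by_bic(Y, W, X, lam_grid, rho_grid, tol=tol, max_outer=max_outer)
        return best
    if criterion == "cv":
        (lam, rho), surface = cross_validate(
            Y, W, X, lam_grid, rho_grid, k=cv_folds, seed=seed, tol=tol, max_outer=max_outer
        )
        fit = fit_penalized(
            PenalizedProblem(Y, W, X, lam=lam, rho=rho), tol=tol, max_outer=max_outer
        )
        fit.cv_error = float(surface["cv_error"].min())
        return fit
    raise ValueError(f"unknown tuning criterion {criterion!r}")


def select_probes(
    cluster_fits: list[tuple[str, list, PenalizedFit]],
    phenotypes: tuple[str, ...] = ("A", "M", "D"),
    zero_tol: float = 0.0,
) -> pd.DataFrame:
    """Union of probes with any nonzero penalized coefficient.

    ``cluster_fits`` holds (cluster_id, probe_ids, fit) triples. A probe
    appearing in several clusters gets one row, keeping per phenotype the
    largest-magnitude coefficient. Rows are ordered by descending maximum
    absolute effect, ties broken by probe id.
    """
    effects: dict[str, np.ndarray] = {}
    sources: dict[str, list] = {}
    for cluster_id, probe_ids, fit in cluster_fits:
        gamma = fit.Gamma3
        if gamma.shape[1] != len(probe_ids):
            raise ValueError(f"cluster {cluster_id}: probe list does not match fit")
        for j, pid in enumerate(probe_ids):
            col = gamma[:, j]
            if not np.any(np.abs(col) > zero_tol):
                continue
            if pid in effects:
                prev = effects[pid]
                effects[pid] = np.where(np.abs(col) > np.abs(prev), col, prev)
                sources[pid].append(cluster_id)
            else:
                effects[pid] = col.copy()
                sources[pid] = [cluster_id]
    cols = [f"effect_{ph}" for ph in phenotypes]
    if not effects:
        return pd.DataFrame(columns=["probe_id", *cols, "clusters"]).set_index("probe_id")
    table = pd.DataFrame.from_dict(effects, orient="index", columns=cols)
    table.index.name = "probe_id"
    table["clusters"] = [";".join(sources[p]) for p in table.index]
    table["_max_abs"] = table[cols].abs().max(axis=1)
    table = table.sort_values(
        ["_max_abs", "probe_id"], ascending=[False, True], kind="stable"
    ).drop(columns="_max_abs")
    return table
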