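"""Slow reference solvers used to validate the production path.

Everything here is algorithmically disjoint from :mod:`mvewas.multivar`:
the coefficient subproblem is solved by FISTA (accelerated proximal
gradient with a global Lipschitz constant) instead of cyclic coordinate
descent, and the precision subproblem by an ADMM splitting with a
closed-form eigenvalue update instead of the graphical-lasso coordinate
algorithm. These routines exist to cross-check objective values and support
sets on small instances; they are not meant to be fast.
"""

from __future__ import annotations

import numpy as np


def ref_objective(Y, W, X, Gamma_w, Gamma3, Theta, lam, rho) -> float:
    """Independent evaluation of the penalized objective."""
    Y, W, X = (np.asarray(a, dtype=float) for a in (Y, W, X))
    n = Y.shape[0]
    R = Y - W @ Gamma_w - X @ Gamma3.T
    S = R.T @ R / n
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        return np.inf
    off = np.abs(Theta).sum() - np.abs(np.diag(Theta)).sum()
    return float(
        np.trace(S @ Theta) - logdet + lam * np.abs(Gamma3).sum() + rho * off
    )


def _soft(x: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def fista_gamma_step(
    Z: np.ndarray,
    Y: np.ndarray,
    Theta: np.ndarray,
    lam: float,
    n_unpenalized: int,
    B0: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 20000,
) -> np.ndarray:
    """Minimize (1/n) tr((Y-ZB)^T (Y-ZB) Theta) + lam ||B[c:]||_1 by FISTA."""
    n = Z.shape[0]
    c = n_unpenalized
    L = (
        2.0
        / n
        * np.linalg.eigvalsh(Z.T @ Z).max()
        * np.linalg.eigvalsh(Theta).max()
    )
    B = np.zeros((Z.shape[1], Y.shape[1])) if B0 is None else B0.copy()
    A = B.copy()
    t = 1.0
    f_prev = np.inf
    for _ in range(max_iter):
        grad = -2.0 / n * Z.T @ (Y - Z @ A) @ Theta
        B_new = A - grad / L
        B_new[c:] = _soft(B_new[c:], lam / L)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        A = B_new + (t - 1.0) / t_new * (B_new - B)
        step = np.abs(B_new - B).max()
        B, t = B_new, t_new
        R = Y - Z @ B
        f = float(np.trace(R.T @ R @ Theta) / n + lam * np.abs(B[c:]).sum())
        if f > f_prev:  # adaptive restart of the momentum
            A = B.copy()
            t = 1.0
        if step < tol and abs(f_prev - f) < tol * max(1.0, abs(f)):
            break
        f_prev = min(f, f_prev)
    return B


def admm_theta_step(
    S: np.ndarray,
    rho: float,
    mu: float = 1.0,
    tol: float = 1e-11,
    max_iter: int = 50000,
) -> np.ndarray:
    """Minimize tr(S Theta) - logdet Theta + rho ||Theta||_1,offdiag by ADMM.

    The Theta update is the closed-form eigenvalue shrinkage of the
    logdet proximal operator; the splitting variable absorbs the
    off-diagonal soft threshold. Returns the (exactly sparse) splitting
    variable at convergence.
    """
    q = S.shape[0]
    Zv = np.linalg.pinv(S + np.eye(q) * 1e-3)
    Lagr = np.zeros((q, q))
    off_mask = ~np.eye(q, dtype=bool)
    for _ in range(max_iter):
        A = mu * (Zv - Lagr) - S
        w, V = np.linalg.eigh((A + A.T) / 2.0)
        theta_w = (w + np.sqrt(w * w + 4.0 * mu)) / (2.0 * mu)
        Theta = (V * theta_w) @ V.T
        M = Theta + Lagr
        Z_new = M.copy()
        Z_new[off_mask] = _soft(M[off_mask], rho / mu)
        primal = np.abs(Theta - Z_new).max()
        dual = mu * np.abs(Z_new - Zv).max()
        Zv = Z_new
        Lagr = Lagr + Theta - Zv
        if primal < tol and dual < tol:
            break
    return (Zv + Zv.T) / 2.0


def ref_fit(
    Y: np.ndarray,
    W: np.ndarray,
    X: np.ndarray,
    lam: float,
    rho: float,
    tol: float = 1e-10,
    max_alternations: int = 500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Reference alternating solution; returns (Gamma_w, Gamma3, Theta, obj)."""
    Y, W, X = (np.asarray(a, dtype=float) for a in (Y, W, X))
    n, q = Y.shape
    c = W.shape[1]
    Z = np.hstack([W, X])
    B = np.zeros((Z.shape[1], q))
    B[:c], *_ = np.linalg.lstsq(W, Y, rcond=None)
    R = Y - Z @ B
    S = R.T @ R / n
    Theta = np.linalg.inv(S) if rho == 0 else admm_theta_step(S, rho)
    obj = ref_objective(Y, W, X, B[:c], B[c:].T, Theta, lam, rho)
    for _ in range(max_alternations):
        B = fista_gamma_step(Z, Y, Theta, lam, c, B0=B)
        R = Y - Z @ B
        S = R.T @ R / n
        Theta = np.linalg.inv(S) if rho == 0 else admm_theta_step(S, rho)
        new_obj = ref_objective(Y, W, X, B[:c], B[c:].T, Theta, lam, rho)
        if abs(obj - new_obj) < tol * max(1.0, abs(obj)):
            obj = new_obj
            break
        obj = new_obj
    return B[:c].copy(), B[c:].T.copy(), Theta, obj
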