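"""Regulator selection per module via the weighted cooperative Lasso.

For a module with member genes ``C`` the solver minimizes

    1/2 * sum_{j in C} 1/(n1 * sigma2_j) * ||Zt1[:, j] - Zr1 @ B[:, j]||^2
      + lam * sum_k w_k * (||B_+[k, :]||_2 + ||B_-[k, :]||_2)

where ``B_+``/``B_-`` are the positive/negative parts of each regulator row.
The penalty is a group penalty applied separately to the two sign parts of a
row: it produces row sparsity (regulator selection) while encouraging each
selected regulator to act with one sign across the whole module.

The problem is solved with over-relaxed ADMM: the quadratic loss block has a
closed-form solve (cached eigendecomposition of Zr1'Zr1), the penalty block is
the explicit proximal operator of the cooperative penalty (group
soft-thresholding of the positive and negative parts independently). The step
length rho is adapted by residual balancing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

_NONZERO_ROW_TOL = 1e-10


@dataclass
class ADMMConfig:
    rho: float = 1.0
    over_relaxation: float = 1.6
    eps_abs: float = 1e-10
    eps_rel: float = 1e-7
    max_iter: int = 5000
    adapt_every: int = 10
    balance_factor: float = 10.0


@dataclass
class SelectionResult:
    """Coop-Lasso coefficients and the regulator set they induce.

    ``coef`` is the full regulator x module-gene coefficient matrix (rows of
    excluded/deselected regulators are exactly zero), ``regulators`` the
    indices of nonzero rows and ``signs`` the per-regulator sign (sign of the
    row mean; exact zero ties resolve to +1).
    """

    coef: np.ndarray
    regulators: np.ndarray
    signs: np.ndarray
    converged: bool = True
    n_iter: int = 0
    objective: float = np.nan


def residual_variances(
    Zt1_module: np.ndarray, Zr1: np.ndarray, return_coef: bool = False
):
    """Plug-in residual variances of module genes regressed on all regulators.

    With ``n1 > p_r`` an unbiased OLS estimate is used,
    ``sigma2 = RSS / (n1 - p_r)``. Otherwise ridge regression with penalty
    equal to the smallest eigenvalue of ``Zr1'Zr1`` plus a fudge factor of
    1e-4 is used and the denominator is ``n1 - df_ridge`` with ``df_ridge``
    the trace of the ridge hat matrix. Variances are floored at 1e-12.
    """
    Y = np.atleast_2d(np.asarray(Zt1_module, dtype=float))
    if Y.shape[0] == 1 and Zr1.shape[0] != 1:
        Y = Y.T
    X = np.asarray(Zr1, dtype=float)
    n1, p_r = X.shape
    if n1 < 2:
        raise ValueError("need at least 2 training cells")

    if n1 > p_r:
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        df = float(p_r)
    else:
        G = X.T @ X
        eigvals = scipy.linalg.eigvalsh(G)
        pen = max(eigvals[0], 0.0) + 1e-4
        evals, evecs = scipy.linalg.eigh(G + pen * np.eye(p_r))
        B = evecs @ ((evecs.T @ (X.T @ Y)) / evals[:, None])
        hat_eigs = np.clip(eigvals, 0.0, None)
        df = float(np.sum(hat_eigs / (hat_eigs + pen)))

    rss = np.sum((Y - X @ B) ** 2, axis=0)
    denom = n1 - df
    if denom <= 0:
        raise ValueError("variance denominator n1 - df is not positive")
    sigma2 = rss / denom
    bad = sigma2 < 1e-12
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} numerically zero residual variance(s) floored at 1e-12",
            stacklevel=2,
        )
    sigma2 = np.maximum(sigma2, 1e-12)
    if return_coef:
        return sigma2, B
    return sigma2


def adaptive_weights(B_ols: np.ndarray, module_size: int) -> np.ndarray:
    """Adaptive-Lasso-style weights ``w_k = sqrt(|C| / ||B_ols[k, :]||_2)``.

    Rows with zero norm get weight +inf: such regulators carry no least-squares
    signal and are excluded from selection at any positive penalty.
    """
    if module_size < 1:
        raise ValueError("module_size must be >= 1")
    norms = np.linalg.norm(np.atleast_2d(B_ols), axis=1)
    w = np.full(norms.shape, np.inf)
    nz = norms > 0
    w[nz] = np.sqrt(module_size / norms[nz])
    return w


def coop_group_prox(V: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Proximal operator of the cooperative penalty, rowwise.

    Each row is split into its positive and negative parts; group
    soft-thresholding is applied to each part independently and the two
    results are summed.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    t = np.broadcast_to(np.asarray(thresholds, dtype=float), (V.shape[0],))
    Vp = np.clip(V, 0.0, None)
    Vn = np.clip(V, None, 0.0)
    out = np.zeros_like(V)
    for part in (Vp, Vn):
        norms = np.linalg.norm(part, axis=1)
        nz = norms > 0
        scale = np.zeros_like(norms)
        scale[nz] = np.maximum(0.0, 1.0 - t[nz] / norms[nz])
        out += part * scale[:, None]
    return out


def coop_objective(
    B: np.ndarray,
    Zt1_module: np.ndarray,
    Zr1: np.ndarray,
    sigma2: np.ndarray,
    weights: np.ndarray,
    lam: float,
) -> float:
    """Value of the weighted coop-Lasso objective at ``B`` (p_r x |C|)."""
    Y = np.asarray(Zt1_module, dtype=float)
    X = np.asarray(Zr1, dtype=float)
    n1 = X.shape[0]
    c = 1.0 / (n1 * np.asarray(sigma2, dtype=float))
    resid = Y - X @ B
    loss = 0.5 * float(np.sum(c * np.sum(resid**2, axis=0)))
    Bp = np.clip(B, 0.0, None)
    Bn = np.clip(B, None, 0.0)
    row_pen = np.linalg.norm(Bp, axis=1) + np.linalg.norm(Bn, axis=1)
    finite = np.isfinite(weights)
    if np.any(~finite & (row_pen > 0)):
        return np.inf
    pen = lam * float(np.sum(weights[finite] * row_pen[finite]))
    return loss + pen


def lambda_max(
    Zt1_module: np.ndarray, Zr1: np.ndarray, sigma2: np.ndarray, weights: np.ndarray
) -> float:
    """Smallest penalty for which the all-zero coefficient matrix is optimal.

    From the KKT condition at B = 0 the zero matrix is a minimizer iff for
    every regulator row of the (weighted) gradient both the positive and the
    negative part have 2-norm at most ``lam * w_k``.
    """
    Y = np.asarray(Zt1_module, dtype=float)
    X = np.asarray(Zr1, dtype=float)
    n1 = X.shape[0]
    c = 1.0 / (n1 * np.asarray(sigma2, dtype=float))
    G = X.T @ Y * c[None, :]  # negative gradient of the loss at B = 0
    Gp = np.clip(G, 0.0, None)
    Gn = np.clip(G, None, 0.0)
    row = np.maximum(np.linalg.norm(Gp, axis=1), np.linalg.norm(Gn, axis=1))
    finite = np.isfinite(weights)
    if not finite.any():
        return 0.0
    return float(np.max(row[finite] / weights[finite]))


def extract_regulator_set(B_CL: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nonzero rows of the coefficient matrix and their signs.

    A regulator is selected when any entry of its row exceeds the numerical
    zero threshold; its sign is the sign of the row mean (+1 on an exact tie).
    """
    B_CL = np.atleast_2d(np.asarray(B_CL, dtype=float))
    selected = np.flatnonzero(np.max(np.abs(B_CL), axis=1) > _NONZERO_ROW_TOL)
    means = B_CL[selected].mean(axis=1)
    signs = np.where(means < 0, -1, 1).astype(int)
    return selected, signs


def solve_coop_lasso(
    Zt1_module: np.ndarray,
    Zr1: np.ndarray,
    sigma2: np.ndarray,
    weights: np.ndarray,
    lam: float,
    admm: ADMMConfig | None = None,
    warm_start: np.ndarray | None = None,
) -> SelectionResult:
    """Solve the weighted coop-Lasso for one module with over-relaxed ADMM.

    Regulators with infinite weight are removed from the problem and their
    coefficient rows forced to zero. Returns the penalty-block iterate (exact
    zeros on deselected rows) together with the induced regulator set and
    signs.
    """
    if admm is None:
        admm = ADMMConfig()
    if lam < 0:
        raise ValueError("lam must be >= 0")
    Y = np.asarray(Zt1_module, dtype=float)
    X_full = np.asarray(Zr1, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n1, p_r = X_full.shape
    m = Y.shape[1]
    if sigma2.shape != (m,):
        raise ValueError("sigma2 must have one entry per module gene")
    if weights.shape != (p_r,):
        raise ValueError("weights must have one entry per regulator")

    active = np.isfinite(weights)
    X = X_full[:, active]
    w = weights[active]
    p = X.shape[1]
    B_full = np.zeros((p_r, m))
    if p == 0:
        return SelectionResult(B_full, np.empty(0, dtype=int), np.empty(0, dtype=int),
                               objective=coop_objective(B_full, Y, X_full, sigma2, weights, lam))

    c = 1.0 / (n1 * sigma2)
    G = X.T @ X
    evals, Q = scipy.linalg.eigh(G)
    evals = np.clip(evals, 0.0, None)
    XtYc = (X.T @ Y) * c[None, :]
    QtXtYc = Q.T @ XtYc

    rho = admm.rho
    alpha = admm.over_relaxation
    if warm_start is not None:
        Theta = np.asarray(warm_start, dtype=float)[active].copy()
    else:
        Theta = np.zeros((p, m))
    U = np.zeros((p, m))
    size = np.sqrt(p * m)

    converged = False
    it = 0
    for it in range(1, admm.max_iter + 1):
        rhs = QtXtYc + Q.T @ (rho * (Theta - U))
        denom = evals[:, None] * c[None, :] + rho
        B = Q @ (rhs / denom)

        B_hat = alpha * B + (1.0 - alpha) * Theta
        Theta_old = Theta
        Theta = coop_group_prox(B_hat + U, lam * w / rho)
        U = U + B_hat - Theta

        r_norm = np.linalg.norm(B - Theta)
        s_norm = rho * np.linalg.norm(Theta - Theta_old)
        eps_pri = admm.eps_abs * size + admm.eps_rel * max(
            np.linalg.norm(B), np.linalg.norm(Theta)
        )
        eps_dual = admm.eps_abs * size + admm.eps_rel * rho * np.linalg.norm(U)
        if r_norm <= eps_pri and s_norm <= eps_dual:
            converged = True
            break

        if it % admm.adapt_every == 0:
            if r_norm > admm.balance_factor * s_norm:
                rho *= 2.0
                U /= 2.0
            elif s_norm > admm.balance_factor * r_norm:
                rho /= 2.0
                U *= 2.0

    if not converged:
        warnings.warn(
            f"coop-Lasso ADMM did not converge in {admm.max_iter} iterations "
            f"(primal residual {r_norm:.2e}); returning best iterate",
            stacklevel=2,
        )

    B_full[active] = Theta
    regulators, signs = extract_regulator_set(B_full)
    obj = coop_objective(B_full, Y, X_full, sigma2, weights, lam)
    return SelectionResult(
        coef=B_full,
        regulators=regulators,
        signs=signs,
        converged=converged,
        n_iter=it,
        objective=obj,
    )
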