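"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths they are used to check: the convex
problems are re-solved through scipy's general-purpose L-BFGS-B optimizer on
the exact positive/negative-part split reformulation (B = P - N with
P, N >= 0, under which the cooperative penalty becomes a smooth-domain
function of P and N), and NNLS is re-solved by exhaustive enumeration of
active sets.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.optimize


def _split_objective_grad(z, shape, loss_fn, lam_w, eps):
    """Objective/gradient of loss(P - N) + smoothed cooperative penalty.

    The group norm ||x|| is replaced by sqrt(||x||^2 + eps^2) - eps, which is
    smooth, convex and within eps of the exact norm; eps = 0 recovers the
    exact objective with a subgradient (0 at zero groups).
    """
    p, m = shape
    P = z[: p * m].reshape(p, m)
    N = z[p * m:].reshape(p, m)
    B = P - N
    loss, G = loss_fn(B)
    pen = 0.0
    gP = G.copy()
    gN = -G
    for part, g in ((P, gP), (N, gN)):
        sq = np.sum(part**2, axis=1)
        smooth = np.sqrt(sq + eps**2)
        pen += float(np.sum(lam_w * (smooth - eps)))
        nz = smooth > 0
        g[nz] += (lam_w[nz] / smooth[nz])[:, None] * part[nz]
    return loss + pen, np.concatenate([gP.ravel(), gN.ravel()])


def coop_lasso_oracle(Y, X, sigma2, weights, lam, n_starts=3, seed=0):
    """Best objective value found by L-BFGS-B for the weighted coop-Lasso.

    Uses smoothing continuation (decreasing eps in a smoothed group norm,
    warm-started) followed by an exact-objective polish, from several starting
    points. Rows with infinite weight are excluded (their coefficients are
    zero in any finite-objective solution). Returns (objective, B).
    """
    Y = np.asarray(Y, float)
    X_full = np.asarray(X, float)
    n1 = X_full.shape[0]
    active = np.isfinite(weights)
    Xa = X_full[:, active]
    w = np.asarray(weights, float)[active]
    p, m = Xa.shape[1], Y.shape[1]
    c = 1.0 / (n1 * np.asarray(sigma2, float))

    def loss_fn(B):
        R = Xa @ B - Y
        loss = 0.5 * float(np.sum(c * np.sum(R**2, axis=0)))
        G = (Xa.T @ R) * c[None, :]
        return loss, G

    def exact_objective(B):
        R = Xa @ B - Y
        loss = 0.5 * float(np.sum(c * np.sum(R**2, axis=0)))
        Bp = np.clip(B, 0, None)
        Bn = np.clip(B, None, 0)
        return loss + float(
            np.sum(lam_w * (np.linalg.norm(Bp, axis=1) + np.linalg.norm(Bn, axis=1)))
        )

    lam_w = lam * w
    rng = np.random.default_rng(seed)
    B_ls, *_ = np.linalg.lstsq(Xa, Y, rcond=None) if p else (np.zeros((0, m)),)
    starts = [np.zeros((p, m)), B_ls]
    starts += [0.5 * rng.standard_normal((p, m)) for _ in range(n_starts - 1)]

    bounds = [(0, None)] * (2 * p * m)
    best_obj, best_B = np.inf, np.zeros((p, m))
    for B0 in starts:
        z = np.concatenate([np.clip(B0, 0, None).ravel(), np.clip(-B0, 0, None).ravel()])
        for eps in (1e-1, 1e-3, 1e-6, 0.0):
            res = scipy.optimize.minimize(
                _split_objective_grad,
                z,
                args=((p, m), loss_fn, lam_w, eps),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 20000, "maxfun": 50000, "ftol": 1e-16, "gtol": 1e-12},
            )
            z = res.x
        B = z[: p * m].reshape(p, m) - z[p * m:].reshape(p, m)
        # snap numerically dead groups to exact zero (can only lower the objective)
        for part_sign in (1, -1):
            part = np.clip(part_sign * B, 0, None)
            norms = np.linalg.norm(part, axis=1)
            for k in np.flatnonzero((norms > 0) & (norms < 1e-7)):
                B[k][part_sign * B[k] > 0] = 0.0
        obj = exact_objective(B)
        if obj < best_obj:
            best_obj, best_B = obj, B
    B_full = np.zeros((X_full.shape[1], m))
    B_full[active] = best_B
    return best_obj, B_full


def prox_objective(x, v, t):
    """0.5 ||x - v||^2 + t (||x_+|| + ||x_-||)."""
    xp = np.clip(x, 0, None)
    xn = np.clip(x, None, 0)
    return 0.5 * float(np.sum((x - v) ** 2)) + t * (
        float(np.linalg.norm(xp)) + float(np.linalg.norm(xn))
    )


def prox_oracle(v, t):
    """Numerical minimizer of the prox objective via the P/N split."""
    v = np.asarray(v, float)
    m = v.size

    def fun(z):
        P, N = z[:m], z[m:]
        x = P - N
        r = x - v
        pen = t * (np.linalg.norm(P) + np.linalg.norm(N))
        g = np.concatenate([r, -r])
        for off, part in ((0, P), (m, N)):
            nrm = np.linalg.norm(part)
            if nrm > 0:
                g[off : off + m] += t * part / nrm
        return 0.5 * float(r @ r) + pen, g

    z0 = np.concatenate([np.clip(v, 0, None), np.clip(-v, 0, None)])
    res = scipy.optimize.minimize(
        fun, z0, jac=True, method="L-BFGS-B", bounds=[(0, None)] * (2 * m),
        options={"maxiter": 10000, "ftol": 1e-18, "gtol": 1e-14},
    )
    return res.x[:m] - res.x[m:]


def nnls_oracle(X, y):
    """Exact NNLS by enumerating supports (use only for few columns).

    For every support S the unconstrained least-squares solution restricted to
    S is computed; feasible candidates (non-negative) are scored and the best
    kept. The NNLS optimum has a support whose restricted LS solution is
    non-negative, so the enumeration contains it.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    q = X.shape[1]
    best = (np.inf, np.zeros(q))
    for r in range(q + 1):
        for S in itertools.combinations(range(q), r):
            b = np.zeros(q)
            if S:
                sol, *_ = np.linalg.lstsq(X[:, S], y, rcond=None)
                if np.any(sol < 0):
                    continue
                b[list(S)] = sol
            rss = float(np.sum((y - X @ b) ** 2))
            if rss < best[0] - 1e-15:
                best = (rss, b)
    return best[1]


def ari_pair_counting(a, b):
    """Adjusted Rand index from the raw pair-counting definition."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    sum_ij = sum_a = sum_b = 0.0
    for la in np.unique(a):
        for lb in np.unique(b):
            nij = int(np.sum((a == la) & (b == lb)))
            sum_ij += nij * (nij - 1) / 2
    for la in np.unique(a):
        na = int(np.sum(a == la))
        sum_a += na * (na - 1) / 2
    for lb in np.unique(b):
        nb = int(np.sum(b == lb))
        sum_b += nb * (nb - 1) / 2
    total = n * (n - 1) / 2
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
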