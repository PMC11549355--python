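"""Module re-estimation and target-gene reallocation.

After regulator selection, each module's coefficients are re-estimated without
penalty for *all* target genes by sign-constrained least squares (NNLS on the
signed design), which removes the shrinkage bias and enforces the selected
signs. Cross-module predictive R-squared on the assessment split drives the
rag-bag filter (genes explained by no module are parked in a noise cluster)
and per-cell likelihood votes, optionally blended with a gene-gene prior,
reassign the remaining genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.special import logsumexp

RAGBAG = -1

_SIGMA2_FLOOR = 1e-12


@dataclass
class ModuleModel:
    """Regulatory program of one module, defined for all target genes.

    ``coef`` has shape ``(|regulators|, p_t)`` with non-negative entries;
    column j models target gene j from the signed regulator design. ``sigma2``
    is the per-gene residual variance. An empty regulator set marks the module
    as inactive.
    """

    regulators: np.ndarray
    signs: np.ndarray
    coef: np.ndarray
    sigma2: np.ndarray | None

    @property
    def active(self) -> bool:
        return self.regulators.size > 0

    def predict(self, Zr: np.ndarray) -> np.ndarray:
        """Predicted target expression (cells x p_t)."""
        if not self.active:
            return np.zeros((Zr.shape[0], self.coef.shape[1]))
        design = Zr[:, self.regulators] * self.signs[None, :]
        return design @ self.coef


@dataclass
class PriorSpec:
    """Gene-gene prior links for target genes.

    ``J`` is a 0/1 symmetric matrix over target genes with zero diagonal;
    ``mu`` in [0, 1] blends prior and likelihood during voting and ``alpha``
    is the small baseline added to prior fractions before normalization so
    that log-probabilities stay finite.
    """

    J: np.ndarray
    mu: float = 0.5
    alpha: float = 1e-6

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ValueError("J must be square")
        if np.any(np.diag(self.J) != 0):
            raise ValueError("J must have a zero diagonal")
        if not np.array_equal(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class Partition:
    """Hard module assignment per target gene; RAGBAG (-1) marks noise genes."""

    labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=RAGBAG) < RAGBAG or self.labels.max(initial=0) >= self.K:
            raise ValueError("labels must be in {-1, 0, ..., K-1}")

    @property
    def ragbag(self) -> np.ndarray:
        return self.labels == RAGBAG

    def members(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.labels == i)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels[self.labels >= 0], minlength=self.K)

    def __eq__(self, other) -> bool:  # ragbag membership counts as a difference
        return isinstance(other, Partition) and self.K == other.K and np.array_equal(
            self.labels, other.labels
        )


def nnls_fit(X: np.ndarray, Y: np.ndarray, warn_underdetermined: bool = True) -> np.ndarray:
    """Non-negative least squares with a matrix of responses.

    Minimizes ``||Y[:, j] - X b_j||_2`` subject to ``b_j >= 0`` for every
    response column. For tall designs the problem is reduced through a
    Cholesky factor of the Gram matrix so each per-column solve is tiny.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, q = X.shape
    m = Y.shape[1]
    if warn_underdetermined and q > n:
        warnings.warn(
            f"NNLS design has more columns ({q}) than rows ({n}); "
            "solution is not unique",
            stacklevel=2,
        )
    B = np.zeros((q, m))
    if q == 0 or m == 0:
        return B
    # reduce via Gram Cholesky when it is well posed; fall back to the raw design
    A, C = X, Y
    if n > q:
        G = X.T @ X
        try:
            R = scipy.linalg.cholesky(G + 1e-12 * np.trace(G) / q * np.eye(q), lower=False)
            A = R
            C = scipy.linalg.solve_triangular(R.T, X.T @ Y, lower=True)
        except scipy.linalg.LinAlgError:
            pass
    for j in range(m):
        if not np.any(C[:, j]):
            continue
        B[:, j], _ = scipy.optimize.nnls(A, C[:, j])
    return B


def reestimate_module_models(
    Zt1: np.ndarray,
    Zr1: np.ndarray,
    selections: list[tuple[np.ndarray, np.ndarray]],
) -> list[ModuleModel]:
    """Unpenalized sign-constrained re-fit of every module for all targets.

    ``selections`` holds one ``(regulator_indices, signs)`` pair per module.
    Residual variances use the unbiased denominator ``n1 - |R_i|`` and are
    floored at 1e-12. Modules with an empty regulator set are inactive.
    """
    Zt1 = np.asarray(Zt1, dtype=float)
    Zr1 = np.asarray(Zr1, dtype=float)
    n1, p_t = Zt1.shape
    models = []
    for regs, signs in selections:
        regs = np.asarray(regs, dtype=int)
        signs = np.asarray(signs, dtype=int)
        if regs.size == 0:
            models.append(ModuleModel(regs, signs, np.zeros((0, p_t)), None))
            continue
        if n1 <= regs.size:
            raise ValueError(
                f"variance denominator n1 - |R_i| <= 0 (n1={n1}, |R_i|={regs.size})"
            )
        design = Zr1[:, regs] * signs[None, :]
        B = nnls_fit(design, Zt1)
        rss = np.sum((Zt1 - design @ B) ** 2, axis=0)
        sigma2 = np.maximum(rss / (n1 - regs.size), _SIGMA2_FLOOR)
        models.append(ModuleModel(regs, signs, B, sigma2))
    return models


def cross_module_r2(
    Zt2: np.ndarray, Zr2: np.ndarray, models: list[ModuleModel]
) -> np.ndarray:
    """Predictive R-squared of every target gene under every module's program.

    Computed on the assessment split with the total sum of squares taken about
    the assessment-split gene mean. Values can be negative; inactive modules
    and constant genes yield -inf.
    """
    Zt2 = np.asarray(Zt2, dtype=float)
    Zr2 = np.asarray(Zr2, dtype=float)
    n2, p_t = Zt2.shape
    tss = np.sum((Zt2 - Zt2.mean(axis=0)) ** 2, axis=0)
    const = tss == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant assessment-split gene(s); R^2 set to -inf",
            stacklevel=2,
        )
    r2 = np.full((len(models), p_t), -np.inf)
    for i, model in enumerate(models):
        if not model.active:
            continue
        rss = np.sum((Zt2 - model.predict(Zr2)) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = 1.0 - rss / tss
        vals[const] = -np.inf
        r2[i] = vals
    return r2


def ragbag_filter(r2: np.ndarray, tau: float) -> np.ndarray:
    """Flag genes whose best cross-module R-squared falls below tau."""
    if not np.isfinite(tau) and tau > 0:
        raise ValueError("tau must be finite or -inf")
    return np.max(r2, axis=0) < tau


def prior_cluster_probabilities(
    prior: PriorSpec, labels: np.ndarray, gene: int, K: int
) -> np.ndarray:
    """Prior probability of one gene belonging to each module.

    Fractions ``f_i = J[gene, :] @ 1{labels == i} / |module i|`` (0 for empty
    modules) are shifted by the baseline alpha and normalized across modules.
    The result is strictly positive and sums to one.
    """
    labels = np.asarray(labels)
    row = prior.J[gene]
    f = np.zeros(K)
    for i in range(K):
        members = labels == i
        size = int(members.sum())
        if size > 0:
            f[i] = row[members].sum() / size
    f = f + prior.alpha
    return f / f.sum()


def _log_likelihoods(
    Zt2: np.ndarray, Zr2: np.ndarray, models: list[ModuleModel]
) -> np.ndarray:
    """Per-observation Gaussian log-likelihood, shape (K, n2, p_t).

    Inactive modules get -inf everywhere.
    """
    n2, p_t = Zt2.shape
    K = len(models)
    ll = np.full((K, n2, p_t), -np.inf)
    for i, model in enumerate(models):
        if not model.active:
            continue
        resid = Zt2 - model.predict(Zr2)
        s2 = model.sigma2[None, :]
        ll[i] = -0.5 * np.log(2 * np.pi * s2) - resid**2 / (2 * s2)
    return ll


def allocate_targets(
    Zt2: np.ndarray,
    Zr2: np.ndarray,
    models: list[ModuleModel],
    ragbag: np.ndarray,
    rng: np.random.Generator,
    prior: PriorSpec | None = None,
    labels_prev: np.ndarray | None = None,
) -> Partition:
    """Reassign every non-ragbag gene by majority vote over assessment cells.

    Each cell votes for the module maximizing
    ``(1 - mu) * log L + mu * log p`` where ``L`` is the per-cell likelihood
    normalized across modules and ``p`` the prior module probability of the
    gene. Genes are processed in a seeded random order; prior fractions are
    recomputed per gene from the partially updated partition. Vote ties and
    per-cell argmax ties break toward the lowest module index.
    """
    Zt2 = np.asarray(Zt2, dtype=float)
    Zr2 = np.asarray(Zr2, dtype=float)
    n2, p_t = Zt2.shape
    K = len(models)
    ragbag = np.asarray(ragbag, dtype=bool)
    if not any(m.active for m in models) and not ragbag.all():
        raise ValueError("all modules are empty; nothing to allocate")

    mu = prior.mu if prior is not None else 0.0
    active = np.array([m.active for m in models])
    if not active.any():
        return Partition(labels=np.full(p_t, RAGBAG, dtype=int), K=K)
    ll = _log_likelihoods(Zt2, Zr2, models)
    # normalize across modules per cell (log-sum-exp over active modules)
    norm = logsumexp(ll[active], axis=0)
    log_L = ll - norm[None, :, :]

    labels = np.full(p_t, RAGBAG, dtype=int)
    working = (
        np.asarray(labels_prev, dtype=int).copy()
        if labels_prev is not None
        else np.full(p_t, RAGBAG, dtype=int)
    )
    order = rng.permutation(p_t)
    for j in order:
        if ragbag[j]:
            working[j] = RAGBAG
            continue
        score = log_L[:, :, j].copy()  # K x n2
        if prior is not None and mu > 0:
            p_j = prior_cluster_probabilities(prior, working, j, K)
            score = (1.0 - mu) * score + mu * np.log(p_j)[:, None]
        else:
            score = (1.0 - mu) * score
        score[~active] = -np.inf
        votes = np.argmax(score, axis=0)  # lowest index wins argmax ties
        counts = np.bincount(votes, minlength=K)
        counts[~active] = 0
        winner = int(np.argmax(counts))  # lowest index wins vote ties
        labels[j] = winner
        working[j] = winner
    return Partition(labels=labels, K=K)
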