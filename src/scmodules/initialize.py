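"""Initial partition of target genes from the target-regulator cross-correlation.

Each target gene is represented by its vector of Pearson correlations with all
regulators on the training split; k-means++ with restarts clusters these
profiles. Because the representation is built from regulator correlations, the
initialization is not equivalent to clustering raw target expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans


@dataclass
class InitialPartition:
    labels: np.ndarray  # module index per target gene, 0-based
    K: int
    restarts: int
    seed: int
    wcss: float = np.nan

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.K:
            raise ValueError("labels out of range for K modules")


def cross_correlation(Zt1: np.ndarray, Zr1: np.ndarray) -> np.ndarray:
    """Pearson correlation of every target (rows) with every regulator (cols).

    Zero-variance columns yield correlation 0 with a warning (such genes carry
    no linear signal and will be weakly clustered).
    """
    Zt1 = np.asarray(Zt1, dtype=float)
    Zr1 = np.asarray(Zr1, dtype=float)
    if Zt1.shape[0] != Zr1.shape[0]:
        raise ValueError("Zt1 and Zr1 must share the cell dimension")
    n = Zt1.shape[0]

    def standardize(M):
        mu = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance column(s); correlations set to 0",
                stacklevel=3,
            )
        sd_safe = np.where(zero, 1.0, sd)
        S = (M - mu) / sd_safe
        S[:, zero] = 0.0
        return S

    St = standardize(Zt1)
    Sr = standardize(Zr1)
    corr = St.T @ Sr / (n - 1)
    return np.clip(corr, -1.0, 1.0)


def initial_partition(
    corr: np.ndarray, K: int, restarts: int = 10, seed: int = 0
) -> InitialPartition:
    """Cluster correlation profiles into K groups with k-means++ restarts.

    The best of ``restarts`` runs by within-cluster sum of squares is kept;
    the result is deterministic given the seed.
    """
    corr = np.asarray(corr, dtype=float)
    p_t = corr.shape[0]
    if K > p_t:
        raise ValueError(f"K={K} exceeds the number of target genes ({p_t})")
    km = KMeans(
        n_clusters=K,
        init="k-means++",
        n_init=restarts,
        max_iter=100,
        tol=1e-8,
        random_state=seed,
    )
    labels = km.fit_predict(corr)
    return InitialPartition(labels=labels, K=K, restarts=restarts, seed=seed, wcss=float(km.inertia_))
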