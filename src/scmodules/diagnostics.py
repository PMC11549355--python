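"""Model-selection scores, the regulatory table, and external validation.

Internal measures (computed on the assessment split):

* predictive R-squared per module — how well the module's regulatory program
  predicts its member genes out of split;
* regulator importance — relative loss of module R-squared when one regulator
  is dropped and the module re-fit, ``I = 1 - R2_without / R2_full`` clipped
  to [0, 1];
* per-gene silhouette — contrast between a gene's R-squared in its own module
  and its best R-squared elsewhere.

External measures compare an estimated partition and regulator sets against a
known ground truth (adjusted Rand index, cluster homogeneity, per-gene
regulator TPR/FPR).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .allocate import ModuleModel, Partition, nnls_fit
from .driver import FitResult
from .initialize import cross_correlation
from .io import DataSplits

REGULATORY_TABLE_GATE = 0.025


def module_predictive_r2(
    fit: FitResult, splits: DataSplits, config_index: int = -1
) -> np.ndarray:
    """Out-of-split R-squared per module over its member genes.

    ``1 - RSS_i / TSS_i`` with both sums pooled over the module's members on
    the assessment split. Empty or inactive modules are NaN.
    """
    conf = fit.configurations[config_index]
    return _module_r2(conf.partition, conf.models, splits)


def _module_r2(
    partition: Partition, models: list[ModuleModel], splits: DataSplits
) -> np.ndarray:
    Zt2, Zr2 = splits.Zt2, splits.Zr2
    mean2 = Zt2.mean(axis=0)
    out = np.full(partition.K, np.nan)
    for i, model in enumerate(models):
        members = partition.members(i)
        if members.size == 0 or not model.active:
            continue
        pred = model.predict(Zr2)[:, members]
        rss = float(np.sum((Zt2[:, members] - pred) ** 2))
        tss = float(np.sum((Zt2[:, members] - mean2[members]) ** 2))
        if tss == 0:
            continue
        out[i] = 1.0 - rss / tss
    return out


def regulator_importance(
    fit: FitResult, splits: DataSplits, config_index: int = -1
) -> pd.DataFrame:
    """Importance of each selected regulator in each module.

    For regulator k in module i the module is re-fit by NNLS on the training
    split without k and scored on the assessment split; importance is
    ``1 - R2_{i,-k} / R2_i`` clipped to [0, 1]. Modules whose full-model
    R-squared is not positive give missing (NaN) importances.
    """
    conf = fit.configurations[config_index]
    partition, models = conf.partition, conf.models
    full_r2 = _module_r2(partition, models, splits)
    rows = []
    for i, model in enumerate(models):
        members = partition.members(i)
        if not model.active or members.size == 0:
            continue
        for pos, k in enumerate(model.regulators):
            if full_r2[i] <= 0 or not np.isfinite(full_r2[i]):
                rows.append((i, int(k), np.nan))
                continue
            keep = np.delete(np.arange(model.regulators.size), pos)
            reduced = _reduced_module_r2(
                splits, members, model.regulators[keep], model.signs[keep]
            )
            imp = float(np.clip(1.0 - reduced / full_r2[i], 0.0, 1.0))
            rows.append((i, int(k), imp))
    return pd.DataFrame(rows, columns=["module", "regulator", "importance"])


def _reduced_module_r2(
    splits: DataSplits, members: np.ndarray, regs: np.ndarray, signs: np.ndarray
) -> float:
    """R-squared of a module refit with a reduced regulator set.

    An empty reduced set is the null model (prediction identically zero on the
    training-centered scale).
    """
    Zt2m = splits.Zt2[:, members]
    tss = float(np.sum((Zt2m - Zt2m.mean(axis=0)) ** 2))
    if tss == 0:
        return np.nan
    if regs.size == 0:
        pred = np.zeros_like(Zt2m)
    else:
        design1 = splits.Zr1[:, regs] * signs[None, :]
        B = nnls_fit(design1, splits.Zt1[:, members])
        design2 = splits.Zr2[:, regs] * signs[None, :]
        pred = design2 @ B
    rss = float(np.sum((Zt2m - pred) ** 2))
    return 1.0 - rss / tss


def silhouette_scores(r2: np.ndarray, partition: Partition) -> np.ndarray:
    """Per-gene silhouette from the cross-module R-squared matrix.

    For gene j in module i: ``a = R2[i, j]``, ``b = max(0, max_{c != i}
    R2[c, j])`` and ``S = (a - b) / max(a, b)``. Ragbag/unassigned genes are
    NaN; a degenerate ``max(a, b) <= 0`` gives 0 (logged).
    """
    r2 = np.asarray(r2, dtype=float)
    K, p_t = r2.shape
    scores = np.full(p_t, np.nan)
    degenerate = 0
    for j in range(p_t):
        i = partition.labels[j]
        if i < 0:
            continue
        a = r2[i, j]
        others = np.delete(r2[:, j], i)
        b = max(0.0, float(np.max(others))) if others.size else 0.0
        denom = max(a, b)
        if denom <= 0 or not np.isfinite(denom):
            scores[j] = 0.0
            degenerate += 1
        else:
            scores[j] = (a - b) / denom
    if degenerate:
        warnings.warn(
            f"{degenerate} gene(s) with degenerate silhouette (a, b <= 0) set to 0",
            stacklevel=2,
        )
    return scores


def build_regulatory_table(
    fit: FitResult, splits: DataSplits, config_index: int = -1
) -> np.ndarray:
    """Regulator x module table of mean coop-Lasso coefficients.

    Entry (k, i) is the mean over module i's member genes of the final-cycle
    coop-Lasso coefficient of regulator k, kept only when the median training
    correlation between regulator k and the module's members exceeds 0.025;
    otherwise 0.
    """
    conf = fit.configurations[config_index]
    partition = conf.partition
    p_r = splits.n_regulators
    corr = cross_correlation(splits.Zt1, splits.Zr1)  # p_t x p_r
    table = np.zeros((p_r, partition.K))
    for i, sel in enumerate(conf.selections):
        members = partition.members(i)
        if sel is None or members.size == 0:
            continue
        med = np.median(corr[members], axis=0)  # per regulator
        mean_coef = sel.coef.mean(axis=1)
        table[:, i] = np.where(med > REGULATORY_TABLE_GATE, mean_coef, 0.0)
    return table


def adjusted_rand_index(truth: np.ndarray, estimate: np.ndarray) -> float:
    """Adjusted Rand index between two label vectors.

    The rag bag (-1) is treated as a cluster label of its own.
    """
    truth = np.asarray(truth)
    estimate = np.asarray(estimate)
    if truth.shape != estimate.shape:
        raise ValueError("partitions must cover the same genes")
    return float(adjusted_rand_score(truth, estimate))


def cluster_homogeneity(truth: np.ndarray, estimate: np.ndarray) -> float:
    """Average over ground-truth clusters of the largest fraction of their
    genes landing in a single estimated cluster.

    Insensitive to cluster splitting in the estimate (a single giant estimated
    cluster scores 1), hence reported alongside the adjusted Rand index.
    """
    truth = np.asarray(truth)
    estimate = np.asarray(estimate)
    if truth.shape != estimate.shape:
        raise ValueError("partitions must cover the same genes")
    fracs = []
    for lab in np.unique(truth):
        members = estimate[truth == lab]
        counts = pd.Series(members).value_counts()
        fracs.append(counts.iloc[0] / members.size)
    return float(np.mean(fracs))


def regulator_selection_rates(
    truth_links: list[set[int]], est_links: list[set[int]], n_regulators: int
) -> tuple[float, float]:
    """Per-gene regulator true/false positive rates, averaged over genes.

    For each target gene the estimated regulator set (the program of its
    assigned module; empty for rag-bag genes) is compared against the true
    set. TPR is undefined for genes with an empty truth set, which are
    excluded from the TPR average; FPR uses the complement of the truth set as
    denominator.
    """
    if len(truth_links) != len(est_links):
        raise ValueError("truth and estimate must cover the same genes")
    tprs, fprs = [], []
    for truth, est in zip(truth_links, est_links):
        if truth:
            tprs.append(len(truth & est) / len(truth))
        n_neg = n_regulators - len(truth)
        if n_neg > 0:
            fprs.append(len(est - truth) / n_neg)
    tpr = float(np.mean(tprs)) if tprs else np.nan
    fpr = float(np.mean(fprs)) if fprs else np.nan
    return tpr, fpr
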