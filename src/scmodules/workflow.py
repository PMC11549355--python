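"""End-to-end drivers: grid fits with artifacts, and simulation studies.

These functions tie the stages together the way a user script would: split
the data once, initialize once per K, fit every (K, penalty) grid cell,
compute diagnostics and write plain-text artifacts plus a summary table that
supports penalty/module-count selection (look for the elbow in module
R-squared and importance along the penalty path; prefer the K with the best
mean silhouette). One master seed is fanned out to per-stage streams.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .allocate import PriorSpec
from .diagnostics import (
    adjusted_rand_index,
    build_regulatory_table,
    cluster_homogeneity,
    module_predictive_r2,
    regulator_importance,
    regulator_selection_rates,
    silhouette_scores,
)
from .driver import FitConfig, FitResult, fit
from .initialize import cross_correlation, initial_partition
from .io import DataSplits, ExpressionBundle, make_data_splits
from .simulate import GroundTruth, SimulationConfig, simulate_bundle


def _stage_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def fit_grid(
    splits: DataSplits,
    K_grid: list[int],
    penalty_grid: list[float],
    noise_threshold: float = 0.05,
    mu: float = 0.0,
    prior: PriorSpec | None = None,
    seed: int = 0,
    restarts: int = 10,
    max_cycles: int = 50,
) -> dict[tuple[int, float], FitResult]:
    """Fit every (K, penalty) grid cell; one initialization per K."""
    if not K_grid or not penalty_grid:
        raise ValueError("K and penalty grids must be non-empty")
    init_seed, fit_seed = _stage_seeds(seed, 2)
    corr = cross_correlation(splits.Zt1, splits.Zr1)
    results: dict[tuple[int, float], FitResult] = {}
    for K in K_grid:
        init = initial_partition(corr, K, restarts=restarts, seed=init_seed)
        for lam in penalty_grid:
            config = FitConfig(
                n_modules=K,
                penalty=lam,
                noise_threshold=noise_threshold,
                mu=mu,
                max_cycles=max_cycles,
                seed=fit_seed,
            )
            results[(K, lam)] = fit(splits, init, config, prior=prior)
    return results


def summarize_fits(
    fits: dict[tuple[int, float], FitResult], splits: DataSplits
) -> pd.DataFrame:
    """Selection-guidance summary: one row per grid cell."""
    rows = []
    for (K, lam), res in fits.items():
        part = res.partition
        sizes = part.sizes()
        n_nonempty = int(np.sum(sizes > 0))
        mod_r2 = module_predictive_r2(res, splits)
        imp = regulator_importance(res, splits)["importance"]
        sil = silhouette_scores(res.r2, part)
        n_regs = int(sum(m.regulators.size for m in res.models))
        rows.append(
            dict(
                K=K,
                penalty=lam,
                n_modules=n_nonempty,
                n_selected_regulators=n_regs,
                mean_module_r2=float(np.nanmean(mod_r2)) if np.any(np.isfinite(mod_r2)) else np.nan,
                median_module_r2=float(np.nanmedian(mod_r2)) if np.any(np.isfinite(mod_r2)) else np.nan,
                mean_importance=float(imp.mean()) if len(imp) else np.nan,
                median_importance=float(imp.median()) if len(imp) else np.nan,
                mean_silhouette=float(np.nanmean(sil)) if np.any(np.isfinite(sil)) else np.nan,
                n_ragbag=int(part.ragbag.sum()),
                converged=res.converged,
                cycle_length=res.cycle_length,
            )
        )
    return pd.DataFrame(rows).sort_values(["K", "penalty"]).reset_index(drop=True)


def write_fit_artifacts(
    res: FitResult, splits: DataSplits, out_dir, config_index: int = -1
) -> None:
    """Write modules.tsv, regulators.tsv, regtable.tsv and diagnostics.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conf = res.configurations[config_index]
    part = conf.partition

    pd.DataFrame(
        {
            "gene": splits.target_names,
            "module": part.labels,
            "ragbag": part.ragbag,
        }
    ).to_csv(out / "modules.tsv", sep="\t", index=False)

    reg_rows = []
    for i, model in enumerate(conf.models):
        for pos, k in enumerate(model.regulators):
            reg_rows.append(
                dict(
                    module=i,
                    regulator=splits.regulator_names[int(k)],
                    sign=int(model.signs[pos]),
                    mean_coef=float(model.coef[pos].mean()),
                )
            )
    pd.DataFrame(
        reg_rows, columns=["module", "regulator", "sign", "mean_coef"]
    ).to_csv(out / "regulators.tsv", sep="\t", index=False)

    table = build_regulatory_table(res, splits, config_index)
    pd.DataFrame(
        table,
        index=splits.regulator_names,
        columns=[f"module{i}" for i in range(part.K)],
    ).to_csv(out / "regtable.tsv", sep="\t", float_format="%.10g")

    mod_r2 = module_predictive_r2(res, splits, config_index)
    sil = silhouette_scores(conf.r2, part)
    meta = dict(
        K=res.config.n_modules,
        penalty=res.config.penalty,
        noise_threshold=res.config.noise_threshold,
        mu=res.config.mu,
        seed=res.config.seed,
        split_seed=splits.seed,
        split_fraction=splits.split_fraction,
        converged=res.converged,
        cycle_length=res.cycle_length,
        n_cycles=res.n_cycles,
        module_r2=[None if not np.isfinite(v) else float(v) for v in mod_r2],
        mean_silhouette=(
            float(np.nanmean(sil)) if np.any(np.isfinite(sil)) else None
        ),
        n_ragbag=int(part.ragbag.sum()),
    )
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def run_fit_grid(
    bundle: ExpressionBundle,
    K_grid: list[int],
    penalty_grid: list[float],
    out_dir=None,
    split_fraction: float = 0.5,
    noise_threshold: float = 0.05,
    mu: float = 0.0,
    prior: PriorSpec | None = None,
    seed: int = 0,
    center_within_strata: bool = False,
) -> tuple[dict[tuple[int, float], FitResult], pd.DataFrame, DataSplits]:
    """Split, fit the full grid, summarize and (optionally) write artifacts."""
    split_seed, grid_seed = _stage_seeds(seed, 2)
    splits = make_data_splits(
        bundle, fraction=split_fraction, center_within_strata=center_within_strata,
        seed=split_seed,
    )
    fits = fit_grid(
        splits, K_grid, penalty_grid, noise_threshold=noise_threshold, mu=mu,
        prior=prior, seed=grid_seed,
    )
    summary = summarize_fits(fits, splits)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (K, lam), res in fits.items():
            write_fit_artifacts(res, splits, out / f"K{K}_lam{lam:g}")
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return fits, summary, splits


def evaluate_against_truth(
    res: FitResult, splits: DataSplits, truth: GroundTruth, config_index: int = -1
) -> dict[str, float]:
    """External validation of one fit against the planted structure."""
    conf = res.configurations[config_index]
    part = conf.partition
    est_sets = []
    for lab in part.labels:
        if lab < 0:
            est_sets.append(set())
        else:
            est_sets.append({int(k) for k in conf.models[lab].regulators})
    tpr, fpr = regulator_selection_rates(
        [set(s) for s in truth.gene_regulator_sets()], est_sets, splits.n_regulators
    )
    sil = silhouette_scores(conf.r2, part)
    return dict(
        ari=adjusted_rand_index(truth.target_labels, part.labels),
        homogeneity=cluster_homogeneity(truth.target_labels, part.labels),
        tpr=tpr,
        fpr=fpr,
        mean_silhouette=float(np.nanmean(sil)) if np.any(np.isfinite(sil)) else np.nan,
        n_modules=int(np.sum(part.sizes() > 0)),
        n_ragbag=int(part.ragbag.sum()),
    )


def run_simulation_study(
    sim_config: SimulationConfig,
    K_grid: list[int],
    penalty_grid: list[float],
    seeds: list[int],
    noise_threshold: float = 0.05,
    mu: float = 0.0,
    use_truth_prior: bool = False,
) -> pd.DataFrame:
    """Simulate, fit the grid, and score against truth; one row per cell.

    With ``use_truth_prior`` a prior matrix encoding ground-truth
    co-membership of target genes is supplied to the fit (used to study the
    effect of the prior strength ``mu``).
    """
    rows = []
    for seed in seeds:
        cfg = SimulationConfig(**{**asdict(sim_config), "seed": seed})
        bundle, truth = simulate_bundle(cfg)
        prior = None
        if use_truth_prior:
            prior = truth_prior(truth)
        split_seed, grid_seed = _stage_seeds(seed, 2)
        splits = make_data_splits(bundle, seed=split_seed)
        fits = fit_grid(
            splits, K_grid, penalty_grid, noise_threshold=noise_threshold,
            mu=mu, prior=prior, seed=grid_seed,
        )
        for (K, lam), res in fits.items():
            metrics = evaluate_against_truth(res, splits, truth)
            rows.append(dict(seed=seed, K=K, penalty=lam, **metrics))
    return pd.DataFrame(rows)


def truth_prior(truth: GroundTruth, alpha: float = 1e-6) -> PriorSpec:
    """Prior link matrix marking true co-membership of target genes."""
    labels = truth.target_labels
    same = (labels[:, None] == labels[None, :]) & (labels[:, None] >= 0)
    J = same.astype(float)
    np.fill_diagonal(J, 0.0)
    return PriorSpec(J=J, mu=0.5, alpha=alpha)
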