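"""Orchestration of the alternating fit.

Each cycle runs Step 1 (regulator selection per non-empty module on the
training split) and Step 2 (re-estimation and reallocation against the
assessment split). A history of partitions is kept; the algorithm stops when
the current partition equals any earlier one. A repeat at distance one is
convergence; a longer loop is an unstable limit cycle and every configuration
inside the loop is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .allocate import (
    RAGBAG,
    ModuleModel,
    Partition,
    PriorSpec,
    allocate_targets,
    cross_module_r2,
    ragbag_filter,
    reestimate_module_models,
)
from .coop_lasso import (
    ADMMConfig,
    SelectionResult,
    adaptive_weights,
    residual_variances,
    solve_coop_lasso,
)
from .initialize import InitialPartition
from .io import DataSplits


@dataclass
class FitConfig:
    """Tuning parameters of one fit.

    ``n_modules`` is the initial module count K, ``penalty`` the coop-Lasso
    penalty, ``noise_threshold`` the rag-bag cutoff tau on the best
    cross-module predictive R-squared, ``mu`` the prior strength, and
    ``min_module_size`` the smallest module kept alive; smaller modules are
    released for redistribution in the next cycle. The special value "auto"
    uses twice the module's selected-regulator count as the floor — note that
    at very small penalties this can release healthy modules wholesale, so the
    default is a plain floor of 2.
    """

    n_modules: int
    penalty: float = 0.1
    noise_threshold: float = 0.05
    mu: float = 0.0
    min_module_size: int | str = 2
    max_cycles: int = 50
    seed: int = 0
    admm: ADMMConfig = field(default_factory=ADMMConfig)

    def __post_init__(self) -> None:
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


@dataclass
class Configuration:
    """One partition together with everything estimated from it."""

    partition: Partition
    selections: list[SelectionResult | None]
    models: list[ModuleModel]
    r2: np.ndarray  # K x p_t cross-module predictive R^2


@dataclass
class FitResult:
    """Outcome of the alternating fit.

    ``configurations`` holds one entry when converged, or every configuration
    in the terminal loop (oldest first) when a limit cycle of length > 1 was
    found. ``cycle_length`` is 1 on convergence, the loop length on a limit
    cycle and 0 when the cycle budget ran out.
    """

    configurations: list[Configuration]
    history: list[Partition]
    converged: bool
    cycle_length: int
    n_cycles: int
    config: FitConfig

    @property
    def partition(self) -> Partition:
        return self.configurations[-1].partition

    @property
    def models(self) -> list[ModuleModel]:
        return self.configurations[-1].models

    @property
    def selections(self) -> list[SelectionResult | None]:
        return self.configurations[-1].selections

    @property
    def r2(self) -> np.ndarray:
        return self.configurations[-1].r2


def detect_cycle(history: list[Partition], current: Partition) -> tuple[bool, int]:
    """Find the most recent earlier occurrence of ``current``.

    Returns ``(True, loop_length)`` with loop length measured from the most
    recent match, or ``(False, 0)``.
    """
    for back, past in enumerate(reversed(history), start=1):
        if past == current:
            return True, back
    return False, 0


def _min_size(config: FitConfig, n_regs: int) -> int:
    if config.min_module_size == "auto":
        return max(2 * n_regs, 1)
    return int(config.min_module_size)


def _step1(splits: DataSplits, partition: Partition, config: FitConfig,
           warm: list[tuple[np.ndarray, np.ndarray] | None]) -> list[SelectionResult | None]:
    """Regulator selection for every non-empty module.

    ``warm`` carries (members, coefficients) from the previous cycle; the
    warm start is only reused when the module's member set is unchanged.
    """
    selections: list[SelectionResult | None] = []
    for i in range(partition.K):
        members = partition.members(i)
        if members.size == 0:
            selections.append(None)
            continue
        Y = splits.Zt1[:, members]
        sigma2, B_ols = residual_variances(Y, splits.Zr1, return_coef=True)
        w = adaptive_weights(B_ols, members.size)
        warm_coef = None
        if warm[i] is not None and np.array_equal(warm[i][0], members):
            warm_coef = warm[i][1]
        sel = solve_coop_lasso(
            Y, splits.Zr1, sigma2, w, config.penalty, admm=config.admm,
            warm_start=warm_coef,
        )
        selections.append(sel)
    return selections


def fit(
    splits: DataSplits,
    init: InitialPartition,
    config: FitConfig,
    prior: PriorSpec | None = None,
) -> FitResult:
    """Alternate regulator selection and gene reallocation until a repeat.

    Deterministic given (splits, init, config, prior). On a limit cycle of
    length L > 1 all L configurations are returned with ``converged=False``;
    if ``max_cycles`` is exhausted without a repeat, the last configuration is
    returned with ``cycle_length=0`` and a warning.
    """
    if init.K != config.n_modules:
        raise ValueError("initial partition K does not match config.n_modules")
    if prior is not None:
        prior = PriorSpec(J=prior.J, mu=config.mu, alpha=prior.alpha)
        if prior.J.shape[0] != splits.n_targets:
            raise ValueError("prior matrix J must be p_t x p_t over target genes")
    elif config.mu > 0:
        warnings.warn("mu > 0 has no effect without a prior matrix", stacklevel=2)

    if splits.n1 <= splits.n_regulators:
        warnings.warn(
            f"n1 ({splits.n1}) <= p_r ({splits.n_regulators}); unbiased variance "
            "estimation is infeasible and ridge fallbacks will be used",
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    K = config.n_modules
    partition = Partition(labels=init.labels.copy(), K=K)
    history: list[Partition] = [partition]
    records: list[Configuration] = []
    warm: list[tuple[np.ndarray, np.ndarray] | None] = [None] * K

    converged = False
    cycle_length = 0
    for cycle in range(1, config.max_cycles + 1):
        selections = _step1(splits, partition, config, warm)
        pairs = []
        for i, sel in enumerate(selections):
            if sel is None or sel.regulators.size == 0:
                pairs.append((np.empty(0, dtype=int), np.empty(0, dtype=int)))
                warm[i] = None
            else:
                pairs.append((sel.regulators, sel.signs))
                warm[i] = (partition.members(i), sel.coef)
        models = reestimate_module_models(splits.Zt1, splits.Zr1, pairs)
        for model in models:
            if model.active and model.regulators.size >= splits.n1:
                warnings.warn(
                    "a module selected at least n1 regulators; decrease the penalty "
                    "path or increase the training split",
                    stacklevel=2,
                )
        r2 = cross_module_r2(splits.Zt2, splits.Zr2, models)
        ragbag = ragbag_filter(r2, config.noise_threshold)
        new_partition = allocate_targets(
            splits.Zt2,
            splits.Zr2,
            models,
            ragbag,
            rng,
            prior=prior,
            labels_prev=partition.labels,
        )
        # release modules below their minimum viable size
        labels = new_partition.labels.copy()
        for i, model in enumerate(models):
            size = int(np.sum(labels == i))
            if 0 < size < _min_size(config, model.regulators.size):
                labels[labels == i] = RAGBAG
        new_partition = Partition(labels=labels, K=K)

        records.append(Configuration(partition, selections, models, r2))
        found, loop = detect_cycle(history, new_partition)
        if found:
            cycle_length = loop
            converged = loop == 1
            break
        history.append(new_partition)
        partition = new_partition
    else:
        warnings.warn(
            f"no repeated partition within {config.max_cycles} cycles; "
            "returning the last configuration (converged=False)",
            stacklevel=2,
        )
        return FitResult(
            configurations=records[-1:],
            history=history,
            converged=False,
            cycle_length=0,
            n_cycles=config.max_cycles,
            config=config,
        )

    # configurations inside the terminal loop, oldest first
    loop_records = records[-cycle_length:]
    return FitResult(
        configurations=loop_records,
        history=history,
        converged=converged,
        cycle_length=cycle_length,
        n_cycles=len(records),
        config=config,
    )
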