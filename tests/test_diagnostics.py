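import numpy as np
import pytest

from oracles import ari_pair_counting
from scmodules.allocate import Partition, RAGBAG, reestimate_module_models, cross_module_r2
from scmodules.coop_lasso import SelectionResult
from scmodules.diagnostics import (
    adjusted_rand_index,
    build_regulatory_table,
    cluster_homogeneity,
    module_predictive_r2,
    regulator_importance,
    regulator_selection_rates,
    silhouette_scores,
)
from scmodules.driver import Configuration, FitConfig, FitResult
from scmodules.io import DataSplits


def _make_splits(Zt1, Zr1, Zt2, Zr2):
    return DataSplits(
        Zt1=Zt1, Zr1=Zr1, Zt2=Zt2, Zr2=Zr2,
        target_names=[f"t{j}" for j in range(Zt1.shape[1])],
        regulator_names=[f"r{k}" for k in range(Zr1.shape[1])],
        split_fraction=0.5, seed=0,
    )


def _make_fit(partition, selections, models, r2, K):
    conf = Configuration(partition, selections, models, r2)
    return FitResult(
        configurations=[conf], history=[partition], converged=True,
        cycle_length=1, n_cycles=1, config=FitConfig(n_modules=K),
    )


def _orthogonal_design(n, q, rng, scale=1.0):
    """Columns orthogonal with equal norms (exact R2 bookkeeping)."""
    M = rng.standard_normal((n, q))
    Q, _ = np.linalg.qr(M)
    return scale * Q[:, :q] * np.sqrt(n)


class TestModulePredictiveR2:
    def test_perfect_and_single_gene_reduction(self, rng):
        n = 40
        Zr1 = _orthogonal_design(n, 2, rng)
        Zr2 = _orthogonal_design(n, 2, rng)
        # module 0: gene 0 = reg0 exactly; module 1: gene 1 noisy
        Zt1 = np.column_stack([Zr1[:, 0], Zr1[:, 1] + rng.standard_normal(n)])
        Zt2 = np.column_stack([Zr2[:, 0], Zr2[:, 1] + rng.standard_normal(n)])
        splits = _make_splits(Zt1, Zr1, Zt2, Zr2)
        models = reestimate_module_models(
            Zt1, Zr1,
            [(np.array([0]), np.array([1])), (np.array([1]), np.array([1]))],
        )
        r2 = cross_module_r2(Zt2, Zr2, models)
        part = Partition(np.array([0, 1]), K=2)
        res = _make_fit(part, [None, None], models, r2, K=2)
        mod_r2 = module_predictive_r2(res, splits)
        assert mod_r2[0] == pytest.approx(1.0, abs=1e-10)
        # single-gene module R2 equals the cross-module R2 entry for that gene
        assert mod_r2[1] == pytest.approx(r2[1, 1])

    def test_empty_module_missing(self, rng):
        n = 30
        Zr1 = rng.standard_normal((n, 1))
        Zt1 = Zr1 + 0.1 * rng.standard_normal((n, 1))
        splits = _make_splits(Zt1, Zr1, Zt1.copy(), Zr1.copy())
        models = reestimate_module_models(Zt1, Zr1, [(np.array([0]), np.array([1]))] * 2)
        r2 = cross_module_r2(Zt1, Zr1, models)
        part = Partition(np.array([0]), K=2)  # module 1 empty
        res = _make_fit(part, [None, None], models, r2, K=2)
        mod_r2 = module_predictive_r2(res, splits)
        assert np.isnan(mod_r2[1])


class TestRegulatorImportance:
    def test_orthogonal_split_importance(self, rng):
        """Target = reg0 + reg1 with orthogonal equal-power regulators: each
        regulator carries half the signal plus there is no noise, so removing
        one costs half the explained variance: I = 1 - 0.5/1.0 = 0.5 (up to
        the small offset from TSS being taken about the sample mean)."""
        n = 200
        Zr = _orthogonal_design(n, 2, rng)
        Zt = (Zr[:, 0] + Zr[:, 1])[:, None]
        splits = _make_splits(Zt, Zr, Zt.copy(), Zr.copy())
        models = reestimate_module_models(Zt, Zr, [(np.array([0, 1]), np.array([1, 1]))])
        r2 = cross_module_r2(Zt, Zr, models)
        part = Partition(np.array([0]), K=1)
        res = _make_fit(part, [None], models, r2, K=1)
        imp = regulator_importance(res, splits)
        assert len(imp) == 2
        np.testing.assert_allclose(imp["importance"], [0.5, 0.5], atol=0.01)

    def test_duplicated_regulator_importance_zero(self, rng):
        n = 100
        x = rng.standard_normal(n)
        Zr = np.column_stack([x, x])  # identical columns
        Zt = x[:, None]
        splits = _make_splits(Zt, Zr, Zt.copy(), Zr.copy())
        models = reestimate_module_models(Zt, Zr, [(np.array([0, 1]), np.array([1, 1]))])
        r2 = cross_module_r2(Zt, Zr, models)
        res = _make_fit(Partition(np.array([0]), K=1), [None], models, r2, K=1)
        imp = regulator_importance(res, splits)
        np.testing.assert_allclose(imp["importance"], [0.0, 0.0], atol=1e-8)

    def test_sole_informative_regulator_importance_one(self, rng):
        n = 100
        Zr = rng.standard_normal((n, 1))
        Zt = Zr + 0.2 * rng.standard_normal((n, 1))
        splits = _make_splits(Zt, Zr, Zt.copy(), Zr.copy())
        models = reestimate_module_models(Zt, Zr, [(np.array([0]), np.array([1]))])
        r2 = cross_module_r2(Zt, Zr, models)
        res = _make_fit(Partition(np.array([0]), K=1), [None], models, r2, K=1)
        imp = regulator_importance(res, splits)
        # reduced model is empty -> prediction 0 -> R2 ~ 0 -> importance ~ 1
        assert imp["importance"].iloc[0] == pytest.approx(1.0, abs=0.05)


class TestSilhouetteScores:
    def test_plug_in_values(self):
        r2 = np.array([[0.8, 0.2, 0.5], [0.4, 0.5, 0.5]])
        part = Partition(np.array([0, 0, 0]), K=2)
        s = silhouette_scores(r2, part)
        assert s[0] == pytest.approx(0.5)  # (0.8-0.4)/0.8
        assert s[1] == pytest.approx(-0.6)  # (0.2-0.5)/0.5
        assert s[2] == pytest.approx(0.0)

    def test_single_module_is_one(self):
        r2 = np.array([[0.7]])
        s = silhouette_scores(r2, Partition(np.array([0]), K=1))
        assert s[0] == pytest.approx(1.0)

    def test_negative_best_other_floored_at_zero(self):
        r2 = np.array([[0.6], [-0.9]])
        s = silhouette_scores(r2, Partition(np.array([0]), K=2))
        assert s[0] == pytest.approx(1.0)  # b floored to 0

    def test_degenerate_zero_with_warning(self):
        r2 = np.array([[0.0], [-1.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            s = silhouette_scores(r2, Partition(np.array([0]), K=2))
        assert s[0] == 0.0

    def test_ragbag_is_nan(self):
        r2 = np.array([[0.5, 0.5]])
        s = silhouette_scores(r2, Partition(np.array([0, RAGBAG]), K=1))
        assert np.isnan(s[1])


class TestRegulatoryTable:
    def test_gate_and_mean(self, rng):
        n = 60
        x = rng.standard_normal(n)
        Zr1 = np.column_stack([x, rng.standard_normal(n)])
        # two module genes correlated with regulator 0, uncorrelated with 1
        Zt1 = np.column_stack([x + 0.1 * rng.standard_normal(n),
                               x + 0.1 * rng.standard_normal(n)])
        splits = _make_splits(Zt1, Zr1, Zt1.copy(), Zr1.copy())
        coef = np.array([[0.2, 0.4], [0.0, 0.0]])
        sel = SelectionResult(coef=coef, regulators=np.array([0]), signs=np.array([1]))
        models = reestimate_module_models(Zt1, Zr1, [(np.array([0]), np.array([1]))])
        r2 = cross_module_r2(Zt1, Zr1, models)
        part = Partition(np.array([0, 0]), K=1)
        res = _make_fit(part, [sel], models, r2, K=1)
        table = build_regulatory_table(res, splits)
        assert table[0, 0] == pytest.approx(0.3)  # mean of (0.2, 0.4), gate passed
        assert table[1, 0] == 0.0  # unselected/uncorrelated row

    def test_anticorrelated_regulator_gated_out(self, rng):
        n = 60
        x = rng.standard_normal(n)
        Zr1 = (-x)[:, None]  # median correlation is negative -> gate fails
        Zt1 = np.column_stack([x, x]) + 0.05 * rng.standard_normal((n, 2))
        splits = _make_splits(Zt1, Zr1, Zt1.copy(), Zr1.copy())
        coef = np.array([[0.5, 0.7]])
        sel = SelectionResult(coef=coef, regulators=np.array([0]), signs=np.array([1]))
        models = reestimate_module_models(Zt1, Zr1, [(np.array([0]), np.array([-1]))])
        r2 = cross_module_r2(Zt1, Zr1, models)
        res = _make_fit(Partition(np.array([0, 0]), K=1), [sel], models, r2, K=1)
        table = build_regulatory_table(res, splits)
        assert table[0, 0] == 0.0


class TestExternalValidation:
    def test_ari_examples(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == pytest.approx(1.0)
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)
        assert adjusted_rand_index([1, 1, 1], [2, 2, 2]) == pytest.approx(1.0)

    def test_ari_matches_pair_counting_on_random_partitions(self, rng):
        for _ in range(20):
            a = rng.integers(-1, 4, size=30)
            b = rng.integers(-1, 4, size=30)
            assert adjusted_rand_index(a, b) == pytest.approx(
                ari_pair_counting(a, b), abs=1e-12
            )

    def test_homogeneity_examples(self):
        assert cluster_homogeneity([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)
        # truth cluster of 4 split 3/1 contributes 0.75
        assert cluster_homogeneity([0, 0, 0, 0], [1, 1, 1, 2]) == pytest.approx(0.75)
        # giant estimated cluster scores 1 (known blind spot)
        assert cluster_homogeneity([0, 0, 1, 1], [0, 0, 0, 0]) == pytest.approx(1.0)

    def test_selection_rates_examples(self):
        # exact recovery
        assert regulator_selection_rates([{0, 1}], [{0, 1}], 10) == (1.0, 0.0)
        # truth {A,B}, est {A,C}: TPR 1/2, FPR 1/8
        tpr, fpr = regulator_selection_rates([{0, 1}], [{0, 2}], 10)
        assert tpr == pytest.approx(0.5)
        assert fpr == pytest.approx(1 / 8)
        # empty estimate
        assert regulator_selection_rates([{0, 1}], [set()], 10) == (0.0, 0.0)

    def test_empty_truth_excluded_from_tpr(self):
        tpr, fpr = regulator_selection_rates([set(), {0}], [{0}, {0}], 5)
        assert tpr == pytest.approx(1.0)  # only the second gene counts
        assert fpr == pytest.approx((1 / 5 + 0.0) / 2)
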