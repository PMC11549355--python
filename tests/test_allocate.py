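import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

from oracles import nnls_oracle
from scmodules.allocate import (
    RAGBAG,
    ModuleModel,
    Partition,
    PriorSpec,
    _log_likelihoods,
    allocate_targets,
    cross_module_r2,
    nnls_fit,
    prior_cluster_probabilities,
    ragbag_filter,
    reestimate_module_models,
)


class TestNNLS:
    def test_recovers_nonnegative_truth(self, rng):
        X = rng.standard_normal((40, 3))
        B0 = np.abs(rng.standard_normal((3, 4)))
        B = nnls_fit(X, X @ B0)
        np.testing.assert_allclose(B, B0, atol=1e-8)

    def test_negative_ls_solution_clipped_to_zero(self):
        X = np.array([[1.0], [1.0]])
        y = np.array([[-1.0], [-2.0]])
        B = nnls_fit(X, y)
        assert B[0, 0] == 0.0

    def test_zero_response_gives_zero(self, rng):
        X = rng.standard_normal((10, 2))
        B = nnls_fit(X, np.zeros((10, 3)))
        np.testing.assert_array_equal(B, np.zeros((2, 3)))

    def test_underdetermined_warns(self, rng):
        with pytest.warns(UserWarning, match="more columns"):
            nnls_fit(rng.standard_normal((2, 4)), rng.standard_normal((2, 1)))

    @pytest.mark.parametrize("q", [1, 2, 3])
    def test_matches_exhaustive_enumeration(self, q, rng):
        for _ in range(20):
            X = rng.standard_normal((15, q))
            y = rng.standard_normal((15, 1))
            ours = nnls_fit(X, y)[:, 0]
            oracle = nnls_oracle(X, y[:, 0])
            np.testing.assert_allclose(ours, oracle, atol=1e-10)


class TestReestimateModuleModels:
    def test_identity_target_coefficient_one(self, rng):
        Zr1 = rng.standard_normal((50, 3))
        Zt1 = Zr1[:, :1].copy()
        models = reestimate_module_models(
            Zt1, Zr1, [(np.array([0]), np.array([1]))]
        )
        assert models[0].coef[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert models[0].sigma2[0] == pytest.approx(1e-12)  # floored

    def test_sign_constraint_binds(self, rng):
        Zr1 = rng.standard_normal((50, 1))
        Zt1 = -Zr1.copy()  # anti-correlated with a positively signed regulator
        models = reestimate_module_models(Zt1, Zr1, [(np.array([0]), np.array([1]))])
        assert models[0].coef[0, 0] == 0.0

    def test_variance_denominator(self, rng):
        n1 = 10
        Zr1 = rng.standard_normal((n1, 2))
        Zt1 = rng.standard_normal((n1, 1))
        regs, signs = np.array([0, 1]), np.array([1, 1])
        models = reestimate_module_models(Zt1, Zr1, [(regs, signs)])
        design = Zr1 * signs
        rss = float(np.sum((Zt1[:, 0] - design @ models[0].coef[:, 0]) ** 2))
        assert models[0].sigma2[0] == pytest.approx(rss / (n1 - 2))

    def test_empty_selection_inactive(self, rng):
        models = reestimate_module_models(
            rng.standard_normal((10, 2)),
            rng.standard_normal((10, 2)),
            [(np.empty(0, dtype=int), np.empty(0, dtype=int))],
        )
        assert not models[0].active

    def test_too_many_regulators_errors(self, rng):
        regs = np.arange(5)
        with pytest.raises(ValueError, match="n1"):
            reestimate_module_models(
                rng.standard_normal((4, 2)),
                rng.standard_normal((4, 5)),
                [(regs, np.ones(5, dtype=int))],
            )


class TestCrossModuleR2:
    def test_perfect_and_null_and_hand_value(self):
        Zr2 = np.array([[1.0], [2.0], [-1.0], [-2.0]])
        # gene 0 = regulator exactly; gene 1 has residuals (1, -1, 0, 0)
        Zt2 = np.column_stack([Zr2[:, 0], Zr2[:, 0] + np.array([1.0, -1.0, 0, 0])])
        model = ModuleModel(
            np.array([0]), np.array([1]), np.array([[1.0, 1.0]]), np.array([0.1, 0.1])
        )
        null_model = ModuleModel(
            np.array([0]), np.array([1]), np.array([[0.0, 0.0]]), np.array([0.1, 0.1])
        )
        r2 = cross_module_r2(Zt2, Zr2, [model, null_model])
        assert r2[0, 0] == pytest.approx(1.0)
        tss1 = float(np.sum((Zt2[:, 1] - Zt2[:, 1].mean()) ** 2))
        assert r2[0, 1] == pytest.approx(1.0 - 2.0 / tss1)
        # the all-zero model on a centered gene scores exactly 0
        assert r2[1, 0] == pytest.approx(0.0)

    def test_hand_arithmetic_tss8(self):
        # residuals (1,-1,0,0) against a gene with TSS 8 -> R2 = 0.75
        Zt2 = np.array([[2.0], [0.0], [0.0], [-2.0]])  # mean 0, TSS 8
        pred = Zt2[:, 0] - np.array([1.0, -1.0, 0.0, 0.0])
        Zr2 = pred[:, None]
        model = ModuleModel(np.array([0]), np.array([1]), np.array([[1.0]]), np.array([0.1]))
        r2 = cross_module_r2(Zt2, Zr2, [model])
        assert r2[0, 0] == pytest.approx(0.75)

    def test_constant_gene_minus_inf_with_warning(self, rng):
        Zt2 = np.ones((6, 1))
        Zr2 = rng.standard_normal((6, 1))
        model = ModuleModel(np.array([0]), np.array([1]), np.zeros((1, 1)), np.array([1.0]))
        with pytest.warns(UserWarning, match="constant"):
            r2 = cross_module_r2(Zt2, Zr2, [model])
        assert r2[0, 0] == -np.inf

    def test_inactive_module_minus_inf(self, rng):
        model = ModuleModel(np.empty(0, dtype=int), np.empty(0, dtype=int), np.zeros((0, 1)), None)
        r2 = cross_module_r2(rng.standard_normal((5, 1)), rng.standard_normal((5, 1)), [model])
        assert np.all(np.isneginf(r2))


class TestRagbagFilter:
    @pytest.mark.parametrize(
        "best,tau,flagged",
        [(0.03, 0.05, True), (1.0, 0.99, False), (0.03, -np.inf, False)],
    )
    def test_threshold_cases(self, best, tau, flagged):
        r2 = np.array([[best - 0.02], [best]])
        assert ragbag_filter(r2, tau)[0] == flagged


class TestPriorProbabilities:
    def test_no_links_uniform(self):
        prior = PriorSpec(J=np.zeros((4, 4)))
        labels = np.array([0, 1, 2, 0])
        p = prior_cluster_probabilities(prior, labels, gene=0, K=3)
        np.testing.assert_allclose(p, [1 / 3, 1 / 3, 1 / 3])

    def test_hand_fractions(self):
        # gene 0 linked to gene 1 (module 0, size 2) and gene 3 (module 1, size 4)
        J = np.zeros((7, 7))
        J[0, [1, 3]] = 1
        J[[1, 3], 0] = 1
        prior = PriorSpec(J=J)
        labels = np.array([0, 0, 0, 1, 1, 1, 1])
        labels[0] = 0
        # module 0: genes {0,1,2} minus the focal gene also counts itself; use
        # explicit membership: module 0 = {0,1}, module 1 = {3,4,5,6}, gene 2 in module 0
        labels = np.array([0, 0, RAGBAG, 1, 1, 1, 1])
        p = prior_cluster_probabilities(prior, labels, gene=0, K=2)
        # f = (1/2, 1/4) -> normalized (2/3, 1/3), alpha negligible
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], atol=1e-5)

    def test_empty_module_fraction_zero(self):
        J = np.zeros((3, 3))
        J[0, 1] = J[1, 0] = 1
        prior = PriorSpec(J=J)
        labels = np.array([0, 0, 0])
        p = prior_cluster_probabilities(prior, labels, gene=0, K=2)
        assert p[1] < p[0]
        assert p[1] > 0  # alpha keeps it strictly positive

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_sums_to_one_and_positive(self, seed):
        rng = np.random.default_rng(seed)
        q = 6
        J = (rng.random((q, q)) < 0.4).astype(float)
        J = np.triu(J, 1)
        J = J + J.T
        prior = PriorSpec(J=J)
        labels = rng.integers(-1, 3, size=q)
        p = prior_cluster_probabilities(prior, labels, gene=0, K=3)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p > 0)

    def test_prior_spec_validation(self):
        with pytest.raises(ValueError, match="diagonal"):
            PriorSpec(J=np.eye(2))
        with pytest.raises(ValueError, match="symmetric"):
            PriorSpec(J=np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestAllocateTargets:
    def _setup(self, rng, sigma_bad=25.0):
        n2, p_t = 40, 3
        Zr2 = rng.standard_normal((n2, 2))
        Zt2 = np.column_stack([Zr2[:, 0]] * p_t) + 0.05 * rng.standard_normal((n2, p_t))
        good = ModuleModel(
            np.array([0]), np.array([1]), np.ones((1, p_t)), np.full(p_t, 0.01)
        )
        bad = ModuleModel(
            np.array([1]), np.array([1]), np.zeros((1, p_t)), np.full(p_t, sigma_bad)
        )
        return Zt2, Zr2, [good, bad]

    def test_likelihood_normalization_sums_to_one(self, rng):
        Zt2, Zr2, models = self._setup(rng)
        ll = _log_likelihoods(Zt2, Zr2, models)
        log_norm = ll - logsumexp(ll, axis=0)[None]
        np.testing.assert_allclose(np.exp(log_norm).sum(axis=0), 1.0, atol=1e-12)

    def test_perfect_module_wins_every_vote(self, rng):
        Zt2, Zr2, models = self._setup(rng)
        part = allocate_targets(
            Zt2, Zr2, models, np.zeros(3, bool), np.random.default_rng(0)
        )
        np.testing.assert_array_equal(part.labels, [0, 0, 0])

    def test_mu_one_follows_prior_only(self, rng):
        Zt2, Zr2, models = self._setup(rng)
        # prior links gene 2 to genes 0 and 1 which sit in module 1
        J = np.zeros((3, 3))
        J[2, [0, 1]] = 1
        J[[0, 1], 2] = 1
        prior = PriorSpec(J=J, mu=1.0)
        part = allocate_targets(
            Zt2,
            Zr2,
            models,
            np.zeros(3, bool),
            np.random.default_rng(3),
            prior=prior,
            labels_prev=np.array([1, 1, 0]),
        )
        assert part.labels[2] == 1  # likelihood strongly prefers 0, prior wins

    def test_vote_tie_breaks_to_lowest_index(self):
        # two identical modules -> identical scores everywhere -> argmax = 0
        n2, p_t = 10, 2
        Zr2 = np.linspace(-1, 1, n2)[:, None]
        Zt2 = np.column_stack([Zr2[:, 0]] * p_t)
        m = ModuleModel(np.array([0]), np.array([1]), np.ones((1, p_t)), np.full(p_t, 0.5))
        part = allocate_targets(
            Zt2, Zr2, [m, m], np.zeros(p_t, bool), np.random.default_rng(0)
        )
        np.testing.assert_array_equal(part.labels, [0, 0])

    def test_ragbag_genes_not_allocated(self, rng):
        Zt2, Zr2, models = self._setup(rng)
        ragbag = np.array([False, True, False])
        part = allocate_targets(Zt2, Zr2, models, ragbag, np.random.default_rng(0))
        assert part.labels[1] == RAGBAG
        assert part.ragbag.tolist() == [False, True, False]

    def test_all_inactive_with_pending_genes_errors(self, rng):
        p_t = 2
        empty = ModuleModel(np.empty(0, int), np.empty(0, int), np.zeros((0, p_t)), None)
        with pytest.raises(ValueError, match="empty"):
            allocate_targets(
                rng.standard_normal((5, p_t)),
                rng.standard_normal((5, 1)),
                [empty],
                np.zeros(p_t, bool),
                np.random.default_rng(0),
            )


class TestPartition:
    def test_equality_includes_ragbag(self):
        a = Partition(np.array([0, 1, RAGBAG]), K=2)
        b = Partition(np.array([0, 1, 1]), K=2)
        c = Partition(np.array([0, 1, RAGBAG]), K=2)
        assert a == c
        assert a != b

    def test_label_range_validated(self):
        with pytest.raises(ValueError):
            Partition(np.array([0, 2]), K=2)
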