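import numpy as np
import pytest

from treelandscape.evaluate import procrustes
from treelandscape.optimize import (
    Embedding,
    InadmissiblePairError,
    OptimizerSpec,
    admissible_pairs,
    embed,
    initialize,
    run_batch,
    run_gauss_seidel_newton,
    run_linear_iteration,
    run_majorization,
    run_mcmc,
    run_sgd,
)
from treelandscape.stress import StressSpec, embedded_distances, stress_value


class TestAdmissiblePairs:
    def test_exactly_fourteen(self):
        pairs = admissible_pairs()
        assert len(pairs) == 14
        assert len(set(pairs)) == 14

    def test_cca_exclusions(self):
        pairs = admissible_pairs()
        assert ("cca", "majorization") not in pairs
        assert ("cca", "gauss_seidel_newton") not in pairs
        assert ("cca", "sgd") in pairs
        assert ("cca", "mcmc") in pairs

    def test_kruskal1_linear_iteration_substitution(self):
        pairs = admissible_pairs()
        assert ("kruskal1", "linear_iteration") in pairs
        assert ("kruskal1", "sgd") not in pairs

    def test_inadmissible_pair_raises_with_rule(self):
        delta = embedded_distances(np.random.default_rng(0).uniform(size=(6, 2)))
        with pytest.raises(InadmissiblePairError, match="14 admissible"):
            embed(delta, "cca", "majorization", p=2, seed=0)


class TestInitialize:
    def test_deterministic_and_bounded(self):
        delta = embedded_distances(np.random.default_rng(0).uniform(size=(8, 2)))
        a = initialize(delta, 3, 7)
        b = initialize(delta, 3, 7)
        c = initialize(delta, 3, 8)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)
        assert a.min() >= 0 and a.max() <= delta.max()
        assert a.shape == (8, 3)


class TestMajorization:
    def test_monotone_trace_on_random_instances(self):
        rng = np.random.default_rng(1)
        for name in ("normalized", "kruskal1", "nlm"):
            delta = embedded_distances(rng.uniform(size=(20, 3)))
            emb = run_majorization(delta, StressSpec(name=name),
                                   initialize(delta, 2, 0))
            assert np.all(np.diff(emb.trace) <= 1e-9 * np.abs(emb.trace[:-1]) + 1e-15)

    def test_exact_recovery(self, embeddable_delta50):
        _, delta = embeddable_delta50
        emb = run_majorization(delta, StressSpec(name="normalized"),
                               initialize(delta, 2, 1))
        assert emb.final_stress < 1e-4

    def test_recovers_unit_square_up_to_similarity(self):
        # a single start can hit a known 4-point local minimum, so this
        # follows the multi-restart protocol and takes the best run
        truth = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        delta = embedded_distances(truth)
        batch = run_batch(delta, "normalized", "majorization", p=2,
                          n_restarts=5, base_seed=0)
        assert procrustes(truth, batch.best.X).residual < 1e-3


class TestGaussSeidelNewton:
    def test_exact_recovery(self, embeddable_delta50):
        _, delta = embeddable_delta50
        emb = run_gauss_seidel_newton(delta, StressSpec(name="normalized"),
                                      initialize(delta, 2, 1))
        assert emb.final_stress < 1e-4

    def test_within_five_percent_of_majorization(self):
        rng = np.random.default_rng(6)
        delta = embedded_distances(rng.uniform(size=(50, 4)))  # not embeddable at p=2
        best = {}
        for run in (run_majorization, run_gauss_seidel_newton):
            vals = [run(delta, StressSpec(name="normalized"),
                        initialize(delta, 2, s)).final_stress for s in range(3)]
            best[run.__name__] = min(vals)
        assert best["run_gauss_seidel_newton"] <= 1.05 * best["run_majorization"]

    def test_single_point_is_coordinatewise_optimal(self):
        """Frozen-others single-point stress cannot be improved materially."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(7)
        delta = embedded_distances(rng.uniform(size=(12, 2)))
        spec = StressSpec(name="normalized")
        emb = run_gauss_seidel_newton(delta, spec, initialize(delta, 2, 0))
        X = emb.X

        def point_stress(xi, i=3):
            Y = X.copy()
            Y[i] = xi
            return stress_value(spec, delta, Y)

        res = minimize(point_stress, X[3], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        assert point_stress(X[3]) - res.fun < 1e-3 * max(res.fun, 1e-6)


class TestSGD:
    def test_exact_recovery_normalized(self, embeddable_delta50):
        _, delta = embeddable_delta50
        emb = run_sgd(delta, StressSpec(name="normalized"),
                      initialize(delta, 2, 1), rng=np.random.default_rng(1))
        assert emb.final_stress < 1e-3

    def test_bit_reproducible_given_seed(self, embeddable_delta50):
        _, delta = embeddable_delta50
        a = embed(delta, "cca", "sgd", p=2, seed=9)
        b = embed(delta, "cca", "sgd", p=2, seed=9)
        np.testing.assert_array_equal(a.X, b.X)
        assert a.final_stress == b.final_stress


class TestMCMC:
    def test_acceptance_behaviour_at_temperature_extremes(self):
        rng = np.random.default_rng(8)
        delta = embedded_distances(rng.uniform(size=(10, 2)))
        spec = StressSpec(name="normalized")
        # at T -> 0 only descents are accepted: stress never ends above start
        cold = OptimizerSpec(name="mcmc", T0=1e-300, max_sweeps=50)
        X0 = initialize(delta, 2, 0)
        emb = run_mcmc(delta, spec, X0, cold, rng=np.random.default_rng(0))
        assert emb.final_stress <= stress_value(spec, delta, X0)

    def test_exact_recovery_ten_points(self):
        rng = np.random.default_rng(9)
        delta = embedded_distances(rng.uniform(size=(10, 2)))
        emb = run_mcmc(delta, StressSpec(name="normalized"),
                       initialize(delta, 2, 3), rng=np.random.default_rng(3))
        assert emb.final_stress < 1e-2

    def test_returns_best_visited_state(self, embeddable_delta50):
        _, delta = embeddable_delta50
        spec = StressSpec(name="normalized")
        emb = run_mcmc(delta, spec, initialize(delta, 2, 5),
                       OptimizerSpec(name="mcmc", max_sweeps=200),
                       rng=np.random.default_rng(5))
        # reported stress must match the returned coordinates
        assert stress_value(spec, delta, emb.X) == pytest.approx(
            emb.final_stress, rel=1e-9)


class TestLinearIteration:
    def test_converges_on_embeddable_instance(self, embeddable_delta50):
        _, delta = embeddable_delta50
        best = min(
            run_linear_iteration(delta, StressSpec(name="kruskal1"),
                                 initialize(delta, 2, seed),
                                 OptimizerSpec(name="linear_iteration",
                                               max_sweeps=3000)).final_stress
            for seed in (0, 2))
        assert best < 1e-2

    def test_absurd_step_diverges_with_diagnostic(self, embeddable_delta50):
        _, delta = embeddable_delta50
        with pytest.raises(RuntimeError, match="smaller fixed step"):
            run_linear_iteration(delta, StressSpec(name="kruskal1"),
                                 initialize(delta, 2, 0),
                                 OptimizerSpec(name="linear_iteration", eta=100.0))

    def test_trace_not_guaranteed_monotone(self, embeddable_delta50):
        """Fixed-step descent without line search may overshoot: at least one
        sweep on some start shows a stress uptick."""
        _, delta = embeddable_delta50
        saw_uptick = False
        for seed in range(5):
            emb = run_linear_iteration(
                delta, StressSpec(name="kruskal1"), initialize(delta, 2, seed),
                OptimizerSpec(name="linear_iteration", max_sweeps=400),
                record_trace=True)
            if np.any(np.diff(emb.trace) > 1e-12):
                saw_uptick = True
                break
        assert saw_uptick


class TestRunBatch:
    def test_restarts_have_distinct_seeds(self, embeddable_delta50):
        _, delta = embeddable_delta50
        batch = run_batch(delta, "normalized", "majorization", p=2,
                          n_restarts=4, base_seed=100)
        assert len(batch.runs) == 4
        assert len({r.seed for r in batch.runs}) == 4

    def test_best_not_worse_than_any_run(self, embeddable_delta50):
        _, delta = embeddable_delta50
        batch = run_batch(delta, "normalized", "majorization", p=2,
                          n_restarts=4, base_seed=100)
        assert all(batch.best.final_stress <= r.final_stress for r in batch.runs)
        assert batch.stderr_stress >= 0

    def test_inadmissible_pair_rejected(self, embeddable_delta50):
        _, delta = embeddable_delta50
        with pytest.raises(InadmissiblePairError):
            run_batch(delta, "cca", "gauss_seidel_newton", p=2, n_restarts=2)

    def test_final_stress_not_above_initial_on_best_restart(self, embeddable_delta50):
        _, delta = embeddable_delta50
        for stress, opt in [("normalized", "sgd"), ("kruskal1", "majorization")]:
            batch = run_batch(delta, stress, opt, p=2, n_restarts=2, base_seed=0)
            spec = StressSpec(name=stress)
            for r in batch.runs:
                init = stress_value(spec, delta, initialize(delta, 2, r.seed))
                assert r.final_stress <= init


class TestDeterminism:
    @pytest.mark.parametrize("stress,opt", [
        ("normalized", "majorization"),
        ("normalized", "gauss_seidel_newton"),
        ("nlm", "sgd"),
        ("kruskal1", "mcmc"),
        ("kruskal1", "linear_iteration"),
    ])
    def test_identical_seed_identical_embedding(self, stress, opt):
        rng = np.random.default_rng(12)
        delta = embedded_distances(rng.uniform(size=(15, 2)))
        spec = OptimizerSpec(name=opt, max_sweeps=60)
        a = embed(delta, stress, opt, p=2, seed=4, opt_spec=spec)
        b = embed(delta, stress, opt, p=2, seed=4, opt_spec=spec)
        np.testing.assert_array_equal(a.X, b.X)
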