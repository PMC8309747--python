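"""Binary-PSO mechanics: update equations, elitism, reset, and the
exhaustive-search oracle."""

import numpy as np
import pytest

import nirstack as ns
from nirstack.pso import (
    Particle,
    Swarm,
    detect_premature_convergence,
    diversity,
    init_swarm,
    reset_swarm,
    update_global_best,
    update_personal_best,
    update_position,
    update_velocity,
)


class TestSigmoid:
    def test_zero_is_half(self):
        assert ns.sigmoid(0.0) == pytest.approx(0.5)

    def test_symmetry_identity(self):
        for v in (-30.0, -2.5, 0.1, 7.0, 800.0):
            assert ns.sigmoid(v) + ns.sigmoid(-v) == pytest.approx(1.0)

    def test_closed_form_value(self):
        assert ns.sigmoid(10.0) == pytest.approx(1.0 / (1.0 + np.exp(-10.0)), rel=1e-12)
        assert ns.sigmoid(10.0) == pytest.approx(0.9999546, abs=1e-7)

    def test_overflow_safe(self):
        assert ns.sigmoid(1000.0) == pytest.approx(1.0)
        assert ns.sigmoid(-1000.0) == pytest.approx(0.0)

    def test_literal_convention_is_decreasing(self):
        assert ns.sigmoid(10.0, literal=True) == pytest.approx(1.0 / (1.0 + np.exp(10.0)))


class TestVelocityUpdate:
    def _particle(self, x, v, pb):
        x = np.asarray(x, dtype=np.int8)
        return Particle(x, np.asarray(v, dtype=float), np.asarray(pb, dtype=np.int8), 0.0)

    def test_pure_inertia(self):
        cfg = ns.PSOConfig(w=1.0, c1=0.0, c2=0.0, v_max=10.0)
        p = self._particle([0, 1], [1.5, -2.0], [1, 1])
        update_velocity(p, np.array([1, 0], dtype=np.int8), cfg, np.random.default_rng(0))
        np.testing.assert_allclose(p.velocity, [1.5, -2.0])

    def test_attraction_vanishes_at_both_bests(self):
        cfg = ns.PSOConfig(w=0.5, c1=2.0, c2=2.0, v_max=10.0)
        x = np.array([1, 0], dtype=np.int8)
        p = self._particle(x, [2.0, -1.0], x)
        update_velocity(p, x, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(p.velocity, [1.0, -0.5])

    def test_hand_computed_update(self):
        # w=0.9, c1=c2=2, dt=1, x=0, x_pb=x_sb=1, v=0, q=r=0.5 -> v = 2.0
        class HalfRng:
            def uniform(self, *a, **k):
                return 0.5

        cfg = ns.PSOConfig(w=0.9, c1=2.0, c2=2.0, dt=1.0, v_max=10.0)
        p = self._particle([0], [0.0], [1])
        update_velocity(p, np.array([1], dtype=np.int8), cfg, HalfRng())
        assert p.velocity[0] == pytest.approx(2.0)

    def test_clamped_to_vmax(self):
        cfg = ns.PSOConfig(w=1.0, c1=50.0, c2=50.0, v_max=6.0)
        p = self._particle([0], [5.0], [1])
        update_velocity(p, np.array([1], dtype=np.int8), cfg, np.random.default_rng(0))
        assert abs(p.velocity[0]) <= 6.0


class TestBests:
    def test_personal_best_strict_improvement_only(self):
        p = Particle(np.array([1, 0], dtype=np.int8), np.zeros(2), np.array([0, 1], dtype=np.int8), 0.5)
        update_personal_best(p, 0.5)  # tie: unchanged
        np.testing.assert_array_equal(p.best_position, [0, 1])
        update_personal_best(p, 0.6)
        np.testing.assert_array_equal(p.best_position, [1, 0])
        assert p.best_fitness == 0.6

    def test_personal_best_tracks_running_maximum(self):
        p = Particle(np.array([1], dtype=np.int8), np.zeros(1), np.array([1], dtype=np.int8), -np.inf)
        for f in (0.3, 0.5, 0.4):
            update_personal_best(p, f)
        assert p.best_fitness == 0.5

    def test_global_best_ties_keep_incumbent(self):
        a = Particle(np.array([1, 0], dtype=np.int8), np.zeros(2), np.array([1, 0], dtype=np.int8), 0.7)
        b = Particle(np.array([0, 1], dtype=np.int8), np.zeros(2), np.array([0, 1], dtype=np.int8), 0.7)
        swarm = Swarm([a, b], a.best_position.copy(), 0.7)
        update_global_best(swarm)
        np.testing.assert_array_equal(swarm.best_position, [1, 0])

    def test_single_particle_swarm(self):
        a = Particle(np.array([1], dtype=np.int8), np.zeros(1), np.array([1], dtype=np.int8), 0.9)
        swarm = Swarm([a], np.array([0], dtype=np.int8), -np.inf)
        update_global_best(swarm)
        assert swarm.best_fitness == 0.9


class TestInitAndPosition:
    def test_init_deterministic(self):
        cfg = ns.PSOConfig(n_particles=5)
        a = init_swarm(cfg, 12, np.random.default_rng(3))
        b = init_swarm(cfg, 12, np.random.default_rng(3))
        for pa, pb in zip(a.particles, b.particles):
            np.testing.assert_array_equal(pa.position, pb.position)
            np.testing.assert_allclose(pa.velocity, pb.velocity)

    def test_init_d1_forces_selected(self):
        cfg = ns.PSOConfig(n_particles=10)
        swarm = init_swarm(cfg, 1, np.random.default_rng(0))
        for p in swarm.particles:
            np.testing.assert_array_equal(p.position, [1])

    def test_no_all_zero_positions_over_seeds(self):
        cfg = ns.PSOConfig(n_particles=50)
        for seed in range(100):
            swarm = init_swarm(cfg, 3, np.random.default_rng(seed))
            assert all(p.position.any() for p in swarm.particles)

    def test_position_saturated_velocity(self):
        cfg = ns.PSOConfig()
        p = Particle(np.array([0, 0], dtype=np.int8), np.array([40.0, -40.0]),
                     np.array([1, 1], dtype=np.int8), 0.0)
        update_position(p, np.random.default_rng(0), cfg)
        assert p.position[0] == 1
        assert p.position[1] == 0

    def test_zero_velocity_bit_is_fair_coin(self):
        cfg = ns.PSOConfig()
        rng = np.random.default_rng(0)
        draws = []
        # second coordinate pinned on (saturated velocity) so the all-zero
        # repair never distorts the fair coin on coordinate 0
        p = Particle(np.array([0, 1], dtype=np.int8), np.array([0.0, 40.0]),
                     np.array([1, 1], dtype=np.int8), 0.0)
        for _ in range(10_000):
            update_position(p, rng, cfg)
            draws.append(p.position[0])
        assert abs(np.mean(draws) - 0.5) < 0.02


class TestConvergenceAndReset:
    def _collapsed_swarm(self, cfg, D=10, n=8):
        pos = np.ones(D, dtype=np.int8)
        particles = [
            Particle(pos.copy(), np.full(D, cfg.v_max), pos.copy(), 0.5) for _ in range(n)
        ]
        return Swarm(particles, pos.copy(), 0.5)

    def test_fresh_swarm_not_flagged(self):
        cfg = ns.PSOConfig(n_particles=20)
        for seed in range(100):
            swarm = init_swarm(cfg, 30, np.random.default_rng(seed))
            # fresh random positions are diverse; velocities may touch v_max
            assert diversity(swarm) > cfg.diversity_threshold
            assert not detect_premature_convergence(swarm, cfg)

    def test_collapsed_saturated_swarm_flagged(self):
        cfg = ns.PSOConfig()
        assert detect_premature_convergence(self._collapsed_swarm(cfg), cfg)

    def test_single_particle_diversity_is_zero(self):
        cfg = ns.PSOConfig()
        p = Particle(np.ones(4, dtype=np.int8), np.zeros(4), np.ones(4, dtype=np.int8), 0.0)
        swarm = Swarm([p], p.position.copy(), 0.0)
        assert diversity(swarm) == 0.0
        assert not detect_premature_convergence(swarm, cfg)  # velocity below v_max
        p.velocity[:] = cfg.v_max
        assert detect_premature_convergence(swarm, cfg)

    def test_reset_preserves_bests_and_restores_diversity(self):
        cfg = ns.PSOConfig()
        swarm = self._collapsed_swarm(cfg, D=40)
        before_best = swarm.best_fitness
        before_div = diversity(swarm)
        reset_swarm(swarm, np.random.default_rng(0), cfg)
        assert swarm.best_fitness == before_best
        assert all(p.best_fitness == 0.5 for p in swarm.particles)
        assert diversity(swarm) > before_div

    def test_reset_reproducible(self):
        cfg = ns.PSOConfig()
        a = self._collapsed_swarm(cfg, D=20)
        b = self._collapsed_swarm(cfg, D=20)
        reset_swarm(a, np.random.default_rng(9), cfg)
        reset_swarm(b, np.random.default_rng(9), cfg)
        for pa, pb in zip(a.particles, b.particles):
            np.testing.assert_array_equal(pa.position, pb.position)
            np.testing.assert_allclose(pa.velocity, pb.velocity)


def _size_only_fitness(mask, dataset=None):
    """alpha=0 limit of the wrapper objective: compactness only."""
    return 1.0 - mask.n_selected / len(mask)


class TestRunPso:
    def _dummy_dataset(self, D=10):
        grid = ns.WavelengthGrid(np.arange(400.0, 400.0 + D))
        return ns.SpectraDataset(
            grid=grid,
            reflectance=0.5 + 0.01 * np.random.default_rng(0).standard_normal((6, D)),
            variety=[1, 1, 2, 2, 3, 3], sample_id=list(range(6)),
            replicate_id=[1] * 6, nitrogen=np.ones(6), organic_matter=np.ones(6),
        )

    def test_size_only_objective_reaches_single_channel(self):
        ds = self._dummy_dataset(10)
        cfg = ns.PSOConfig(seed=0)
        mask, history = ns.run_pso(ds, _size_only_fitness, cfg)
        assert mask.n_selected == 1
        assert history[-1] == pytest.approx(0.9)

    def test_history_is_monotone_nondecreasing(self):
        ds = self._dummy_dataset(12)
        mask, history = ns.run_pso(ds, _size_only_fitness, ns.PSOConfig(seed=3))
        assert all(b >= a for a, b in zip(history, history[1:]))

    def test_full_determinism_given_seed(self):
        ds = self._dummy_dataset(12)
        m1, h1 = ns.run_pso(ds, _size_only_fitness, ns.PSOConfig(seed=5))
        m2, h2 = ns.run_pso(ds, _size_only_fitness, ns.PSOConfig(seed=5))
        np.testing.assert_array_equal(m1.bits, m2.bits)
        assert h1 == h2

    def test_subset_fitness_formula_limits(self, tiny_problem):
        ds = tiny_problem["dataset"]
        specs = ns.default_model_specs()
        stack = ns.StackSpec(
            base=[specs["knn"], specs["ridge"]],
            meta=ns.ModelSpec("logistic", "classifier", {"solver": "lbfgs"}),
            internal_folds=3, task="classifier",
        )
        mask = ns.FeatureMask(np.array([1, 0, 0, 0, 0, 0, 0, 0]))
        # alpha = 0: pure compactness, independent of the data
        assert ns.subset_fitness(mask, ds, stack, alpha=0.0, folds=3, seed=0) == pytest.approx(
            1.0 - 1.0 / 8.0
        )
        # alpha = 1: pure accuracy
        j1 = ns.subset_fitness(mask, ds, stack, alpha=1.0, folds=3, seed=0)
        p = ns.cv_accuracy(stack, ns.apply_feature_mask(ds, mask).reflectance, ds.variety, 3, 0)
        assert j1 == pytest.approx(p)

    def test_all_zero_mask_is_minus_inf(self, tiny_problem):
        stack = ns.build_fsgc()
        mask = ns.FeatureMask(np.zeros(8, dtype=np.int8))
        assert ns.subset_fitness(mask, tiny_problem["dataset"], stack) == -np.inf


class TestExhaustiveOracle:
    def test_d1(self):
        grid = ns.WavelengthGrid(np.array([500.0]))
        ds = ns.SpectraDataset(
            grid=grid, reflectance=np.full((2, 1), 0.5), variety=[1, 2],
            sample_id=[0, 1], replicate_id=[1, 1], nitrogen=[1.0, 2.0],
            organic_matter=[40.0, 41.0],
        )
        mask = ns.exhaustive_best_subset(ds, _size_only_fitness)
        np.testing.assert_array_equal(mask.bits, [1])

    def test_size_only_tie_break_prefers_channel_zero(self):
        grid = ns.WavelengthGrid(np.arange(400.0, 406.0))
        ds = ns.SpectraDataset(
            grid=grid, reflectance=np.full((2, 6), 0.5), variety=[1, 2],
            sample_id=[0, 1], replicate_id=[1, 1], nitrogen=[1.0, 2.0],
            organic_matter=[40.0, 41.0],
        )
        mask = ns.exhaustive_best_subset(ds, _size_only_fitness)
        np.testing.assert_array_equal(mask.indices, [0])

    def test_large_d_refused(self):
        grid = ns.WavelengthGrid(np.arange(400.0, 420.0))
        ds = ns.SpectraDataset(
            grid=grid, reflectance=np.full((2, 20), 0.5), variety=[1, 2],
            sample_id=[0, 1], replicate_id=[1, 1], nitrogen=[1.0, 2.0],
            organic_matter=[40.0, 41.0],
        )
        with pytest.raises(ValueError, match="16"):
            ns.exhaustive_best_subset(ds, _size_only_fitness)

    def test_oracle_dominates_pso(self, tiny_problem):
        ds, fitness = tiny_problem["dataset"], tiny_problem["fitness"]
        f_star = tiny_problem["oracle_fitness"]
        for seed in (0, 1, 2):
            mask, _ = ns.run_pso(ds, fitness, ns.PSOConfig(seed=seed))
            assert fitness(mask, ds) <= f_star + 1e-12
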