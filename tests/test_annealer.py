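import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import spearmanr

import combcrystal as cc
from combcrystal.annealer import PairPotentialParams

D = 5.4
POT = PairPotentialParams(d=D)


class TestPairPotential:
    def test_sigma_is_zero_crossing(self):
        assert math.isclose(cc.pair_potential(POT.sigma, POT), 0.0, abs_tol=1e-14)
        assert math.isclose(POT.sigma, D / 2 ** (1 / 6), rel_tol=1e-15)

    def test_minimum_at_equilibrium_spacing(self):
        res = minimize_scalar(lambda r: cc.pair_potential(r, POT),
                              bounds=(0.5 * D, 2.0 * D), method="bounded",
                              options={"xatol": 1e-10})
        assert abs(res.x - D) < 1e-6
        assert math.isclose(res.fun, -0.25, abs_tol=1e-12)

    def test_value_at_twice_sigma(self):
        # (1/2)^12 - (1/2)^6 = 1/4096 - 1/64
        expect = 1 / 4096 - 1 / 64
        assert math.isclose(cc.pair_potential(2 * POT.sigma, POT), expect,
                            rel_tol=1e-12)

    def test_nonpositive_distance_raises(self):
        with pytest.raises(ValueError):
            cc.pair_potential(0.0, POT)
        with pytest.raises(ValueError):
            cc.pair_potential(np.array([1.0, -2.0]), POT)

    def test_vectorized_matches_scalar(self):
        rs = np.linspace(0.5 * D, 3 * D, 17)
        vec = cc.pair_potential(rs, POT)
        assert np.allclose(vec, [cc.pair_potential(r, POT) for r in rs])


class TestLocalEnergy:
    def test_single_pair_at_equilibrium(self):
        pts = np.array([[0, 0], [D, 0], [50, 50.0]])
        system = cc.ParticleSystem(pts, np.array([True, True, False]),
                                   ((-1, -1), (60, 60)))
        system.spec = cc.FrustrationSpec(d=D)
        graph = cc.first_neighbors(pts)
        # particle 0's neighbors: 1 at distance d and 2 far away
        e = cc.local_energy(system, graph, 0)
        far = cc.pair_potential(np.hypot(50, 50), POT)
        assert math.isclose(e, -0.25 + far, rel_tol=1e-9)

    def test_perfect_lattice_interior_energy(self):
        pts = cc.perfect_lattice(7, 7, D)
        system = cc.ParticleSystem(pts, np.ones(len(pts), bool),
                                   (pts.min(0) - 1, pts.max(0) + 1))
        system.spec = cc.FrustrationSpec(d=D)
        graph = cc.first_neighbors(pts)
        center = np.argmin(np.hypot(*(pts - pts.mean(0)).T))
        assert graph.degree(center) == 6
        assert math.isclose(cc.local_energy(system, graph, center), -1.5,
                            abs_tol=1e-9)

    def test_edge_contribution_is_symmetric(self):
        pts = np.array([[0, 0], [D, 0], [D / 2, D]])
        system = cc.ParticleSystem(pts, np.ones(3, bool), ((-1, -1), (7, 7)))
        graph = cc.first_neighbors(pts)
        # the (0,1) edge enters both local energies with the same value
        r01 = cc.pair_potential(D, POT)
        e0 = cc.local_energy(system, graph, 0)
        e1 = cc.local_energy(system, graph, 1)
        r02 = cc.pair_potential(np.hypot(D / 2, D), POT)
        r12 = cc.pair_potential(np.hypot(D / 2, D), POT)
        assert math.isclose(e0 - r02, r01, rel_tol=1e-9)
        assert math.isclose(e1 - r12, r01, rel_tol=1e-9)


class TestMetropolis:
    def test_energy_decreasing_always_accepted(self):
        assert cc.metropolis_accept(-0.3, 1e-6, 0.999999)

    def test_threshold_at_unit_reduced_energy(self):
        # exp(-1) ~ 0.3679
        assert cc.metropolis_accept(0.5, 0.5, 0.30)
        assert not cc.metropolis_accept(0.5, 0.5, 0.40)

    def test_zero_delta_is_certain(self):
        assert cc.metropolis_accept(0.0, 0.2, 0.999)

    def test_nonpositive_temperature_raises(self):
        with pytest.raises(ValueError):
            cc.metropolis_accept(0.1, 0.0, 0.5)

    def test_empirical_acceptance_matches_boltzmann(self):
        """Over 10^4 trials at fixed dU/T the acceptance frequency lies
        within 3 standard errors of exp(-dU/T)."""
        rng = np.random.default_rng(42)
        n = 10_000
        for ratio in (0.5, 1.0, 2.0):
            p = math.exp(-ratio)
            hits = sum(cc.metropolis_accept(ratio, 1.0, rng.random())
                       for _ in range(n))
            se = math.sqrt(p * (1 - p) / n)
            assert abs(hits / n - p) < 3 * se


class TestProposeMove:
    def _system(self):
        pts = np.array([[0.0, 0.0], [D, 0.0], [D / 2, D]])
        return cc.ParticleSystem(pts, np.array([True, True, False]),
                                 ((0, 0), (D, D)))

    def test_zero_step_is_identity(self):
        s = self._system()
        rng = np.random.default_rng(0)
        cand = cc.propose_move(s, 2, 0.0, rng)
        assert np.allclose(cand, s.positions[2], atol=1e-12)

    def test_clamped_to_box(self):
        s = self._system()
        s.positions[2] = [0.0, 0.0]  # corner
        rng = np.random.default_rng(1)
        for _ in range(200):
            cand = cc.propose_move(s, 2, 5.0, rng)
            assert np.all(cand >= 0.0) and np.all(cand <= D)

    def test_fixed_particle_rejected(self):
        with pytest.raises(ValueError):
            cc.propose_move(self._system(), 0, 0.1, np.random.default_rng(0))

    def test_deterministic_sequence(self):
        s = self._system()
        seq1 = [cc.propose_move(s, 2, 0.3, np.random.default_rng(9))
                for _ in range(1)]
        seq2 = [cc.propose_move(s, 2, 0.3, np.random.default_rng(9))
                for _ in range(1)]
        assert np.allclose(seq1, seq2)


class TestAnneal:
    def test_free_particle_relaxes_to_equilibrium_distance(self):
        """One free center near two fixed ones settles d +/- 1% away."""
        fixed = np.array([[0.0, 0.0], [D, 0.0]])
        free = np.array([[D / 2 + 0.9, D * 0.6]])
        pts = np.vstack([fixed, free])
        system = cc.ParticleSystem(pts, np.array([True, True, False]),
                                   ((-2 * D, -2 * D), (3 * D, 3 * D)))
        cfg = cc.AnnealConfig(T0=0.05, gamma=0.6, n_stages=20,
                              sweeps_per_stage=40, step_sigma=0.2,
                              relocate_prob=0.0, seed=4)
        final, _ = cc.anneal(system, POT, cfg)
        r = np.hypot(*(final.positions[2] - final.positions[:2]).T)
        assert np.all(np.abs(r - D) < 0.01 * D)

    def test_fixed_particles_bit_identical(self, tiny_result):
        model = tiny_result.model
        before = model.system.positions[model.system.fixed_mask]
        after = tiny_result.system.positions[tiny_result.system.fixed_mask]
        assert np.array_equal(before, after)

    def test_trace_has_monotone_temperature_and_length(self, tiny_result):
        trace = tiny_result.trace
        assert len(trace) == tiny_result.model.config.n_stages
        assert np.all(np.diff(trace.temperature) < 0)

    def test_energy_decreases_over_the_schedule(self):
        """Stage energies trend downward (Spearman rho < 0) and the final
        energy is below the initial one in at least 9 of 10 seeded runs."""
        spec = cc.FrustrationSpec(A=0, L=2, h=0, rows=6, cols=4)
        wins = 0
        rhos = []
        for seed in range(10):
            cfg = cc.AnnealConfig(n_stages=10, sweeps_per_stage=10, seed=seed)
            res = cc.HoneycombModel.from_scenario(spec, seed=seed,
                                                  config=cfg).fit()
            e = res.trace.total_energy
            wins += e[-1] <= e[0]
            rhos.append(spearmanr(np.arange(len(e)), e).statistic)
        assert wins >= 9
        assert np.mean(rhos) < 0

    def test_no_moving_particles_raises(self):
        pts = cc.perfect_lattice(4, 4, D)
        system = cc.ParticleSystem(pts, np.ones(len(pts), bool),
                                   (pts.min(0) - 1, pts.max(0) + 1))
        with pytest.raises(ValueError):
            cc.anneal(system, POT, cc.AnnealConfig())

    def test_identical_seeds_identical_runs(self):
        spec = cc.FrustrationSpec(A=10, L=2, h=0, rows=6, cols=4)
        cfg = cc.AnnealConfig(n_stages=4, sweeps_per_stage=8, seed=11)
        r1 = cc.HoneycombModel.from_scenario(spec, seed=11, config=cfg).fit()
        r2 = cc.HoneycombModel.from_scenario(spec, seed=11, config=cfg).fit()
        assert np.array_equal(r1.system.positions, r2.system.positions)
        assert np.array_equal(r1.trace.total_energy, r2.trace.total_energy)
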