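"""Elastic-polymer path sampling: energies, forces, path measure, CV."""

import numpy as np
import pytest
from scipy import stats

from mopcv.bias import BiasConfig
from mopcv.dynamics import BrownianParams
from mopcv.mop import (PathPolymer, PathSample, effective_potential,
                       end_to_end_cv, lowest_action_path, polymer_forces,
                       relax_polymer, run_mop)
from mopcv.potentials import HarmonicWell, MullerBrown, ThermoParams


def random_polymer(rng, n=5, lo=(-1.0, 0.0), hi=(1.0, 2.0), **kw):
    return PathPolymer(rng.uniform(lo, hi, size=(n, 2)), **kw)


class TestEffectivePotential:
    def test_single_bead_is_bare_energy(self, mb):
        p = PathPolymer(np.array([[0.2, 1.0]]))
        assert effective_potential(p, mb) == pytest.approx(
            float(mb.energy(np.array([0.2, 1.0]))))

    def test_zero_extension_springs_vanish(self, mb):
        # beads placed exactly at R_{n+1} = R_n + L_n: only U(R_1) remains
        p0 = np.array([-0.52, 1.47])
        beads = [p0]
        mob = BrownianParams().mobility
        for _ in range(7):
            beads.append(beads[-1] - mob * mb.gradient(beads[-1]))
        poly = PathPolymer(np.array(beads))
        assert effective_potential(poly, mb) == pytest.approx(
            float(mb.energy(p0)), rel=1e-12)

    def test_matches_independent_transcription(self, mb, rng):
        # direct, loop-based rewrite of the polymer energy as oracle
        for _ in range(10):
            poly = random_polymer(rng)
            R = poly.beads
            K = (poly.physical.mass * poly.physical.damping
                 / (2.0 * poly.physical.dt))
            mob = poly.physical.dt / (poly.physical.mass * poly.physical.damping)
            v = float(mb.energy(R[0]))
            for n in range(len(R) - 1):
                L = mob * (-mb.gradient(R[n]))
                d = R[n + 1] - R[n] - L
                v += 0.5 * K * float(d @ d)
            assert effective_potential(poly, mb) == pytest.approx(v, rel=1e-12)


class TestPolymerForces:
    def test_matches_finite_difference_gradient(self, mb, rng):
        h = 1e-6
        for _ in range(10):
            poly = random_polymer(rng, n=5)
            F = polymer_forces(poly, mb)
            for n in range(poly.n_beads):
                for d in range(2):
                    bp = poly.beads.copy()
                    bm = poly.beads.copy()
                    bp[n, d] += h
                    bm[n, d] -= h
                    fd = -(effective_potential(PathPolymer(bp), mb)
                           - effective_potential(PathPolymer(bm), mb)) / (2 * h)
                    assert abs(F[n, d] - fd) < 1e-5

    def test_dropping_hessian_coupling_breaks_forces(self, mb, rng):
        # guard against silently simplifying L_n to a constant: the naive
        # spring-chain gradient must NOT match the finite-difference gradient
        poly = random_polymer(rng, n=5)
        R = poly.beads
        K = poly.spring_k
        mob = poly.physical.mobility
        L = -mob * mb.gradient(R[:-1])
        d = R[1:] - R[:-1] - L
        grad = np.zeros_like(R)
        grad[:-1] += -K * d            # Hessian term omitted
        grad[1:] += K * d
        grad[0] += mb.gradient(R[0])
        naive = -grad
        exact = polymer_forces(poly, mb)
        assert np.max(np.abs(naive - exact)) > 1e-3

    def test_harmonic_reduces_to_linear_operator(self, rng):
        # constant Hessian kI: the force is an explicit linear map of beads
        k = 2.0
        pot = HarmonicWell(k=k, dim=2)
        poly = random_polymer(rng, n=6)
        R = poly.beads
        K = poly.spring_k
        mob = poly.physical.mobility
        a = 1.0 - mob * k              # R_{n+1} - a R_n with L_n = -mob k R_n
        d = R[1:] - a * R[:-1]
        grad = np.zeros_like(R)
        grad[:-1] += K * d * (-a)
        grad[1:] += K * d
        grad[0] += k * R[0]
        assert np.allclose(polymer_forces(poly, pot), -grad, atol=1e-10)

    def test_free_particle_gives_discrete_laplacian(self, zero_potential, rng):
        poly = random_polymer(rng, n=8)
        R = poly.beads
        K = poly.spring_k
        F = polymer_forces(poly, zero_potential)
        interior = K * (R[2:] - 2 * R[1:-1] + R[:-2])
        assert np.allclose(F[1:-1], interior, atol=1e-10)


class TestEndToEndCV:
    def test_identical_endpoints_give_zero(self, two_cluster_cv):
        beads = np.tile([0.3, 0.2], (6, 1))
        poly = PathPolymer(beads)
        S, _, _ = end_to_end_cv(poly, two_cluster_cv)
        assert S == pytest.approx(0.0, abs=1e-14)

    def test_reversal_negates(self, two_cluster_cv, rng):
        poly = random_polymer(rng, n=7)
        S, _, _ = end_to_end_cv(poly, two_cluster_cv)
        Srev, _, _ = end_to_end_cv(PathPolymer(poly.beads[::-1].copy()),
                                   two_cluster_cv)
        assert Srev == pytest.approx(-S, abs=1e-12)

    def test_value_equals_endpoint_difference(self, two_cluster_cv, rng):
        poly = random_polymer(rng, n=4)
        S, g1, gN = end_to_end_cv(poly, two_cluster_cv)
        v1, e1 = two_cluster_cv.value_and_gradient(poly.beads[0])
        vN, eN = two_cluster_cv.value_and_gradient(poly.beads[-1])
        assert S == pytest.approx(vN - v1, abs=1e-12)
        assert np.allclose(g1, e1) and np.allclose(gN, eN)


class TestRelaxation:
    def test_zero_steps_is_identity(self, mb, rng):
        beads = np.tile([-0.5, 1.5], (10, 1))
        poly = relax_polymer(beads, mb, n_steps=0, rng=rng)
        assert np.array_equal(poly.beads, beads)

    def test_free_particle_increment_distribution(self, zero_potential):
        # closed-form path measure: increments are i.i.d. Gaussian with
        # per-component variance 1/(beta K) = 2 kT dt/(m nu)
        rng = np.random.default_rng(99)
        poly = relax_polymer(np.zeros((96, 2)), zero_potential,
                             n_steps=40_000, rng=rng)
        K = poly.spring_k
        var = poly.thermo.kT / K
        inc = np.diff(poly.beads, axis=0) / np.sqrt(var)
        ks = stats.kstest(inc.ravel(), "norm")
        assert ks.pvalue > 0.01

    def test_relaxation_lowers_effective_potential_usually(self, mb):
        # starting from a high-V_eff stretched chain, relaxation should lower
        # V_eff in the overwhelming majority of seeded repeats
        line = np.linspace([-0.52, 1.47], [0.99, 1.18], 24)
        lower = 0
        for seed in range(10):
            v0 = effective_potential(PathPolymer(line.copy()), mb)
            poly = relax_polymer(line.copy(), mb, n_steps=2_000,
                                 rng=np.random.default_rng(seed))
            if effective_potential(poly, mb) < v0:
                lower += 1
        assert lower >= 9

    def test_equilibrium_veff_consistent_with_long_run(self, mb):
        # all-beads-at-minimum start relaxes into the equilibrium V_eff band
        # estimated from the tail of a longer unbiased run
        start = np.tile([-0.521, 1.469], (48, 1))
        rng = np.random.default_rng(4)
        poly = relax_polymer(start.copy(), mb, n_steps=8_000, rng=rng)
        v_end = effective_potential(poly, mb)
        vals = []
        for _ in range(30):
            for _ in range(200):
                pass
            poly = relax_polymer(poly.beads, mb, n_steps=500, rng=rng)
            vals.append(effective_potential(poly, mb))
        mu, sd = np.mean(vals), np.std(vals)
        assert abs(v_end - mu) < 3 * sd + 0.5


class TestRunMop:
    def test_zero_bias_matches_plain_relaxation(self, mb, two_cluster_cv):
        start = np.tile([-0.5, 1.5], (12, 1))
        seed = 31
        base = relax_polymer(start.copy(), mb, n_steps=500,
                             rng=np.random.default_rng(seed))
        poly = PathPolymer(start.copy())
        cfg = BiasConfig(barrier=10.0, pace=10**9, sigma=0.1)   # never deposits
        samples, _ = run_mop(poly, mb, two_cluster_cv, cfg, n_steps=500,
                             stride=500, rng=np.random.default_rng(seed))
        assert np.allclose(samples[-1].beads, base.beads, atol=1e-12)

    def test_samples_store_consistent_veff(self, mb, two_cluster_cv):
        poly = PathPolymer(np.tile([-0.5, 1.5], (12, 1)))
        cfg = BiasConfig(barrier=5.0, pace=50, sigma=0.05)
        samples, _ = run_mop(poly, mb, two_cluster_cv, cfg, n_steps=300,
                             stride=100, rng=np.random.default_rng(0))
        for s in samples:
            recomputed = effective_potential(
                PathPolymer(s.beads, physical=poly.physical,
                            thermo=poly.thermo), mb)
            assert s.v_eff == pytest.approx(recomputed, rel=1e-10)


class TestLowestActionPath:
    def _mk(self, v, S=0.0):
        return PathSample(beads=np.zeros((2, 2)), v_eff=v, S=S, step=0)

    def test_single_sample_returns_itself(self):
        s = self._mk(1.0)
        assert lowest_action_path([s]) is s

    def test_ranking_invariant_under_monotone_rescale(self, rng):
        vals = rng.uniform(-5, 5, 20)
        samples = [self._mk(v) for v in vals]
        best = lowest_action_path(samples)
        best_scaled = lowest_action_path(
            [self._mk(10 * v) for v in vals])
        assert best.v_eff * 10 == pytest.approx(best_scaled.v_eff)

    def test_filter_applies_before_minimum(self):
        samples = [self._mk(0.0, S=0.0), self._mk(5.0, S=1.5)]
        best = lowest_action_path(samples, predicate=lambda s: abs(s.S) >= 1)
        assert best.S == 1.5

    def test_empty_after_filter_raises(self):
        with pytest.raises(ValueError):
            lowest_action_path([self._mk(0.0)], predicate=lambda s: False)
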