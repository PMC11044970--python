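"""Well-tempered kernel deposition and free-energy estimation."""

import numpy as np
import pytest

from mopcv.bias import (BiasConfig, BiasState, EmptyRegionError,
                        bias_value_and_derivative, deposit, estimate_delta_f)
from mopcv.dynamics import BrownianParams, Trajectory, run_simulation
from mopcv.potentials import (DoubleWellIn2D, RegionSpec, ThermoParams,
                              delta_f_quadrature)

LEFT = RegionSpec(lambda x, y: x < 0, "left")
RIGHT = RegionSpec(lambda x, y: x > 0, "right")


class XCoordinate:
    def value_and_gradient(self, r):
        return float(r[0]), np.array([1.0, 0.0])


def test_empty_state_is_zero():
    assert bias_value_and_derivative(BiasState(), 0.37) == (0.0, 0.0)


def test_single_kernel_peak():
    state = BiasState()
    state._append(center=0.5, width=0.1, height=0.3)
    v, dv = state.value_and_derivative(0.5)
    assert v == pytest.approx(0.3)
    assert dv == pytest.approx(0.0, abs=1e-14)


def test_derivative_matches_finite_differences(rng):
    state = BiasState()
    for c, w, h in zip(rng.uniform(-1, 1, 15), rng.uniform(0.05, 0.3, 15),
                       rng.uniform(0.01, 0.2, 15)):
        state._append(c, w, h)
    h_fd = 1e-6
    for s in rng.uniform(-1.2, 1.2, 20):
        _, dv = state.value_and_derivative(s)
        v_p, _ = state.value_and_derivative(s + h_fd)
        v_m, _ = state.value_and_derivative(s - h_fd)
        assert dv == pytest.approx((v_p - v_m) / (2 * h_fd), abs=1e-6)


def test_cached_evaluation_tracks_exact(rng):
    state = BiasState()
    cfg = BiasConfig(barrier=5.0, sigma=0.05)
    thermo = ThermoParams(0.1)
    for s in rng.uniform(-0.8, 0.8, 50):
        state.deposit(s, cfg, thermo)
    h = state._grid_ds
    for s in rng.uniform(-1.0, 1.0, 50):
        v, dv = state.value_and_derivative(s)
        vc, dvc = state.cached_value_and_derivative(s)
        assert vc == pytest.approx(v, abs=1e-4)
        # the cached derivative is the exact slope of the cached piecewise-
        # linear potential (so sampling forces and recorded energies agree);
        # it tracks the analytic derivative to within one grid cell of slope
        v_p, _ = state.cached_value_and_derivative(s + h)
        v_m, _ = state.cached_value_and_derivative(s - h)
        assert dvc == pytest.approx((v_p - v_m) / (2 * h), abs=abs(dv) * 0.2 + 1.0)
        assert dvc == pytest.approx(dv, abs=abs(dv) * 0.1 + 2.0)


def test_first_deposit_has_height_h0(thermo):
    state = BiasState()
    cfg = BiasConfig(barrier=10.0, sigma=0.1, height=0.07)
    deposit(state, 0.0, cfg, thermo)
    assert state.kernels[2][0] == pytest.approx(0.07)


def test_repeated_deposit_heights_decay_geometrically(thermo):
    # closed-form recursion at a fixed point: V_{n+1} = V_n + h_n,
    # h_n = h0 exp(-V_n / ((gamma-1) kT)); first-order ratio h1/h0
    cfg = BiasConfig(barrier=100.0, sigma=0.05, height=0.01, bias_factor=11.0)
    state = BiasState()
    for _ in range(10):
        deposit(state, 0.0, cfg, thermo)
    h = state.kernels[2]
    expected_ratio = np.exp(-cfg.height / ((cfg.bias_factor - 1) * thermo.kT))
    ratios = h[1:] / h[:-1]
    assert np.all(ratios < 1.0)
    assert np.all(np.diff(h) < 0)
    assert ratios[0] == pytest.approx(expected_ratio, rel=1e-2)


def test_total_bias_capped_by_barrier(thermo):
    cfg = BiasConfig(barrier=0.5, sigma=0.1, height=0.2)
    state = BiasState()
    for _ in range(100):
        deposit(state, 0.0, cfg, thermo)
    v, _ = state.value_and_derivative(0.0)
    assert v <= cfg.barrier + cfg.height


@pytest.fixture(scope="module")
def biased_double_well_run():
    pot = DoubleWellIn2D(barrier=1.0, k_transverse=4.0)
    thermo = ThermoParams(0.1)
    params = BrownianParams(damping=10.0, dt=0.01, seed=21)
    cfg = BiasConfig(barrier=2.5, pace=100, sigma=0.1, height=0.05)
    bias = BiasState()
    traj = run_simulation(pot, np.array([-1.0, 0.0]), params, thermo, 300_000,
                          bias=bias, cv=XCoordinate(), bias_config=cfg,
                          stride=20, rng=np.random.default_rng(21))
    return pot, thermo, cfg, bias, traj


def test_flat_biased_marginal_in_double_well(biased_double_well_run):
    # converged well-tempered bias ⇒ F(s) + V(s) roughly constant over the
    # explored range (within the barrier window)
    pot, thermo, cfg, bias, traj = biased_double_well_run
    grid = np.linspace(-1.2, 1.2, 121)
    line = np.stack([grid, np.zeros_like(grid)], axis=-1)
    F = pot.energy(line)
    gamma = cfg.gamma(thermo)
    total = F + bias.value(grid) * gamma / (gamma - 1.0)
    spread = total.max() - total.min()
    assert spread < 1.0 * thermo.kT + 0.35   # ~flat on the 1 energy-unit barrier


def test_reweighted_delta_f_matches_quadrature(biased_double_well_run):
    pot, thermo, cfg, bias, traj = biased_double_well_run
    ref = delta_f_quadrature(pot, LEFT, RIGHT, thermo,
                             box=((-2.2, 2.2), (-1.5, 1.5)))
    est, err = estimate_delta_f(traj, LEFT, RIGHT, thermo, burn_in=0.2)
    assert est == pytest.approx(ref, abs=max(2 * err, 0.6))


def test_unbiased_trajectory_delta_f(rng):
    # low barrier, unbiased sampling visits both wells; ΔF from raw counts
    pot = DoubleWellIn2D(barrier=0.15, k_transverse=4.0)
    thermo = ThermoParams(0.1)
    params = BrownianParams(damping=10.0, dt=0.01, seed=9)
    traj = run_simulation(pot, np.array([-1.0, 0.0]), params, thermo,
                          400_000, stride=20, rng=rng)
    ref = delta_f_quadrature(pot, LEFT, RIGHT, thermo,
                             box=((-2.8, 2.8), (-1.5, 1.5)))
    est, err = estimate_delta_f(traj, LEFT, RIGHT, thermo)
    assert est == pytest.approx(ref, abs=max(3 * err, 0.5))


def test_delta_f_invariant_under_constant_bias_shift(biased_double_well_run):
    pot, thermo, cfg, bias, traj = biased_double_well_run
    est, _ = estimate_delta_f(traj, LEFT, RIGHT, thermo)
    shifted = Trajectory(positions=traj.positions, cv_values=traj.cv_values,
                         bias_values=traj.bias_values + 5.0,
                         stride=traj.stride, dt=traj.dt)
    est2, _ = estimate_delta_f(shifted, LEFT, RIGHT, thermo)
    assert est2 == pytest.approx(est, abs=1e-9)


def test_unvisited_region_raises(thermo):
    traj = Trajectory(positions=np.tile([-1.0, 0.0], (50, 1)))
    with pytest.raises(EmptyRegionError, match="right"):
        estimate_delta_f(traj, LEFT, RIGHT, thermo)


def test_fes_from_bias_shape(biased_double_well_run):
    pot, thermo, cfg, bias, traj = biased_double_well_run
    grid = np.linspace(-1.3, 1.3, 200)
    fes = bias.estimate_fes(grid, cfg, thermo)
    assert fes.min() == 0.0
    # wells near +-1 must be low, the origin barrier high
    barrier_idx = np.argmin(np.abs(grid))
    well_idx = np.argmin(np.abs(grid - 1.0))
    assert fes[barrier_idx] > fes[well_idx]
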