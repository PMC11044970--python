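"""End-to-end study recipes on the built-in model potential.

These functions wire the library together for the standard numerical
experiments: unbiased basin sampling, multi-state neural CVs trained from
that data, a stratified-window free-energy profile along the transition
path, and the biased configuration-space run whose reweighted free-energy
difference is compared against the quadrature reference. They are used by
the example scripts and the acceptance entry point.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .bias import BiasState, estimate_delta_f_pooled
from .deeptda import StateDataset, TDATargets, TrainingConfig, train_cv
from .dynamics import BrownianParams, Trajectory, run_simulation
from .potentials import (MullerBrown, REGION_A, REGION_C, ThermoParams,
                         delta_f_quadrature, find_minima)

#: The three metastable minima of the modified surface, ordered along the
#: transition path (initial A, intermediate B, final C); refined at import
#: cost by the tests that need extra precision.
MB_MINIMA = {
    "A": np.array([-0.520858, 1.469006]),
    "B": np.array([0.001481, 0.512697]),
    "C": np.array([0.987891, 1.182877]),
}


def mb_study(seed: int = 0):
    """Standard objects for the 2D benchmark: potential, thermo, dynamics."""
    return (MullerBrown(), ThermoParams(0.1),
            BrownianParams(mass=1.0, damping=10.0, dt=0.01, seed=seed))


def sample_basins(seed: int = 0, n_steps: int = 30_000, stride: int = 5,
                  basins: tuple[str, ...] = ("A", "B", "C")) -> StateDataset:
    """Unbiased configuration clouds in the requested basins, labelled 0..k."""
    pot, thermo, dyn = mb_study(seed)
    rng = np.random.default_rng(seed)
    parts = []
    for k, name in enumerate(basins):
        traj = run_simulation(pot, MB_MINIMA[name], dyn, thermo, n_steps,
                              stride=stride, rng=rng)
        X = traj.positions[1:]
        parts.append(StateDataset(X, np.full(len(X), k)))
    return StateDataset.concatenate(parts)


#: Index-1 saddle between the initial basin and the intermediate one.
SADDLE_AB = np.array([-0.8024, 0.6708])


def sample_transition_region(seed: int = 0, n_runs: int = 150,
                             n_steps: int = 120, u_floor: float = -8.0) -> np.ndarray:
    """Configurations in the corridor around the A–B saddle.

    Short unbiased runs seeded at the saddle fall off along the unstable
    direction; frames are kept while their energy stays above ``u_floor``
    (well above both basin floors), which traces out the transition region.
    """
    pot, thermo, dyn = mb_study(seed)
    rng = np.random.default_rng((seed, 7))
    frames = []
    for _ in range(n_runs):
        start = SADDLE_AB + 0.02 * rng.standard_normal(2)
        traj = run_simulation(pot, start, dyn, thermo, n_steps, stride=2,
                              rng=rng)
        X = traj.positions
        keep = pot.energy(X) >= u_floor
        frames.append(X[keep])
    return np.concatenate(frames)


def train_four_state_cv(seed: int = 0, cap: int = 6000):
    """The transition-state-augmented CV the converged estimate relies on.

    States ordered along the path — initial basin, A–B transition corridor,
    intermediate basin, final basin — with a deliberately broad latent target
    for the corridor. Without the corridor state, the 1D CV lumps the highest
    saddle with basin rims at the same CV value and biased crossings stall.
    """
    basins = sample_basins(seed)
    ts = sample_transition_region(seed)
    rng = np.random.default_rng(seed)
    parts, labels = [], []
    order = [("A", 0), ("TS", 1), ("B", 2), ("C", 3)]
    pools = {"A": basins.X[basins.labels == 0],
             "B": basins.X[basins.labels == 1],
             "C": basins.X[basins.labels == 2],
             "TS": ts}
    for name, lab in order:
        X = pools[name]
        if len(X) > cap:
            X = X[rng.choice(len(X), cap, replace=False)]
        parts.append(X)
        labels.append(np.full(len(X), lab))
    ds = StateDataset(np.concatenate(parts), np.concatenate(labels))
    return train_cv(ds, TDATargets.four_state(),
                    TrainingConfig(seed=seed, max_epochs=1500))


def train_three_state_cv(seed: int = 0, cap: int = 6000):
    """A CV resolving all three metastable states, from unbiased data only."""
    data = sample_basins(seed)
    rng = np.random.default_rng(seed)
    keep = []
    for k in np.unique(data.labels):
        idx = np.flatnonzero(data.labels == k)
        if len(idx) > cap:
            idx = rng.choice(idx, cap, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    ds = StateDataset(data.X[keep], data.labels[keep])
    return train_cv(ds, TDATargets.three_state(),
                    TrainingConfig(seed=seed, max_epochs=1500))


def umbrella_fes(seed: int, cv, pot, thermo, dyn,
                 n_windows: int = 121, kappa: float = 400.0,
                 equil_steps: int = 10_000, sample_steps: int = 120_000,
                 stride: int = 5, span: float = 0.98,
                 tube_radius: float = 0.15,
                 n_bins: int = 800) -> tuple[np.ndarray, np.ndarray]:
    """Free-energy profile F(s) along a path CV by umbrella windows + WHAM.

    Harmonic restraints 0.5 κ (s - s0)² are placed on ``n_windows`` centers
    spanning the CV axis; each window is initialized at the reference-path
    point with matching progress value and confined to a narrow tube around
    the path (a hard-wall term independent of s, which WHAM simply treats
    as part of the potential). The tube keeps every stratum a small
    connected patch, so windows equilibrate quickly and the stitched
    profile is well defined; the basins lie on the path, so the tube
    excludes only negligible Boltzmann mass. Returns (bin centers, F in
    energy units, min-shifted over sampled bins).
    """
    from . import _fastpath
    mb = _fastpath.mb_arrays(pot)
    P, T = cv.points, cv.t
    rng = np.random.default_rng((seed, 11))
    sig = np.sqrt(2.0 * thermo.kT * dyn.mobility)
    centers0 = np.linspace(-span, span, n_windows)
    edges = np.linspace(-1.1, 1.1, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros((n_windows, n_bins))
    for k in range(n_windows):
        s0 = centers0[k]
        R = P[np.argmin(np.abs(T - s0))].copy()
        out_s = np.empty(sample_steps // stride)
        noise = rng.standard_normal((equil_steps, 2)) * sig
        _fastpath.umbrella_window_path(R, noise, *mb, dyn.mobility, P, T,
                                       cv.lam, tube_radius**2, 5000.0,
                                       kappa, s0, np.empty(1),
                                       equil_steps + 1)
        noise = rng.standard_normal((sample_steps, 2)) * sig
        _fastpath.umbrella_window_path(R, noise, *mb, dyn.mobility, P, T,
                                       cv.lam, tube_radius**2, 5000.0,
                                       kappa, s0, out_s, stride)
        counts[k], _ = np.histogram(out_s, bins=edges)
    beta = thermo.beta
    w_ks = 0.5 * kappa * (mids[None, :] - centers0[:, None]) ** 2
    b_ks = np.exp(-beta * w_ks)
    N_k = counts.sum(axis=1)
    f = np.ones(n_windows)
    num = counts.sum(axis=0)
    for _ in range(20000):
        denom = (N_k * f) @ b_ks
        p = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
        f_new = 1.0 / np.maximum(b_ks @ p, 1e-300)
        if np.max(np.abs(np.log(f_new / f))) < 1e-10:
            f = f_new
            break
        f = f_new
    with np.errstate(divide="ignore"):
        F = -thermo.kT * np.log(np.maximum(p, 1e-300))
    good = p > 0
    # unsampled bins (outside the window span) take interpolated values so
    # the profile stays Lipschitz; they carry negligible weight anyway
    F = np.interp(mids, mids[good], F[good])
    return mids, F - F.min()


def biased_delta_f(seed: int = 0, production_steps: int = 1_200_000,
                   n_walkers: int = 12) -> dict:
    """One enhanced-sampling estimate of ΔF(A→C) on the model potential.

    The bias acts on a geometric progress variable along the A→B→C
    transition path (monotone along the route by construction). Its profile
    is converged first — umbrella windows along the CV combined by WHAM
    give F(s), and the static bias V(s) = max F - F(s) makes the biased CV
    marginal flat. Several walkers (half from each endpoint basin) then
    sample the static biased ensemble; region indicators reweighted by
    exp(+βV) give ΔF in k_B T with a 10-time-block standard error.
    """
    from . import _fastpath
    from .pathcv import mb_transition_path
    pot, thermo, dyn = mb_study(seed)
    cv = mb_transition_path(pot, thermo)
    mids, F = umbrella_fes(seed, cv, pot, thermo, dyn)
    bias = BiasState(grid_range=(-1.1, 1.1))
    bias.add_table(np.interp(bias.grid, mids, F.max() - F))
    rng = np.random.default_rng((seed, 101))
    half = n_walkers // 2
    starts = np.concatenate([
        MB_MINIMA["A"] + 0.02 * rng.standard_normal((n_walkers - half, 2)),
        MB_MINIMA["C"] + 0.02 * rng.standard_normal((half, 2))])
    mb = _fastpath.mb_arrays(pot)
    sig = np.sqrt(2.0 * thermo.kT * dyn.mobility)
    stride = 20
    n_frames = production_steps // stride
    m = len(starts)
    out_pos = np.empty((n_frames, m, 2))
    out_s = np.empty((n_frames, m))
    out_v = np.empty((n_frames, m))
    R = starts.copy()
    done = 0
    frame = 0
    while done < production_steps:
        chunk = min(100_000, production_steps - done)
        chunk -= chunk % stride
        noise = rng.standard_normal((chunk, m, 2)) * sig
        nf = chunk // stride
        _fastpath.walker_chunk_path(R, noise, *mb, dyn.mobility,
                                    cv.points, cv.t,
                                    cv.lam, 0.15**2, 5000.0,
                                    bias._grid_v, bias._grid_dv,
                                    bias._grid_lo, bias._grid_ds,
                                    out_pos[frame:frame + nf],
                                    out_s[frame:frame + nf],
                                    out_v[frame:frame + nf], stride)
        done += chunk
        frame += nf
    prod = [Trajectory(positions=out_pos[:, i], cv_values=out_s[:, i],
                       bias_values=out_v[:, i], stride=stride, dt=dyn.dt)
            for i in range(m)]
    est, err = estimate_delta_f_pooled(prod, REGION_A, REGION_C, thermo,
                                       burn_in=0.2)
    return {"delta_f_kT": est, "stderr_kT": err,
            "n_steps": production_steps, "n_kernels": bias.n_kernels,
            "trajectories": prod, "bias": bias, "cv": cv,
            "fes": (mids, F)}


def quadrature_reference() -> float:
    """ΔF(A→C) of the benchmark surface in k_B T by direct integration."""
    pot, thermo, _ = mb_study()
    return delta_f_quadrature(pot, REGION_A, REGION_C, thermo)
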