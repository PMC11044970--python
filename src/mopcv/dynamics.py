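"""Stochastic integrators for configuration-space sampling.

The package standardizes on overdamped (Brownian) dynamics,

    R' = R + (Δt / m ν) F(R) + ξ,   ξ ~ N(0, 2 k_B T Δt / (m ν)),

in both configuration space and trajectory space, because the elastic-polymer
path measure sampled by the ``mop`` module is exactly the distribution of
discrete Brownian trajectories generated by this propagator. An underdamped
BAOAB integrator is available for qualitative comparison only.

Biased runs add the chain-rule force ``-dV_bias/ds · ∇s(R)`` from an adaptive
bias acting on a scalar collective variable s(R).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .potentials import PotentialSurface, ThermoParams


@dataclass(frozen=True)
class BrownianParams:
    """Physical parameters of the overdamped dynamics (natural units)."""

    mass: float = 1.0
    damping: float = 10.0      # ν, 1/time
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mass", "damping", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def mobility(self) -> float:
        """Δt / (m ν): displacement per unit force per step."""
        return self.dt / (self.mass * self.damping)


@dataclass
class Trajectory:
    """Strided record of a configuration-space run."""

    positions: np.ndarray                 # (n_frames, d)
    cv_values: Optional[np.ndarray] = None    # (n_frames,)
    bias_values: Optional[np.ndarray] = None  # (n_frames,) instantaneous V_bias(s)
    stride: int = 1
    dt: float = 0.01

    def __post_init__(self) -> None:
        n = len(self.positions)
        for arr in (self.cv_values, self.bias_values):
            if arr is not None and len(arr) != n:
                raise ValueError("trajectory arrays must have congruent lengths")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.positions)) * self.stride * self.dt

    def __len__(self) -> int:
        return len(self.positions)


def brownian_step(state: np.ndarray, force: np.ndarray, params: BrownianParams,
                  thermo: ThermoParams, rng: np.random.Generator) -> np.ndarray:
    """One Euler–Maruyama update of the overdamped Langevin equation.

    Works on a single configuration (d,) or a batch of walkers (n, d).
    """
    force = np.asarray(force, dtype=float)
    if not np.all(np.isfinite(force)):
        raise FloatingPointError("non-finite force in brownian_step")
    state = np.asarray(state, dtype=float)
    sigma = np.sqrt(2.0 * thermo.kT * params.mobility)
    noise = rng.standard_normal(state.shape) * sigma if sigma > 0 else 0.0
    return state + params.mobility * force + noise


def run_simulation(potential: PotentialSurface,
                   start: np.ndarray,
                   params: BrownianParams,
                   thermo: ThermoParams,
                   n_steps: int,
                   bias=None,
                   cv=None,
                   bias_config=None,
                   stride: int = 100,
                   rng: Optional[np.random.Generator] = None) -> Trajectory:
    """Run (optionally biased) overdamped dynamics and record a Trajectory.

    When ``bias`` (a ``BiasState``) is given, ``cv`` must provide
    ``value_and_gradient(R) -> (s, ds/dR)``; the total force is the physical
    force plus ``-dV_bias/ds · ∇s``. If ``bias_config`` is also given, new
    kernels are deposited every ``bias_config.pace`` steps (the state is
    mutated in place). CV and instantaneous bias are recorded every ``stride``
    steps. Deterministic for a fixed ``rng`` seed.
    """
    if bias is not None and cv is None:
        raise ValueError("a bias requires a CV to act on")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    R = np.array(start, dtype=float)
    n_frames = n_steps // stride + 1
    pos = np.empty((n_frames, R.shape[-1]))
    cvs = np.empty(n_frames) if cv is not None else None
    biases = np.empty(n_frames) if bias is not None else None
    from collections import deque
    sigma_window: deque = deque(maxlen=10 * (bias_config.pace if bias_config
                                             else 100))

    def record(frame: int) -> None:
        pos[frame] = R
        if cv is not None:
            s, _ = cv.value_and_gradient(R)
            cvs[frame] = s
            if bias is not None:
                biases[frame], _ = bias.cached_value_and_derivative(s)

    record(0)
    frame = 1
    for step in range(1, n_steps + 1):
        force = potential.force(R)
        if bias is not None:
            s, grad_s = cv.value_and_gradient(R)
            if not np.all(np.isfinite(grad_s)):
                raise FloatingPointError(f"non-finite CV gradient at step {step}")
            _, dvds = bias.cached_value_and_derivative(s)
            force = force - dvds * grad_s
            if bias_config is not None:
                sigma_window.append(s)
                if step % bias_config.pace == 0:
                    width = None
                    if bias_config.adaptive_sigma:
                        width = float(np.std(sigma_window))
                    bias.deposit(s, bias_config, thermo, width=width)
        R = brownian_step(R, force, params, thermo, rng)
        if step % stride == 0:
            record(frame)
            frame += 1
    return Trajectory(positions=pos, cv_values=cvs, bias_values=biases,
                      stride=stride, dt=params.dt)


def run_multiwalker(potential: PotentialSurface,
                    starts: np.ndarray,
                    params: BrownianParams,
                    thermo: ThermoParams,
                    n_steps: int,
                    bias=None,
                    cv=None,
                    bias_config=None,
                    stride: int = 20,
                    rng: Optional[np.random.Generator] = None) -> list[Trajectory]:
    """Several walkers sharing one adaptive bias (multiple-walker filling).

    All walkers advance in lockstep; every ``pace`` steps one kernel is
    deposited at each walker's CV value into the shared ``bias``. With
    ``bias_config=None`` the bias (if any) is static and the walkers sample
    the frozen biased ensemble — the standard two-stage fill/production
    scheme. Returns one Trajectory per walker.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    R = np.atleast_2d(np.array(starts, dtype=float)).copy()
    m, d = R.shape
    n_frames = n_steps // stride + 1
    pos = np.empty((n_frames, m, d))
    cvs = np.empty((n_frames, m)) if cv is not None else None
    biases = np.empty((n_frames, m)) if bias is not None else None

    from . import _fastpath
    if (bias_config is None and bias is not None and cv is not None
            and _fastpath.applicable(potential, cv) and d == 2):
        # static-bias batch: compiled inner loop
        pos[0] = R
        s0, _ = cv.values_and_gradients(R)
        cvs[0] = s0
        biases[0] = [bias.cached_value_and_derivative(sv)[0] for sv in s0]
        sig = np.sqrt(2.0 * thermo.kT * params.mobility)
        mb = _fastpath.mb_arrays(potential)
        nn = _fastpath.nn_arrays(cv)
        out_pos = pos[1:]
        out_s = cvs[1:]
        out_v = biases[1:]
        done = 0
        frame = 0
        while done < n_steps:
            chunk = min(50_000 // max(m, 1) * stride, n_steps - done)
            chunk -= chunk % stride
            chunk = max(chunk, min(stride, n_steps - done))
            noise = rng.standard_normal((chunk, m, d)) * sig
            nf = chunk // stride
            _fastpath.walker_chunk(R, noise, *mb, params.mobility, *nn,
                                   bias._grid_v, bias._grid_dv,
                                   bias._grid_lo, bias._grid_ds,
                                   out_pos[frame:frame + nf],
                                   out_s[frame:frame + nf],
                                   out_v[frame:frame + nf], stride)
            done += chunk
            frame += nf
        return [Trajectory(positions=pos[:, i], cv_values=cvs[:, i],
                           bias_values=biases[:, i], stride=stride,
                           dt=params.dt)
                for i in range(m)]

    def cv_batch(R):
        if hasattr(cv, "values_and_gradients"):
            return cv.values_and_gradients(R)
        vals = np.empty(m)
        grads = np.empty_like(R)
        for i in range(m):
            vals[i], grads[i] = cv.value_and_gradient(R[i])
        return vals, grads

    def record(frame):
        pos[frame] = R
        if cv is not None:
            svals, _ = cv_batch(R)
            cvs[frame] = svals
            if bias is not None:
                biases[frame] = [bias.cached_value_and_derivative(s)[0]
                                 for s in svals]

    record(0)
    frame = 1
    for step in range(1, n_steps + 1):
        force = potential.force(R)
        if bias is not None and cv is not None:
            svals, grads = cv_batch(R)
            for i in range(m):
                _, dvds = bias.cached_value_and_derivative(svals[i])
                force[i] -= dvds * grads[i]
            if bias_config is not None and step % bias_config.pace == 0:
                for i in range(m):
                    bias.deposit(svals[i], bias_config, thermo)
        R = brownian_step(R, force, params, thermo, rng)
        if step % stride == 0:
            record(frame)
            frame += 1
    return [Trajectory(positions=pos[:, i], 
                       cv_values=None if cvs is None else cvs[:, i],
                       bias_values=None if biases is None else biases[:, i],
                       stride=stride, dt=params.dt)
            for i in range(m)]


def run_baoab(potential: PotentialSurface, start: np.ndarray,
              params: BrownianParams, thermo: ThermoParams, n_steps: int,
              stride: int = 100,
              rng: Optional[np.random.Generator] = None) -> Trajectory:
    """Underdamped Langevin (BAOAB splitting); qualitative comparison only."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    R = np.array(start, dtype=float)
    v = np.zeros_like(R)
    m, dt, nu = params.mass, params.dt, params.damping
    c1 = np.exp(-nu * dt)
    c2 = np.sqrt(thermo.kT / m * (1.0 - c1**2))
    n_frames = n_steps // stride + 1
    pos = np.empty((n_frames, R.shape[-1]))
    pos[0] = R
    frame = 1
    F = potential.force(R)
    for step in range(1, n_steps + 1):
        v = v + 0.5 * dt * F / m
        R = R + 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(R.shape)
        R = R + 0.5 * dt * v
        F = potential.force(R)
        v = v + 0.5 * dt * F / m
        if step % stride == 0:
            pos[frame] = R
            frame += 1
    return Trajectory(positions=pos, stride=stride, dt=dt)
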