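"""Trajectory-space sampling via the elastic-polymer isomorphism.

A discrete overdamped trajectory R_1 → R_2 → … → R_N carries the Boltzmann-like
weight exp(-β V_eff) of a fictitious elastic polymer,

    V_eff = U(R_1) + Σ_{n=1}^{N-1} (K/2) |R_{n+1} - R_n - L_n|²,

with spring constant K = mν/(2Δt) and equilibrium extensions
L_n = (Δt/mν) F_n set by the physical force F_n = -∇U(R_n). Sampling the
polymer at temperature T therefore samples whole trajectories in proportion
to their path probability: the Onsager–Machlup action is monotone in V_eff.

The polymer beads evolve under their own overdamped Langevin dynamics with
forces -∇_{R_n} V_eff; because L_n depends on R_n, these forces pick up a
Hessian coupling that a naive spring-chain gradient misses. An adaptive bias
on the generalized end-to-end distance S = s(R_N) - s(R_1) — the difference
of a configuration-space CV at the endpoints — steers sampling toward
elongated (reactive) polymers while leaving interior beads free to relax
toward low-action tubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .bias import BiasConfig, BiasState
from .dynamics import BrownianParams
from .potentials import NonFiniteEnergyError, PotentialSurface, ThermoParams


@dataclass
class PathPolymer:
    """An ordered chain of bead configurations representing one trajectory.

    ``physical`` holds the Brownian parameters of the *underlying* dynamics
    (they define K and L_n and are part of the path measure); the fictitious
    sampling dynamics of the polymer itself has its own time step and damping.
    """

    beads: np.ndarray                       # (N, d)
    physical: BrownianParams = field(default_factory=BrownianParams)
    thermo: ThermoParams = field(default_factory=ThermoParams)
    dt_poly: float = 0.01
    damping_poly: float = 100.0
    mass_poly: float = 1.0

    def __post_init__(self) -> None:
        self.beads = np.atleast_2d(np.asarray(self.beads, dtype=float))
        if len(self.beads) < 1:
            raise ValueError("a polymer needs at least one bead")

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def spring_k(self) -> float:
        """Effective spring constant K = mν/(2Δt), recomputed on access."""
        p = self.physical
        return p.mass * p.damping / (2.0 * p.dt)

    @property
    def poly_mobility(self) -> float:
        return self.dt_poly / (self.mass_poly * self.damping_poly)


@dataclass(frozen=True)
class PathSample:
    """A saved polymer snapshot with its action surrogate and end-to-end CV."""

    beads: np.ndarray
    v_eff: float
    S: float
    step: int


def _springs(polymer: PathPolymer, potential: PotentialSurface,
             grads: Optional[np.ndarray] = None):
    """Spring extension vectors d_n = R_{n+1} - R_n - L_n, and L coefficients."""
    R = polymer.beads
    mob = polymer.physical.mobility     # Δt/(mν)
    if grads is None:
        grads = potential.gradient(R[:-1])  # ∇U at beads 1..N-1
    L = -mob * grads                    # L_n = (Δt/mν) F_n
    d = R[1:] - R[:-1] - L
    return d, mob


def effective_potential(polymer: PathPolymer, potential: PotentialSurface) -> float:
    """V_eff = U(R_1) + Σ (K/2)|R_{n+1} - R_n - L_n|²."""
    R = polymer.beads
    try:
        u1 = float(potential.energy(R[0]))
    except NonFiniteEnergyError as exc:
        raise NonFiniteEnergyError(f"non-finite energy at bead 0: {exc}") from exc
    if polymer.n_beads == 1:
        return u1
    d, _ = _springs(polymer, potential)
    return u1 + 0.5 * polymer.spring_k * float(np.sum(d * d))


def polymer_forces(polymer: PathPolymer, potential: PotentialSurface) -> np.ndarray:
    """Exact bead forces -∇_{R_n} V_eff, including the Hessian coupling.

    With d_n = R_{n+1} - R_n - L_n the gradient w.r.t. bead n is

        ∇_{R_n} V_eff = K d_{n-1} + K (-I + (Δt/mν) H(R_n)) d_n
                        (+ ∇U(R_1) on the first bead),

    where the Hessian term comes from L_n's dependence on R_n. The last bead
    only feels K d_{N-1}.
    """
    R = polymer.beads
    N, dim = R.shape
    if N == 1:
        return -potential.gradient(R[0])[None, :]
    K = polymer.spring_k
    _, g, H = potential.derivs(R[:-1])  # fused evaluation at beads 1..N-1
    d, mob = _springs(polymer, potential, grads=g)
    grad = np.zeros_like(R)
    # term n couples beads n and n+1 (0-based: d[n] couples R[n], R[n+1]);
    # H @ d written out per component (faster than einsum for small dims)
    Hd = np.empty_like(d)
    if dim == 2:
        Hd[:, 0] = H[:, 0, 0] * d[:, 0] + H[:, 0, 1] * d[:, 1]
        Hd[:, 1] = H[:, 1, 0] * d[:, 0] + H[:, 1, 1] * d[:, 1]
    else:
        Hd = np.einsum("nij,nj->ni", H, d)
    coup = -d + mob * Hd
    grad[:-1] += K * coup
    grad[1:] += K * d
    grad[0] += g[0]
    return -grad


def end_to_end_cv(polymer: PathPolymer, cv_model) -> tuple[float, np.ndarray, np.ndarray]:
    """S = s(R_N) - s(R_1) and ∇s at the two endpoints.

    Returns (S, grad_first, grad_last) where ∂S/∂R_1 = -grad_first and
    ∂S/∂R_N = grad_last; all interior beads have zero CV gradient.
    """
    ends = polymer.beads[[0, -1]]
    if hasattr(cv_model, "values_and_gradients"):
        (s1, sN), (g1, gN) = cv_model.values_and_gradients(ends)
    else:
        s1, g1 = cv_model.value_and_gradient(ends[0])
        sN, gN = cv_model.value_and_gradient(ends[1])
    return sN - s1, g1, gN


def _polymer_step(polymer: PathPolymer, forces: np.ndarray,
                  rng: np.random.Generator, noise_sigma: float) -> None:
    polymer.beads += polymer.poly_mobility * forces
    if noise_sigma > 0:
        polymer.beads += rng.standard_normal(polymer.beads.shape) * noise_sigma


def _noise_sigma(polymer: PathPolymer) -> float:
    return np.sqrt(2.0 * polymer.thermo.kT * polymer.poly_mobility)


def relax_polymer(initial_beads: np.ndarray, potential: PotentialSurface,
                  n_steps: int = 10_000,
                  physical: Optional[BrownianParams] = None,
                  thermo: Optional[ThermoParams] = None,
                  rng: Optional[np.random.Generator] = None,
                  **poly_kwargs) -> PathPolymer:
    """Unbiased polymer Langevin evolution from an initial bead array.

    The conventional initial condition places every bead at one configuration
    (a fully crumpled polymer); relaxation equilibrates the chain toward the
    unbiased path measure before any bias is switched on.
    """
    polymer = PathPolymer(np.array(initial_beads, dtype=float),
                          physical=physical or BrownianParams(),
                          thermo=thermo or ThermoParams(), **poly_kwargs)
    rng = np.random.default_rng(polymer.physical.seed) if rng is None else rng
    sig = _noise_sigma(polymer)
    from . import _fastpath
    if _fastpath.applicable(potential, None) and polymer.n_beads > 1:
        mb = _fastpath.mb_arrays(potential)
        zeros24 = np.zeros((2, 24))
        dummy_nn = (zeros24, np.zeros(24), np.zeros((24, 12)), np.zeros(12),
                    np.zeros((12, 1)), np.zeros(1), -1.0, 1.0)
        grid = np.zeros(2)
        done = 0
        while done < n_steps:
            chunk = min(1000, n_steps - done)
            noise = rng.standard_normal((chunk, polymer.n_beads, 2)) * sig
            _fastpath.mop_chunk(polymer.beads, noise, *mb, polymer.spring_k,
                                polymer.physical.mobility,
                                polymer.poly_mobility, *dummy_nn,
                                grid, grid, 0.0, 1.0, False)
            done += chunk
        return polymer
    for _ in range(n_steps):
        _polymer_step(polymer, polymer_forces(polymer, potential), rng, sig)
    return polymer


def run_mop(polymer: PathPolymer, potential: PotentialSurface, cv_model,
            bias_config: BiasConfig, n_steps: int, stride: int = 500,
            bias: Optional[BiasState] = None,
            rng: Optional[np.random.Generator] = None) -> tuple[list[PathSample], BiasState]:
    """Biased trajectory-space sampling; returns saved samples and the bias.

    All beads follow overdamped dynamics under -∇V_eff; the bias acts on the
    end-to-end CV S, so its chain-rule force touches only the first and last
    beads. Kernels are deposited on S every ``bias_config.pace`` steps and a
    ``PathSample`` is captured every ``stride`` steps.
    """
    bias = BiasState() if bias is None else bias
    rng = np.random.default_rng(polymer.physical.seed) if rng is None else rng
    sig = _noise_sigma(polymer)
    samples: list[PathSample] = []

    from . import _fastpath
    if (_fastpath.applicable(potential, cv_model)
            and not bias_config.adaptive_sigma
            and polymer.n_beads > 1
            and stride % bias_config.pace == 0):
        # compiled inner loop: chunks of one deposition period
        mb = _fastpath.mb_arrays(potential)
        nn = _fastpath.nn_arrays(cv_model)
        pace = bias_config.pace
        step = 0
        while step < n_steps:
            chunk = min(pace, n_steps - step)
            noise = rng.standard_normal((chunk, polymer.n_beads, 2)) * sig
            S_dep = _fastpath.mop_chunk(
                polymer.beads, noise, *mb, polymer.spring_k,
                polymer.physical.mobility, polymer.poly_mobility, *nn,
                bias._grid_v, bias._grid_dv, bias._grid_lo, bias._grid_ds,
                True)
            step += chunk
            if chunk == pace:
                bias.deposit(S_dep, bias_config, polymer.thermo)
            if step % stride == 0:
                v = effective_potential(polymer, potential)
                if not np.isfinite(v):
                    raise NonFiniteEnergyError(
                        f"non-finite V_eff at step {step}; beads:\n"
                        f"{polymer.beads}")
                S_now, _, _ = end_to_end_cv(polymer, cv_model)
                samples.append(PathSample(beads=polymer.beads.copy(),
                                          v_eff=v, S=S_now, step=step))
        return samples, bias

    from collections import deque
    window: deque = deque(maxlen=10 * bias_config.pace)   # OPES-style horizon
    for step in range(1, n_steps + 1):
        forces = polymer_forces(polymer, potential)
        S, g1, gN = end_to_end_cv(polymer, cv_model)
        _, dvds = bias.cached_value_and_derivative(S)
        forces[0] += dvds * g1        # ∂S/∂R_1 = -∇s(R_1)
        forces[-1] -= dvds * gN
        window.append(S)
        if step % bias_config.pace == 0:
            width = None
            if bias_config.adaptive_sigma:
                width = float(np.std(window))
            bias.deposit(S, bias_config, polymer.thermo, width=width)
        _polymer_step(polymer, forces, rng, sig)
        if step % stride == 0:
            v = effective_potential(polymer, potential)
            if not np.isfinite(v):
                raise NonFiniteEnergyError(
                    f"non-finite V_eff at step {step}; beads:\n{polymer.beads}")
            S_now, _, _ = end_to_end_cv(polymer, cv_model)
            samples.append(PathSample(beads=polymer.beads.copy(), v_eff=v,
                                      S=S_now, step=step))
    return samples, bias


def lowest_action_path(samples: Sequence[PathSample],
                       predicate: Optional[Callable[[PathSample], bool]] = None
                       ) -> PathSample:
    """The sample with minimal V_eff (the path-action surrogate).

    ``predicate`` optionally restricts the pool, e.g. to reactive paths only.
    """
    pool = [s for s in samples if predicate is None or predicate(s)]
    if not pool:
        raise ValueError("no samples left after filtering")
    return min(pool, key=lambda s: s.v_eff)
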