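"""Adaptive bias on a scalar collective variable and free-energy estimation.

Well-tempered metadynamics: Gaussian kernels are deposited along the CV every
``pace`` steps with heights damped by the accumulated bias,

    h = h0 · exp( -V(s) / ((γ-1) k_B T) ),

so that the bias converges to -(1-1/γ) F(s). A ``barrier`` parameter caps
exploration: kernel heights are clipped to barrier - V(s), so the total bias
can never exceed the ceiling and late deposits act only where the profile is
still under-filled. With a very large γ the rule degenerates to plain
(non-tempered) metadynamics under a ceiling, the mode the trajectory-space
runs use for exploration. The free-energy surface follows from
F(s) = -γ/(γ-1) V(s) + const, and free-energy differences between
configuration-space regions from reweighting recorded frames with weights
∝ exp(+β V_bias(s_t)).

The bias factor γ defaults to 1 + barrier / (5 k_B T), mapping the energy
scale the bias must fill to a tempering strength that keeps late kernels
small but non-negligible. Besides kernels, a tabulated potential defined on
the evaluation grid can be added (``add_table``), which is how externally
converged profiles are installed as a static bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .potentials import RegionSpec, ThermoParams


@dataclass
class BiasConfig:
    """Deposition schedule and kernel parameters (energies in natural units)."""

    barrier: float = 17.0          # cap on accumulated bias, energy units
    pace: int = 300                # steps between depositions
    sigma: float = 0.03            # kernel width in CV units (ignored if adaptive)
    adaptive_sigma: bool = False   # width = CV std over the last window
    bias_factor: Optional[float] = None  # γ; default 1 + barrier/(5 kT)
    height: Optional[float] = None       # h0; default 1 k_B T
    sigma_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.pace < 1:
            raise ValueError("pace must be >= 1")
        if not self.adaptive_sigma and not self.sigma > 0:
            raise ValueError("sigma must be positive (or adaptive)")
        if self.bias_factor is not None and not self.bias_factor > 1:
            raise ValueError("bias factor must exceed 1")

    def gamma(self, thermo: ThermoParams) -> float:
        if self.bias_factor is not None:
            return self.bias_factor
        return 1.0 + self.barrier / (5.0 * thermo.kT)

    def h0(self, thermo: ThermoParams) -> float:
        return self.height if self.height is not None else thermo.kT


class BiasState:
    """Accumulated repulsive Gaussian kernels on a scalar CV.

    Kernel parameters are stored in growable arrays; an optional uniform-grid
    cache of V(s) is maintained for FES output. Evaluation is always the
    exact kernel sum (C¹ in s).
    """

    def __init__(self, grid_range: tuple[float, float] = (-2.5, 2.5),
                 n_grid: int = 8192):
        self._centers: list[float] = []
        self._widths: list[float] = []
        self._heights: list[float] = []
        self._cap = 64
        self._c = np.empty(self._cap)
        self._w = np.empty(self._cap)
        self._h = np.empty(self._cap)
        self.grid = np.linspace(grid_range[0], grid_range[1], n_grid)
        self._grid_lo = float(grid_range[0])
        self._grid_ds = float(self.grid[1] - self.grid[0])
        self._grid_v = np.zeros(n_grid)
        self._grid_dv = np.zeros(n_grid)
        self._table_v = np.zeros(n_grid)   # non-kernel (tabulated) component

    @property
    def n_kernels(self) -> int:
        return len(self._centers)

    @property
    def kernels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = self.n_kernels
        return self._c[:n].copy(), self._w[:n].copy(), self._h[:n].copy()

    def value_and_derivative(self, s: float) -> tuple[float, float]:
        """(V_bias(s), dV_bias/ds): exact kernel sum plus any tabulated part."""
        v = dv = 0.0
        n = self.n_kernels
        if n:
            z = (s - self._c[:n]) / self._w[:n]
            g = self._h[:n] * np.exp(-0.5 * z * z)
            v = float(np.sum(g))
            dv = float(np.sum(-g * z / self._w[:n]))
        if self._table_v.any():
            tv, tdv = self._table_lookup(s)
            v += tv
            dv += tdv
        return v, dv

    def _table_lookup(self, s: float) -> tuple[float, float]:
        x = (s - self._grid_lo) / self._grid_ds
        i = int(x)
        if x < 0:
            return float(self._table_v[0]), 0.0
        if i + 1 >= len(self.grid):
            return float(self._table_v[-1]), 0.0
        f = x - i
        tv = self._table_v[i] * (1 - f) + self._table_v[i + 1] * f
        tdv = (self._table_v[i + 1] - self._table_v[i]) / self._grid_ds
        return float(tv), float(tdv)

    def add_table(self, values: np.ndarray) -> None:
        """Add a tabulated potential (defined on ``self.grid``) to the bias.

        This is how an externally converged free-energy profile is installed
        as a static bias (the update is a curve rather than a kernel).
        """
        values = np.asarray(values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError("table must be defined on the bias grid")
        self._table_v += values
        self._grid_v += values
        self._grid_dv += np.gradient(values, self._grid_ds)

    def cached_value_and_derivative(self, s: float) -> tuple[float, float]:
        """Fast (V, dV/ds) by linear interpolation on the evaluation grid.

        Used in tight sampling loops. Outside the grid window — i.e. beyond
        the CV range the bias is calibrated for — the value is clamped to
        the edge and the derivative is zero, so the bias never pushes a
        walker further into uncalibrated CV territory.
        """
        x = (s - self._grid_lo) / self._grid_ds
        i = int(x)
        if x < 0:
            return float(self._grid_v[0]), 0.0
        if i + 1 >= len(self.grid):
            return float(self._grid_v[-1]), 0.0
        f = x - i
        v = self._grid_v[i] * (1.0 - f) + self._grid_v[i + 1] * f
        # cell slope: the force is the exact derivative of the recorded
        # piecewise-linear potential, so sampling and reweighting agree
        dv = (self._grid_v[i + 1] - self._grid_v[i]) / self._grid_ds
        return float(v), float(dv)

    def value(self, s: np.ndarray) -> np.ndarray:
        """Vectorized V_bias over an array of CV values."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        n = self.n_kernels
        out = np.zeros(s.shape)
        if n:
            z = (s[..., None] - self._c[:n]) / self._w[:n]
            out += np.sum(self._h[:n] * np.exp(-0.5 * z * z), axis=-1)
        if self._table_v.any():
            out += np.interp(s, self.grid, self._table_v)
        return out

    def _append(self, center: float, width: float, height: float) -> None:
        n = self.n_kernels
        if n == self._cap:
            self._cap *= 2
            for name in ("_c", "_w", "_h"):
                arr = np.empty(self._cap)
                arr[:n] = getattr(self, name)[:n]
                setattr(self, name, arr)
        self._c[n], self._w[n], self._h[n] = center, width, height
        self._centers.append(center)
        self._widths.append(width)
        self._heights.append(height)
        z = (self.grid - center) / width
        g = height * np.exp(-0.5 * z * z)
        self._grid_v += g
        self._grid_dv += -g * z / width

    def deposit(self, s: float, config: BiasConfig, thermo: ThermoParams,
                width: Optional[float] = None) -> None:
        """Add one well-tempered kernel at CV value ``s``.

        ``width`` overrides the configured sigma (adaptive-sigma callers pass
        the CV standard deviation over the last deposition window). The
        height is clipped to ``barrier - V(s)``, so the accumulated bias can
        never exceed the configured ceiling.
        """
        v, _ = self.cached_value_and_derivative(s)
        gamma = config.gamma(thermo)
        h = config.h0(thermo) * np.exp(-v / ((gamma - 1.0) * thermo.kT))
        # cap: clip the height so the total bias never exceeds the barrier;
        # late deposits then act only where the profile is still under-filled
        h = min(h, config.barrier - v)
        if h <= 1e-8:
            return
        w = config.sigma if width is None else max(width, config.sigma_floor)
        self._append(float(s), float(w), float(h))

    def estimate_fes(self, grid: np.ndarray, config: BiasConfig,
                     thermo: ThermoParams) -> np.ndarray:
        """Free-energy curve F(s) on ``grid`` (energy units), min-shifted to 0."""
        gamma = config.gamma(thermo)
        f = -(gamma / (gamma - 1.0)) * self.value(grid)
        return f - f.min()


def bias_value_and_derivative(state: BiasState, s: float) -> tuple[float, float]:
    return state.value_and_derivative(s)


def deposit(state: BiasState, s: float, config: BiasConfig,
            thermo: ThermoParams, width: Optional[float] = None) -> BiasState:
    state.deposit(s, config, thermo, width=width)
    return state


class EmptyRegionError(RuntimeError):
    """A reweighting region received zero statistical weight."""


def estimate_delta_f_pooled(trajectories, region_a: RegionSpec,
                            region_c: RegionSpec, thermo: ThermoParams,
                            n_blocks: int = 10,
                            burn_in: float = 0.0) -> tuple[float, float]:
    """ΔF from several walkers sharing one (static) bias.

    Frames are pooled; the standard error comes from contiguous time blocks
    with the walkers merged inside each block.
    """
    logws, in_as, in_cs = [], [], []
    for traj in trajectories:
        pos = traj.positions
        start = int(burn_in * len(pos))
        pos = pos[start:]
        lw = (thermo.beta * np.asarray(traj.bias_values)[start:]
              if traj.bias_values is not None else np.zeros(len(pos)))
        logws.append(lw)
        in_as.append(region_a(pos[:, 0], pos[:, 1]))
        in_cs.append(region_c(pos[:, 0], pos[:, 1]))
    logw = np.stack(logws)       # (walkers, time)
    in_a = np.stack(in_as)
    in_c = np.stack(in_cs)
    for mask, region in ((in_a, region_a), (in_c, region_c)):
        if not mask.any():
            raise EmptyRegionError(f"region {region.label!r} never visited")
    full = (logsumexp(logw[in_a]) - logsumexp(logw[in_c]))
    T = logw.shape[1]
    edges = np.linspace(0, T, n_blocks + 1, dtype=int)
    block_vals = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        a = in_a[:, lo:hi]
        c = in_c[:, lo:hi]
        if a.any() and c.any():
            lwb = logw[:, lo:hi]
            block_vals.append(logsumexp(lwb[a]) - logsumexp(lwb[c]))
    stderr = (float(np.std(block_vals, ddof=1) / np.sqrt(len(block_vals)))
              if len(block_vals) >= 2 else np.inf)
    return float(full), stderr


def estimate_delta_f(trajectory, region_a: RegionSpec, region_c: RegionSpec,
                     thermo: ThermoParams, n_blocks: int = 10,
                     burn_in: float = 0.0) -> tuple[float, float]:
    """ΔF = F_C - F_A in k_B T from a (possibly biased) trajectory.

    Frames are reweighted with log-weights β·V_bias(s_t) (zero when the run
    was unbiased); ΔF is minus the log-ratio of reweighted region populations.
    Returns (estimate, block-averaged standard error) using ``n_blocks``
    contiguous time blocks; blocks in which either region is unvisited are
    dropped from the error estimate.
    """
    pos = trajectory.positions
    n = len(pos)
    start = int(burn_in * n)
    pos = pos[start:]
    if trajectory.bias_values is not None:
        logw = thermo.beta * np.asarray(trajectory.bias_values)[start:]
    else:
        logw = np.zeros(len(pos))
    in_a = region_a(pos[:, 0], pos[:, 1])
    in_c = region_c(pos[:, 0], pos[:, 1])
    for mask, region in ((in_a, region_a), (in_c, region_c)):
        if not mask.any():
            raise EmptyRegionError(f"region {region.label!r} never visited")

    def df(mask_slice, logw_slice, a_mask, c_mask):
        la = logsumexp(logw_slice[a_mask]) if a_mask.any() else -np.inf
        lc = logsumexp(logw_slice[c_mask]) if c_mask.any() else -np.inf
        return la - lc   # ΔF in kT  (= -(ln P_C - ln P_A))

    full = df(None, logw, in_a, in_c)
    edges = np.linspace(0, len(pos), n_blocks + 1, dtype=int)
    block_vals = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        a, c = in_a[lo:hi], in_c[lo:hi]
        if a.any() and c.any():
            block_vals.append(df(None, logw[lo:hi], a, c))
    if len(block_vals) >= 2:
        stderr = float(np.std(block_vals, ddof=1) / np.sqrt(len(block_vals)))
    else:
        stderr = np.inf
    return float(full), stderr
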