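"""Analytic model potentials, derivatives, and free-energy references.

The workhorse surface is a modified Müller–Brown potential in 2D,

    U(x, y) = sum_k A_k exp[ a_k (x-x0_k)^2 + b_k (x-x0_k)(y-y0_k) + c_k (y-y0_k)^2 ],

a sum of four anisotropic Gaussian wells/bumps whose parameters place three
metastable basins (A, B, C) so that neither coordinate axis resolves the
transition states. All derivatives are analytic, which the path-polymer force
expressions require (they couple to the Hessian of U).

Free-energy differences between configuration-space regions are obtained by
direct quadrature of the Boltzmann weight, giving a deterministic reference
against which enhanced-sampling estimates are judged. At the working
temperature (k_B T = 0.1 while well depths are O(10)) the weight spans
hundreds of orders of magnitude, so all integrals are handled in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize, root
from scipy.special import logsumexp


class NonFiniteEnergyError(FloatingPointError):
    """Raised when a potential evaluates to a non-finite value."""


class QuadratureError(RuntimeError):
    """Raised when grid refinement fails to converge the free-energy integral."""


class SaddleSearchError(RuntimeError):
    """Raised when a stationary-point search fails to converge."""


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic state in natural units (k_B = 1)."""

    temperature: float = 0.1

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def kT(self) -> float:
        return self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.temperature


@dataclass(frozen=True)
class RegionSpec:
    """A labelled region of the 2D plane, given as a vectorizable predicate."""

    predicate: Callable[[np.ndarray, np.ndarray], np.ndarray]
    label: str

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.asarray(self.predicate(x, y), dtype=bool)


#: Initial basin of the modified Müller–Brown surface (holds the global minimum).
REGION_A = RegionSpec(lambda x, y: y > x + 1.5, "A")
#: Diagonal band holding the intermediate (B) and final (C) basins.
REGION_C = RegionSpec(lambda x, y: (y > x - 1.5) & (y < x + 1.5), "C")


class PotentialSurface:
    """Interface for analytic potentials on R^d.

    Subclasses provide vectorized ``energy``, ``gradient`` and (optionally)
    ``hessian``; all accept arrays of shape (..., d).
    """

    dim: int = 2

    def energy(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def gradient(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def hessian(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def force(self, points: np.ndarray) -> np.ndarray:
        return -self.gradient(points)

    def derivs(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(energy, gradient, hessian) in one call; subclasses may fuse work."""
        return self.energy(points), self.gradient(points), self.hessian(points)


@dataclass(frozen=True)
class MBParams:
    """Parameters of the four-term modified Müller–Brown surface.

    Defaults are the published parameter set: amplitudes ``A`` in energy
    units, quadratic-form coefficients ``a``, ``b``, ``c`` in 1/length^2, and
    term centers ``(x0, y0)``.
    """

    A: tuple[float, ...] = (-16.0, -11.0, -17.0, 2.0)
    a: tuple[float, ...] = (-10.0, -1.0, -6.5, 0.4)
    b: tuple[float, ...] = (5.0, 0.0, 11.0, 0.0)
    c: tuple[float, ...] = (-5.0, -10.0, -6.5, 1.1)
    x0: tuple[float, ...] = (1.0, 0.0, -0.5, 0.0)
    y0: tuple[float, ...] = (1.2, 0.5, 1.5, 1.0)

    def __post_init__(self) -> None:
        n = len(self.A)
        for name in ("a", "b", "c", "x0", "y0"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"parameter vector {name!r} has length "
                                 f"{len(getattr(self, name))}, expected {n}")

    @property
    def n_terms(self) -> int:
        return len(self.A)


class MullerBrown(PotentialSurface):
    """Modified Müller–Brown potential with analytic gradient and Hessian."""

    dim = 2

    def __init__(self, params: MBParams | None = None):
        self.params = params or MBParams()
        p = self.params
        self._A = np.asarray(p.A, dtype=float)
        self._a = np.asarray(p.a, dtype=float)
        self._b = np.asarray(p.b, dtype=float)
        self._c = np.asarray(p.c, dtype=float)
        self._x0 = np.asarray(p.x0, dtype=float)
        self._y0 = np.asarray(p.y0, dtype=float)

    def _terms(self, points: np.ndarray):
        pts = np.asarray(points, dtype=float)
        if pts.shape[-1] != 2:
            raise ValueError(f"expected points of shape (..., 2), got {pts.shape}")
        dx = pts[..., 0, None] - self._x0   # (..., 4)
        dy = pts[..., 1, None] - self._y0
        expo = self._a * dx**2 + self._b * dx * dy + self._c * dy**2
        return dx, dy, expo

    def energy(self, points: np.ndarray) -> np.ndarray:
        _, _, expo = self._terms(points)
        with np.errstate(over="raise"):
            try:
                vals = np.sum(self._A * np.exp(expo), axis=-1)
            except FloatingPointError as exc:
                raise NonFiniteEnergyError(
                    f"exponent overflow in potential term (max exponent "
                    f"{np.max(expo):.3g})") from exc
        if not np.all(np.isfinite(vals)):
            raise NonFiniteEnergyError("non-finite energy value")
        return vals

    def energy_terms(self, points: np.ndarray) -> np.ndarray:
        """Per-term contributions A_k exp(...), shape (..., n_terms)."""
        _, _, expo = self._terms(points)
        return self._A * np.exp(expo)

    def gradient(self, points: np.ndarray) -> np.ndarray:
        dx, dy, expo = self._terms(points)
        with np.errstate(over="ignore"):
            w = self._A * np.exp(expo)
        ex = 2.0 * self._a * dx + self._b * dy   # d expo / dx
        ey = self._b * dx + 2.0 * self._c * dy   # d expo / dy
        g = np.stack([np.sum(w * ex, axis=-1), np.sum(w * ey, axis=-1)], axis=-1)
        if not np.all(np.isfinite(g)):
            raise NonFiniteEnergyError("non-finite gradient value")
        return g

    def hessian(self, points: np.ndarray) -> np.ndarray:
        dx, dy, expo = self._terms(points)
        with np.errstate(over="ignore"):
            w = self._A * np.exp(expo)
        return self._hess_from(w, dx, dy)

    def _hess_from(self, w, dx, dy) -> np.ndarray:
        ex = 2.0 * self._a * dx + self._b * dy
        ey = self._b * dx + 2.0 * self._c * dy
        hxx = np.sum(w * (ex * ex + 2.0 * self._a), axis=-1)
        hxy = np.sum(w * (ex * ey + self._b), axis=-1)
        hyy = np.sum(w * (ey * ey + 2.0 * self._c), axis=-1)
        H = np.empty(np.shape(hxx) + (2, 2))
        H[..., 0, 0] = hxx
        H[..., 0, 1] = hxy
        H[..., 1, 0] = hxy
        H[..., 1, 1] = hyy
        return H

    def derivs(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fused (energy, gradient, hessian): one exponential pass per term."""
        dx, dy, expo = self._terms(points)
        with np.errstate(over="ignore"):
            w = self._A * np.exp(expo)
        u = np.sum(w, axis=-1)
        ex = 2.0 * self._a * dx + self._b * dy
        ey = self._b * dx + 2.0 * self._c * dy
        g = np.stack([np.sum(w * ex, axis=-1), np.sum(w * ey, axis=-1)], axis=-1)
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(g))):
            raise NonFiniteEnergyError("non-finite energy/gradient value")
        return u, g, self._hess_from(w, dx, dy)


class DoubleWell1D(PotentialSurface):
    """U(x) = h ((x/w)^2 - 1)^2 — two minima at x = ±w, saddle at 0, barrier h."""

    dim = 1

    def __init__(self, barrier: float = 1.0, half_width: float = 1.0):
        self.barrier = float(barrier)
        self.half_width = float(half_width)

    def energy(self, points: np.ndarray) -> np.ndarray:
        x = np.asarray(points, dtype=float)[..., 0]
        u = (x / self.half_width) ** 2 - 1.0
        return self.barrier * u**2

    def gradient(self, points: np.ndarray) -> np.ndarray:
        x = np.asarray(points, dtype=float)[..., 0]
        w2 = self.half_width**2
        g = self.barrier * 4.0 * x * (x**2 / w2 - 1.0) / w2
        return g[..., None]

    def hessian(self, points: np.ndarray) -> np.ndarray:
        x = np.asarray(points, dtype=float)[..., 0]
        w2 = self.half_width**2
        h = self.barrier * (12.0 * x**2 / w2 - 4.0) / w2
        return h[..., None, None]


class DoubleWellIn2D(PotentialSurface):
    """1D double well along x embedded in 2D with a harmonic channel in y.

    A two-state fixture with no intermediate basin: minima at (±w, 0),
    a single index-1 saddle at the origin.
    """

    dim = 2

    def __init__(self, barrier: float = 1.0, half_width: float = 1.0,
                 k_transverse: float = 4.0):
        self.barrier = float(barrier)
        self.half_width = float(half_width)
        self.k_transverse = float(k_transverse)

    def energy(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        x, y = pts[..., 0], pts[..., 1]
        u = (x / self.half_width) ** 2 - 1.0
        return self.barrier * u**2 + 0.5 * self.k_transverse * y**2

    def gradient(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        x, y = pts[..., 0], pts[..., 1]
        w2 = self.half_width**2
        gx = self.barrier * 4.0 * x * (x**2 / w2 - 1.0) / w2
        gy = self.k_transverse * y
        return np.stack([gx, gy], axis=-1)

    def hessian(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        x = pts[..., 0]
        w2 = self.half_width**2
        H = np.zeros(np.shape(x) + (2, 2))
        H[..., 0, 0] = self.barrier * (12.0 * x**2 / w2 - 4.0) / w2
        H[..., 1, 1] = self.k_transverse
        return H


class HarmonicWell(PotentialSurface):
    """Isotropic harmonic well U = (k/2) |R - center|^2 in d dimensions."""

    def __init__(self, k: float = 1.0, dim: int = 2, center: Sequence[float] | None = None):
        self.k = float(k)
        self.dim = int(dim)
        self.center = np.zeros(self.dim) if center is None else np.asarray(center, float)

    def energy(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points, dtype=float) - self.center
        return 0.5 * self.k * np.sum(d**2, axis=-1)

    def gradient(self, points: np.ndarray) -> np.ndarray:
        return self.k * (np.asarray(points, dtype=float) - self.center)

    def hessian(self, points: np.ndarray) -> np.ndarray:
        shape = np.asarray(points, dtype=float).shape[:-1]
        return np.broadcast_to(self.k * np.eye(self.dim), shape + (self.dim, self.dim)).copy()


# --- registry ----------------------------------------------------------------

_REGISTRY: dict[str, Callable[..., PotentialSurface]] = {
    "muller_brown_modified": lambda **kw: MullerBrown(MBParams(**kw) if kw else None),
    "double_well_1d": DoubleWell1D,
    "double_well_2d": DoubleWellIn2D,
    "harmonic": HarmonicWell,
}


def register_potential(name: str, factory: Callable[..., PotentialSurface]) -> None:
    """Register a custom surface factory under a config-addressable name."""
    _REGISTRY[name] = factory


def make_potential(name: str, **overrides) -> PotentialSurface:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown potential {name!r}; known: {sorted(_REGISTRY)}") from None
    return factory(**overrides)


# --- quadrature free energy --------------------------------------------------

#: Axis-aligned integration window covering all MB term centers with room for
#: the Boltzmann weight to decay to nothing at the edges.
DEFAULT_BOX = ((-2.5, 2.5), (-1.5, 3.5))


def _log_region_integral(potential: PotentialSurface, region: RegionSpec,
                         beta: float, box, n: int) -> float:
    """log ∫_region e^{-βU} dx dy via trapezoid weights on an n×n node grid."""
    (x0, x1), (y0, y1) = box
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([X, Y], axis=-1)
    logw = -beta * potential.energy(pts)
    wx = np.ones(n)
    wx[0] = wx[-1] = 0.5
    logtrap = np.log(wx[:, None]) + np.log(wx[None, :])
    mask = region(X, Y)
    if not mask.any():
        raise QuadratureError(f"region {region.label!r} has no grid support in the box")
    logw = np.where(mask, logw + logtrap, -np.inf)
    dx = (x1 - x0) / (n - 1)
    dy = (y1 - y0) / (n - 1)
    return float(logsumexp(logw) + np.log(dx * dy))


def _check_boundary_decay(potential: PotentialSurface, beta: float, box, n: int = 201) -> None:
    (x0, x1), (y0, y1) = box
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    logw = -beta * potential.energy(np.stack([X, Y], axis=-1))
    boundary = np.concatenate([logw[0], logw[-1], logw[:, 0], logw[:, -1]])
    # boundary weight must be <= 1e-12 of the interior peak
    if boundary.max() > logw.max() + np.log(1e-12):
        raise QuadratureError(
            "integration box too small: Boltzmann weight not negligible on the "
            f"boundary (log ratio {boundary.max() - logw.max():.2f})")


def delta_f_quadrature(potential: PotentialSurface,
                       region_a: RegionSpec = REGION_A,
                       region_c: RegionSpec = REGION_C,
                       thermo: ThermoParams = ThermoParams(),
                       box=DEFAULT_BOX,
                       n_start: int = 129,
                       tol: float = 0.01,
                       max_refine: int = 8) -> float:
    """Free-energy difference ΔF = F_C - F_A in units of k_B T.

    Computes -(1/β) ln(∫_C e^{-βU} / ∫_A e^{-βU}) on a uniform trapezoid grid,
    refining dyadically until two successive estimates agree to ``tol`` k_B T.
    """
    beta = thermo.beta
    _check_boundary_decay(potential, beta, box)
    n = n_start
    prev = None
    for _ in range(max_refine):
        la = _log_region_integral(potential, region_a, beta, box, n)
        lc = _log_region_integral(potential, region_c, beta, box, n)
        est = -(lc - la) / beta / thermo.kT   # report in kT
        if prev is not None and abs(est - prev) < tol:
            return est
        prev = est
        n = 2 * (n - 1) + 1
    raise QuadratureError(
        f"quadrature not converged after {max_refine} refinements; "
        f"last two estimates {prev:.6f} (previous) at n={(n - 1) // 2 + 1}")


# --- stationary points and barriers ------------------------------------------

def _descend(potential: PotentialSurface, start: np.ndarray, box) -> np.ndarray:
    """Bounded local minimization from one start (keeps confining terms finite)."""
    res = minimize(lambda p: float(potential.energy(p)), start,
                   jac=lambda p: potential.gradient(p), method="L-BFGS-B",
                   bounds=list(box), options={"ftol": 1e-15, "gtol": 1e-12,
                                              "maxiter": 500})
    return res.x


def find_minima(potential: PotentialSurface, box=DEFAULT_BOX,
                n_starts: int = 12, dedupe_tol: float = 1e-4) -> np.ndarray:
    """Multi-start local minimization; returns deduplicated minima (n, d)."""
    grids = [np.linspace(lo + 0.05, hi - 0.05, n_starts) for lo, hi in box]
    mesh = np.meshgrid(*grids, indexing="ij")
    starts = np.stack([m.ravel() for m in mesh], axis=-1)
    found = []
    for s in starts:
        p = _descend(potential, s, box)
        if np.linalg.norm(potential.gradient(p)) > 1e-8:
            continue
        evals = np.linalg.eigvalsh(potential.hessian(p))
        if np.min(evals) <= 0:
            continue
        if all(np.linalg.norm(p - q) > dedupe_tol for q in found):
            found.append(p)
    order = np.argsort([float(potential.energy(p)) for p in found])
    return np.asarray([found[i] for i in order])


def find_saddles(potential: PotentialSurface, box=DEFAULT_BOX,
                 n_starts: int = 16, dedupe_tol: float = 1e-4) -> np.ndarray:
    """Index-1 saddle points via multi-start Newton iteration on ∇U = 0."""
    grids = [np.linspace(lo + 0.05, hi - 0.05, n_starts) for lo, hi in box]
    mesh = np.meshgrid(*grids, indexing="ij")
    starts = np.stack([m.ravel() for m in mesh], axis=-1)
    saddles: list[np.ndarray] = []

    def grad_safe(p):
        try:
            return potential.gradient(p)
        except NonFiniteEnergyError:
            return np.full(len(p), 1e8)

    def hess_safe(p):
        try:
            return potential.hessian(p)
        except NonFiniteEnergyError:
            return np.eye(len(p))

    for s in starts:
        res = root(grad_safe, s, jac=hess_safe, method="hybr",
                   options={"xtol": 1e-12})
        if not res.success:
            continue
        p = res.x
        try:
            potential.energy(p)
        except NonFiniteEnergyError:
            continue
        inside = all(lo - 0.25 <= v <= hi + 0.25 for v, (lo, hi) in zip(p, box))
        if not inside or np.linalg.norm(potential.gradient(p)) > 1e-6:
            continue
        evals = np.linalg.eigvalsh(potential.hessian(p))
        if np.sum(evals < 0) != 1:
            continue
        if all(np.linalg.norm(p - q) > dedupe_tol for q in saddles):
            saddles.append(p)
    if not saddles and len(starts):
        raise SaddleSearchError(
            f"no index-1 saddle converged from {len(starts)} starts "
            f"(first start {starts[0]})")
    order = np.argsort([float(potential.energy(p)) for p in saddles])
    return np.asarray([saddles[i] for i in order])


@dataclass(frozen=True)
class Barrier:
    """A minimum-to-saddle barrier: saddle location, flanking minima, height."""

    saddle: np.ndarray
    minima: tuple[np.ndarray, np.ndarray]
    height_kT: float


def barrier_heights(potential: PotentialSurface,
                    thermo: ThermoParams = ThermoParams(),
                    box=DEFAULT_BOX) -> list[Barrier]:
    """All minimum–saddle barriers, sorted by height (descending).

    For every index-1 saddle, the two adjacent minima are located by steepest
    descent after a small displacement along the unstable (negative-curvature)
    Hessian eigenvector; the barrier is measured from the *deeper* adjacent
    minimum, in units of k_B T.
    """
    saddles = find_saddles(potential, box=box)
    out = []
    for sp in saddles:
        H = potential.hessian(sp)
        evals, evecs = np.linalg.eigh(H)
        v = evecs[:, 0]   # unstable direction
        minima = [_descend(potential, sp + sign * 1e-3 * v, box)
                  for sign in (+1.0, -1.0)]
        u_saddle = float(potential.energy(sp))
        u_min = min(float(potential.energy(m)) for m in minima)
        out.append(Barrier(saddle=sp, minima=(minima[0], minima[1]),
                           height_kT=(u_saddle - u_min) / thermo.kT))
    out.sort(key=lambda b: -b.height_kT)
    return out
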