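"""Numba-compiled inner loops for the Müller–Brown polymer sampler.

The trajectory-space runs advance hundreds of thousands of Langevin steps
over a few hundred beads; this module fuses the per-step work (potential
derivatives, spring-chain forces, endpoint CV evaluation, bias interpolation,
integrator update) into one compiled kernel for the common configuration:
a four-term Müller–Brown-type surface, 2D beads, and a {24, 12, 1} ReLU
network CV. Anything else falls back to the generic numpy path in ``mop``.

Noise is precomputed per chunk from the caller's numpy Generator in the same
stream order as the generic path, so both paths sample identical randomness.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _mb_derivs(R, A, a, b, c, x0, y0, g, H):
    """Gradient (n,2) and Hessian components (n,3: xx, xy, yy) of the surface."""
    n = R.shape[0]
    for i in range(n):
        gx = 0.0
        gy = 0.0
        hxx = 0.0
        hxy = 0.0
        hyy = 0.0
        for k in range(4):
            dx = R[i, 0] - x0[k]
            dy = R[i, 1] - y0[k]
            w = A[k] * np.exp(a[k] * dx * dx + b[k] * dx * dy + c[k] * dy * dy)
            ex = 2.0 * a[k] * dx + b[k] * dy
            ey = b[k] * dx + 2.0 * c[k] * dy
            gx += w * ex
            gy += w * ey
            hxx += w * (ex * ex + 2.0 * a[k])
            hxy += w * (ex * ey + b[k])
            hyy += w * (ey * ey + 2.0 * c[k])
        g[i, 0] = gx
        g[i, 1] = gy
        H[i, 0] = hxx
        H[i, 1] = hxy
        H[i, 2] = hyy


@njit(cache=True)
def _nn_value_grad(x, W1, b1, W2, b2, W3, b3, out_grad):
    """Latent value and input gradient of the {24,12,1} ReLU network."""
    h1 = np.empty(24)
    for j in range(24):
        v = b1[j] + W1[0, j] * x[0] + W1[1, j] * x[1]
        h1[j] = v if v > 0.0 else 0.0
    h2 = np.empty(12)
    for j in range(12):
        v = b2[j]
        for i in range(24):
            v += W2[i, j] * h1[i]
        h2[j] = v if v > 0.0 else 0.0
    z = b3[0]
    for i in range(12):
        z += W3[i, 0] * h2[i]
    # backward pass through the relu masks
    d2 = np.empty(12)
    for i in range(12):
        d2[i] = W3[i, 0] if h2[i] > 0.0 else 0.0
    d1 = np.empty(24)
    for i in range(24):
        v = 0.0
        for j in range(12):
            v += W2[i, j] * d2[j]
        d1[i] = v if h1[i] > 0.0 else 0.0
    gx = 0.0
    gy = 0.0
    for i in range(24):
        gx += W1[0, i] * d1[i]
        gy += W1[1, i] * d1[i]
    out_grad[0] = gx
    out_grad[1] = gy
    return z


@njit(cache=True)
def mop_chunk(beads, noise, A, a, b, c, x0, y0, K, mob, mob_poly,
              W1, b1, W2, b2, W3, b3, zmin, zmax,
              grid_v, grid_dv, grid_lo, grid_ds, use_bias):
    """Advance len(noise) polymer steps in place; returns S after the chunk.

    ``noise`` has shape (steps, n_beads, 2) and already carries the thermal
    standard deviation. The bias is evaluated by linear interpolation on the
    (grid_v, grid_dv) cache; the chain-rule force touches only the endpoints.
    """
    n = beads.shape[0]
    g = np.empty((n, 2))
    H = np.empty((n, 3))
    grad = np.empty((n, 2))
    g1 = np.empty(2)
    gN = np.empty(2)
    scale = 2.0 / (zmax - zmin)
    S = 0.0
    for t in range(noise.shape[0]):
        _mb_derivs(beads, A, a, b, c, x0, y0, g, H)
        for i in range(n):
            grad[i, 0] = 0.0
            grad[i, 1] = 0.0
        for m in range(n - 1):
            dx = beads[m + 1, 0] - beads[m, 0] + mob * g[m, 0]
            dy = beads[m + 1, 1] - beads[m, 1] + mob * g[m, 1]
            hdx = H[m, 0] * dx + H[m, 1] * dy
            hdy = H[m, 1] * dx + H[m, 2] * dy
            grad[m, 0] += K * (-dx + mob * hdx)
            grad[m, 1] += K * (-dy + mob * hdy)
            grad[m + 1, 0] += K * dx
            grad[m + 1, 1] += K * dy
        grad[0, 0] += g[0, 0]
        grad[0, 1] += g[0, 1]

        z1 = _nn_value_grad(beads[0], W1, b1, W2, b2, W3, b3, g1)
        zN = _nn_value_grad(beads[n - 1], W1, b1, W2, b2, W3, b3, gN)
        S = scale * (zN - z1)
        if use_bias:
            xg = (S - grid_lo) / grid_ds
            i0 = int(xg)
            if 0 <= i0 < grid_v.shape[0] - 1:
                f = xg - i0
                dvds = grid_dv[i0] * (1.0 - f) + grid_dv[i0 + 1] * f
            else:
                dvds = 0.0   # outside the calibrated CV window: no push
            grad[0, 0] -= dvds * scale * g1[0]
            grad[0, 1] -= dvds * scale * g1[1]
            grad[n - 1, 0] += dvds * scale * gN[0]
            grad[n - 1, 1] += dvds * scale * gN[1]
        for i in range(n):
            beads[i, 0] += -mob_poly * grad[i, 0] + noise[t, i, 0]
            beads[i, 1] += -mob_poly * grad[i, 1] + noise[t, i, 1]
    return S


@njit(cache=True)
def walker_chunk(R, noise, A, a, b, c, x0, y0, mobility,
                 W1, b1, W2, b2, W3, b3, zmin, zmax,
                 grid_v, grid_dv, grid_lo, grid_ds,
                 out_pos, out_s, out_v, stride):
    """Advance a batch of independent walkers under a static CV bias.

    ``noise`` is (steps, m, 2) premultiplied by the thermal sigma; positions,
    CV values and instantaneous bias are recorded every ``stride`` steps into
    the ``out_*`` arrays (shape (steps//stride, m, ...)).
    """
    m = R.shape[0]
    g = np.empty(2)
    scale = 2.0 / (zmax - zmin)
    frame = 0
    for t in range(noise.shape[0]):
        for i in range(m):
            xx = R[i, 0]
            yy = R[i, 1]
            fx = 0.0
            fy = 0.0
            for k in range(4):
                dx = xx - x0[k]
                dy = yy - y0[k]
                w = A[k] * np.exp(a[k] * dx * dx + b[k] * dx * dy
                                  + c[k] * dy * dy)
                fx -= w * (2.0 * a[k] * dx + b[k] * dy)
                fy -= w * (b[k] * dx + 2.0 * c[k] * dy)
            z = _nn_value_grad(R[i], W1, b1, W2, b2, W3, b3, g)
            sv = scale * (z - zmin) - 1.0
            xg = (sv - grid_lo) / grid_ds
            i0 = int(xg)
            if 0 <= i0 < grid_v.shape[0] - 1:
                dvds = (grid_v[i0 + 1] - grid_v[i0]) / grid_ds
            else:
                dvds = 0.0
            fx -= dvds * scale * g[0]
            fy -= dvds * scale * g[1]
            R[i, 0] += mobility * fx + noise[t, i, 0]
            R[i, 1] += mobility * fy + noise[t, i, 1]
        if (t + 1) % stride == 0:
            for i in range(m):
                z = _nn_value_grad(R[i], W1, b1, W2, b2, W3, b3, g)
                sv = scale * (z - zmin) - 1.0
                out_pos[frame, i, 0] = R[i, 0]
                out_pos[frame, i, 1] = R[i, 1]
                out_s[frame, i] = sv
                xg = (sv - grid_lo) / grid_ds
                i0 = int(xg)
                if xg < 0:
                    out_v[frame, i] = grid_v[0]
                elif i0 + 1 >= grid_v.shape[0]:
                    out_v[frame, i] = grid_v[-1]
                else:
                    f = xg - i0
                    out_v[frame, i] = (grid_v[i0] * (1.0 - f)
                                       + grid_v[i0 + 1] * f)
            frame += 1


@njit(cache=True)
def umbrella_window(R, noise, A, a, b, c, x0, y0, mobility,
                    W1, b1, W2, b2, W3, b3, zmin, zmax,
                    kappa, s0, out_s, stride):
    """One walker under a harmonic CV restraint 0.5*kappa*(s-s0)^2.

    Records s every ``stride`` steps into out_s; advances len(noise) steps.
    """
    g = np.empty(2)
    scale = 2.0 / (zmax - zmin)
    frame = 0
    for t in range(noise.shape[0]):
        xx = R[0]
        yy = R[1]
        fx = 0.0
        fy = 0.0
        for k in range(4):
            dx = xx - x0[k]
            dy = yy - y0[k]
            w = A[k] * np.exp(a[k] * dx * dx + b[k] * dx * dy + c[k] * dy * dy)
            fx -= w * (2.0 * a[k] * dx + b[k] * dy)
            fy -= w * (b[k] * dx + 2.0 * c[k] * dy)
        z = _nn_value_grad(R, W1, b1, W2, b2, W3, b3, g)
        sv = scale * (z - zmin) - 1.0
        pull = -kappa * (sv - s0)
        fx += pull * scale * g[0]
        fy += pull * scale * g[1]
        R[0] += mobility * fx + noise[t, 0]
        R[1] += mobility * fy + noise[t, 1]
        if (t + 1) % stride == 0:
            z = _nn_value_grad(R, W1, b1, W2, b2, W3, b3, g)
            out_s[frame] = scale * (z - zmin) - 1.0
            frame += 1


@njit(cache=True)
def _path_value_grad(x, P, T, out_grad):
    """Gaussian-weighted path progress and its gradient.

    The trailing element of T carries λ is NOT used here: λ is passed via
    the module-level convention that T has the same length as P and the
    caller supplies lam through closure-free arguments; instead we derive
    λ from the mean squared node spacing (2.3 / <Δ²>), matching the
    PathProgressCV construction.
    """
    n = P.shape[0]
    # mean squared node spacing
    acc = 0.0
    for k in range(n - 1):
        dx = P[k + 1, 0] - P[k, 0]
        dy = P[k + 1, 1] - P[k, 1]
        acc += dx * dx + dy * dy
    lam = 2.3 * (n - 1) / acc
    dmin = 1e300
    for k in range(n):
        dx = x[0] - P[k, 0]
        dy = x[1] - P[k, 1]
        d2 = dx * dx + dy * dy
        if d2 < dmin:
            dmin = d2
    W = 0.0
    num = 0.0
    gx = 0.0
    gy = 0.0
    tgx = 0.0
    tgy = 0.0
    for k in range(n):
        dx = x[0] - P[k, 0]
        dy = x[1] - P[k, 1]
        d2 = dx * dx + dy * dy
        w = np.exp(-lam * (d2 - dmin))
        W += w
        num += T[k] * w
        gwx = -2.0 * lam * dx * w
        gwy = -2.0 * lam * dy * w
        gx += gwx
        gy += gwy
        tgx += T[k] * gwx
        tgy += T[k] * gwy
    s = num / W
    out_grad[0] = tgx / W - s * gx / W
    out_grad[1] = tgy / W - s * gy / W
    return s


@njit(cache=True)
def _tube_force(x, P, lam, z0sq, kappa_w, out_f):
    """Wall force confining sampling to a tube around the path.

    z² is the soft minimum squared distance to the path nodes,
    z² = d²_min - ln(Σ e^{-λ(d²-d²_min)}) / λ; beyond z0² a harmonic wall
    pushes back along ∇z².
    """
    n = P.shape[0]
    dmin = 1e300
    for k in range(n):
        dx = x[0] - P[k, 0]
        dy = x[1] - P[k, 1]
        d2 = dx * dx + dy * dy
        if d2 < dmin:
            dmin = d2
    W = 0.0
    gx = 0.0
    gy = 0.0
    for k in range(n):
        dx = x[0] - P[k, 0]
        dy = x[1] - P[k, 1]
        d2 = dx * dx + dy * dy
        w = np.exp(-lam * (d2 - dmin))
        W += w
        gx += 2.0 * dx * w
        gy += 2.0 * dy * w
    zsq = dmin - np.log(W) / lam
    out_f[0] = 0.0
    out_f[1] = 0.0
    if zsq > z0sq:
        c = -kappa_w * (zsq - z0sq)
        out_f[0] = c * gx / W
        out_f[1] = c * gy / W


@njit(cache=True)
def umbrella_window_path(R, noise, A, a, b, c, x0, y0, mobility,
                         P, T, lam, z0sq, kappa_w, kappa, s0, out_s, stride):
    """Harmonic-restraint window sampling with the path-progress CV."""
    g = np.empty(2)
    fw = np.empty(2)
    frame = 0
    for t in range(noise.shape[0]):
        xx = R[0]
        yy = R[1]
        fx = 0.0
        fy = 0.0
        for k in range(4):
            dx = xx - x0[k]
            dy = yy - y0[k]
            w = A[k] * np.exp(a[k] * dx * dx + b[k] * dx * dy + c[k] * dy * dy)
            fx -= w * (2.0 * a[k] * dx + b[k] * dy)
            fy -= w * (b[k] * dx + 2.0 * c[k] * dy)
        sv = _path_value_grad(R, P, T, g)
        pull = -kappa * (sv - s0)
        fx += pull * g[0]
        fy += pull * g[1]
        _tube_force(R, P, lam, z0sq, kappa_w, fw)
        fx += fw[0]
        fy += fw[1]
        # Leimkuhler-Matthews update: averaging consecutive noises samples
        # the configurational Boltzmann density with O(dt^2) accuracy
        if t + 1 < noise.shape[0]:
            nx = 0.5 * (noise[t, 0] + noise[t + 1, 0])
            ny = 0.5 * (noise[t, 1] + noise[t + 1, 1])
        else:
            nx = noise[t, 0]
            ny = noise[t, 1]
        dx_ = mobility * fx
        dy_ = mobility * fy
        if dx_ > 0.05:
            dx_ = 0.05
        elif dx_ < -0.05:
            dx_ = -0.05
        if dy_ > 0.05:
            dy_ = 0.05
        elif dy_ < -0.05:
            dy_ = -0.05
        R[0] += dx_ + nx
        R[1] += dy_ + ny
        if (t + 1) % stride == 0:
            out_s[frame] = _path_value_grad(R, P, T, g)
            frame += 1


@njit(cache=True)
def walker_chunk_path(R, noise, A, a, b, c, x0, y0, mobility,
                      P, T, lam, z0sq, kappa_w,
                      grid_v, grid_dv, grid_lo, grid_ds,
                      out_pos, out_s, out_v, stride):
    """Static-bias batch dynamics with the path-progress CV (tube-confined)."""
    m = R.shape[0]
    g = np.empty(2)
    fw = np.empty(2)
    frame = 0
    for t in range(noise.shape[0]):
        for i in range(m):
            xx = R[i, 0]
            yy = R[i, 1]
            fx = 0.0
            fy = 0.0
            for k in range(4):
                dx = xx - x0[k]
                dy = yy - y0[k]
                w = A[k] * np.exp(a[k] * dx * dx + b[k] * dx * dy
                                  + c[k] * dy * dy)
                fx -= w * (2.0 * a[k] * dx + b[k] * dy)
                fy -= w * (b[k] * dx + 2.0 * c[k] * dy)
            sv = _path_value_grad(R[i], P, T, g)
            xg = (sv - grid_lo) / grid_ds
            i0 = int(xg)
            if 0 <= i0 < grid_v.shape[0] - 1:
                dvds = (grid_v[i0 + 1] - grid_v[i0]) / grid_ds
            else:
                dvds = 0.0
            fx -= dvds * g[0]
            fy -= dvds * g[1]
            _tube_force(R[i], P, lam, z0sq, kappa_w, fw)
            fx += fw[0]
            fy += fw[1]
            if t + 1 < noise.shape[0]:
                nx = 0.5 * (noise[t, i, 0] + noise[t + 1, i, 0])
                ny = 0.5 * (noise[t, i, 1] + noise[t + 1, i, 1])
            else:
                nx = noise[t, i, 0]
                ny = noise[t, i, 1]
            # trust region: cap the drift so steep wall regions (negligible
            # statistical weight) cannot blow up the explicit update
            dx_ = mobility * fx
            dy_ = mobility * fy
            if dx_ > 0.05:
                dx_ = 0.05
            elif dx_ < -0.05:
                dx_ = -0.05
            if dy_ > 0.05:
                dy_ = 0.05
            elif dy_ < -0.05:
                dy_ = -0.05
            R[i, 0] += dx_ + nx
            R[i, 1] += dy_ + ny
        if (t + 1) % stride == 0:
            for i in range(m):
                sv = _path_value_grad(R[i], P, T, g)
                out_pos[frame, i, 0] = R[i, 0]
                out_pos[frame, i, 1] = R[i, 1]
                out_s[frame, i] = sv
                xg = (sv - grid_lo) / grid_ds
                i0 = int(xg)
                if xg < 0:
                    out_v[frame, i] = grid_v[0]
                elif i0 + 1 >= grid_v.shape[0]:
                    out_v[frame, i] = grid_v[-1]
                else:
                    f = xg - i0
                    out_v[frame, i] = (grid_v[i0] * (1.0 - f)
                                       + grid_v[i0 + 1] * f)
            frame += 1


def applicable(potential, cv_model) -> bool:
    """Fast path covers 4-term MB-type surfaces with the default network."""
    from .deeptda import TDAModel
    from .potentials import MullerBrown
    if not isinstance(potential, MullerBrown) or potential.params.n_terms != 4:
        return False
    if cv_model is None:
        return True
    if not isinstance(cv_model, TDAModel):
        return False
    mlp = cv_model._mlp
    shapes = [W.shape for W in mlp.W]
    return shapes == [(2, 24), (24, 12), (12, 1)]


def mb_arrays(potential):
    p = potential.params
    return tuple(np.asarray(v, dtype=float)
                 for v in (p.A, p.a, p.b, p.c, p.x0, p.y0))


def nn_arrays(cv_model):
    mlp = cv_model._mlp
    return (mlp.W[0], mlp.b[0], mlp.W[1], mlp.b[1], mlp.W[2], mlp.b[2],
            float(cv_model.zmin), float(cv_model.zmax))
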