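"""Immersed-boundary coupling with the 4-point cosine kernel.

The same kernel is used for spreading nodal forces to the lattice and for
interpolating lattice velocities back to the nodes (adjoint pair), so the
total force handed to the fluid equals the total nodal force exactly.
"""

from __future__ import annotations

import warnings

import numpy as np

from viscolb.errors import StabilityError

#: half-width of the kernel support in lattice units
SUPPORT = 2.0


def delta_weight(r):
    """1D kernel (1/4)(1 + cos(pi r / 2)) for |r| <= 2, else 0.

    Continuous at |r| = 2, value 1/2 at r = 0, exact partition of unity over
    integer shifts.  The 3D weight is the product of the three 1D factors.
    """
    r = np.asarray(r, dtype=float)
    out = 0.25 * (1.0 + np.cos(np.pi * r / 2.0))
    return np.where(np.abs(r) <= SUPPORT, out, 0.0)


def _stencil(positions: np.ndarray, shape, periodic):
    """64-point stencil indices and tensor-product weights for each node.

    Returns (ix, iy, iz, W) with shapes (N, 4) x3 and (N, 4, 4, 4).
    Non-periodic axes clip out-of-range sites and zero their weights.
    """
    positions = np.asarray(positions, dtype=float)
    base = np.floor(positions).astype(np.int64) - 1          # (N, 3)
    offs = np.arange(4)
    idx, wts = [], []
    for ax in range(3):
        sites = base[:, ax, None] + offs                      # (N, 4)
        w = delta_weight(sites - positions[:, ax, None])
        n = shape[ax]
        if periodic[ax]:
            sites = np.mod(sites, n)
        else:
            oob = (sites < 0) | (sites >= n)
            w = np.where(oob, 0.0, w)
            sites = np.clip(sites, 0, n - 1)
        idx.append(sites)
        wts.append(w)
    W = wts[0][:, :, None, None] * wts[1][:, None, :, None] * wts[2][:, None, None, :]
    return idx[0], idx[1], idx[2], W


def spread_forces(positions: np.ndarray, forces: np.ndarray, shape,
                  fluid_mask: np.ndarray | None = None,
                  periodic=(True, False, False)) -> np.ndarray:
    """Lattice force field F_A(x_f) = sum_n f(x_n) D(x_n - x_f).

    If ``fluid_mask`` is given, weight landing on non-fluid sites is dropped
    (clamped spreading) with a warning when the loss is significant.
    """
    ix, iy, iz, W = _stencil(positions, shape, periodic)
    if fluid_mask is not None:
        ok = fluid_mask[ix[:, :, None, None],
                        iy[:, None, :, None],
                        iz[:, None, None, :]]
        lost = float(np.abs(W * ~ok).sum())
        if lost > 1e-9:
            warnings.warn(
                f"membrane node inside wall layer: clamped {lost:.3g} of spread weight",
                stacklevel=2)
        W = np.where(ok, W, 0.0)
    N = len(positions)
    lin = (ix[:, :, None, None] * shape[1] + iy[:, None, :, None]) * shape[2] \
        + iz[:, None, None, :]
    out = np.zeros((3,) + tuple(shape), dtype=float)
    flat = out.reshape(3, -1)
    for c in range(3):
        np.add.at(flat[c], lin.ravel(),
                  (np.asarray(forces)[:, c].reshape(N, 1, 1, 1) * W).ravel())
    return out


def interpolate_velocity(u: np.ndarray, positions: np.ndarray,
                         periodic=(True, False, False)) -> np.ndarray:
    """Node velocities u_p(x_n) = sum_f u(x_f) D(x_f - x_n) (same kernel)."""
    shape = u.shape[1:]
    ix, iy, iz, W = _stencil(positions, shape, periodic)
    vals = u[:, ix[:, :, None, None], iy[:, None, :, None], iz[:, None, None, :]]
    return np.einsum('cnijk,nijk->nc', vals, W)


def advect_nodes(positions: np.ndarray, velocities: np.ndarray, dt: float = 1.0,
                 max_step: float = 0.5) -> np.ndarray:
    """Forward-Euler node update; positions along x stay unwrapped (continuous).

    Raises if any node moves more than ``max_step`` lattice units per step.
    """
    disp = np.asarray(velocities, dtype=float) * dt
    worst = float(np.abs(disp).max()) if disp.size else 0.0
    if worst > max_step:
        raise StabilityError(
            f"node displacement {worst:.3g} exceeds {max_step} lattice units per step")
    return np.asarray(positions, dtype=float) + disp
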