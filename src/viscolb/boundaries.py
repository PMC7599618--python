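"""Channel geometry, non-equilibrium extrapolation walls, and flow driving.

Walls sit ON lattice nodes (the interior of a channel of height h spans
h/dx - 1 fluid nodes).  Each wall node copies the non-equilibrium part of a
designated adjacent fluid node; corners use the diagonal interior neighbour.
The flow axis (x) is periodic; the shear box is additionally periodic in z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from viscolb import lattice, stress
from viscolb.errors import ConfigurationError


@dataclass(frozen=True)
class ChannelGeometry:
    """Physical cross-section: height h, width w (metres), lattice spacing dx."""

    h: float
    w: float
    dx: float

    def __post_init__(self):
        if self.h <= 0 or self.w <= 0 or self.dx <= 0:
            raise ConfigurationError("h, w, dx must be positive")

    @property
    def AR(self) -> float:
        """Aspect ratio h/w (1 = square, < 1 wider than tall)."""
        return self.h / self.w

    @property
    def L(self) -> float:
        """Characteristic length 2hw/(h+w), recomputed on access."""
        return 2.0 * self.h * self.w / (self.h + self.w)


def driving_acceleration(Re: float, nu: float, L: float) -> float:
    """Poiseuille driving acceleration a = 32 nu^2 Re / L^3 (nu = total kinematic)."""
    if L <= 0:
        raise ConfigurationError("characteristic length must be positive")
    return 32.0 * nu * nu * Re / L ** 3


# ---------------------------------------------------------------------------
# cross-section masks (uniform along the periodic flow axis x)
# ---------------------------------------------------------------------------

def duct_section(ny: int, nz: int) -> np.ndarray:
    """Rectangular duct: one wall layer on all four sides, fluid interior."""
    if ny < 5 or nz < 5:
        raise ConfigurationError("duct cross-section needs at least 5 nodes per side")
    m = np.zeros((ny, nz), dtype=bool)
    m[1:-1, 1:-1] = True
    return m


def tube_section(n: int, radius: float | None = None) -> np.ndarray:
    """Circular tube mask in an n x n box; fluid where r <= radius."""
    if n < 7:
        raise ConfigurationError("tube cross-section needs at least 7 nodes")
    if radius is None:
        # d = n - 2 fluid nodes across; the quarter-node bias makes the
        # staircase track the effective no-slip circle of radius (d+1)/2 set
        # by the on-axis wall nodes
        radius = (n - 2) / 2.0 + 0.25
    c = (n - 1) / 2.0
    y, z = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r2 = (y - c) ** 2 + (z - c) ** 2
    return r2 <= radius * radius + 1e-12


def shear_section(ny: int, nz: int) -> np.ndarray:
    """Plane-Couette box: walls at y = 0 and y = ny-1 only (z periodic)."""
    if ny < 10:
        raise ConfigurationError("shear gap must be >= 8 nodes")
    m = np.ones((ny, nz), dtype=bool)
    m[0, :] = False
    m[-1, :] = False
    return m


# 8-neighbourhood used for the wall adjacency search: axis links first
_NEIGH = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)]


@dataclass
class WallSet:
    """Precomputed wall nodes, their adjacent fluid nodes and wall velocities.

    Index arrays refer to the (y, z) cross-section; the same set is applied at
    every x plane.
    """

    yw: np.ndarray
    zw: np.ndarray
    yf: np.ndarray
    zf: np.ndarray
    u_wall: np.ndarray  # (3, n_wall)
    periodic: tuple[bool, bool, bool] = (True, False, False)

    @property
    def n_wall(self) -> int:
        return len(self.yw)


def build_wallset(section: np.ndarray, wall_velocity=None,
                  periodic=(True, False, False)) -> WallSet:
    """Identify wall nodes (solid with a fluid neighbour) and their adjacency.

    ``wall_velocity`` may be None (no-slip), a constant 3-vector, or a callable
    (y, z) -> 3-vector for moving walls.
    """
    ny, nz = section.shape
    yw, zw, yf, zf, uw = [], [], [], [], []
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    for y in range(ny):
        for z in range(nz):
            if section[y, z]:
                continue
            best = None
            for rank, (dy, dz) in enumerate(_NEIGH):
                yy, zz = y + dy, z + dz
                if periodic[1]:
                    yy %= ny
                if periodic[2]:
                    zz %= nz
                if not (0 <= yy < ny and 0 <= zz < nz):
                    continue
                if not section[yy, zz]:
                    continue
                axis = 0 if rank < 4 else 1  # prefer axis links over diagonals
                dist = (yy - cy) ** 2 + (zz - cz) ** 2
                key = (axis, dist, rank)
                if best is None or key < best[0]:
                    best = (key, yy, zz)
            if best is None:
                continue  # deep solid node, inert
            yw.append(y)
            zw.append(z)
            yf.append(best[1])
            zf.append(best[2])
            if wall_velocity is None:
                uw.append((0.0, 0.0, 0.0))
            elif callable(wall_velocity):
                uw.append(tuple(wall_velocity(y, z)))
            else:
                uw.append(tuple(wall_velocity))
    if not yw:
        raise ConfigurationError("section mask has no wall layer")
    return WallSet(
        yw=np.array(yw), zw=np.array(zw), yf=np.array(yf), zf=np.array(zf),
        u_wall=np.array(uw, dtype=float).T.copy(), periodic=periodic,
    )


def wall_populations_f(rho_f: np.ndarray, u_f: np.ndarray, f_fluid: np.ndarray,
                       u_w: np.ndarray) -> np.ndarray:
    """Non-equilibrium extrapolation for the solvent populations of one wall set.

    f(wall) = feq(rho_f, u_w) + [f(x_f) - feq(rho_f, u_f)], with rho_f, u_f
    taken from the adjacent fluid nodes.
    """
    feq_fluid = lattice.equilibrium_distribution(rho_f, u_f)
    feq_wall = lattice.equilibrium_distribution(rho_f, u_w)
    return feq_wall + f_fluid - feq_fluid


def wall_populations_G(tau6_f: np.ndarray, u_f: np.ndarray, G_fluid: np.ndarray,
                       u_w: np.ndarray) -> np.ndarray:
    """Same extrapolation for the tensor populations, with tau from the fluid node."""
    Geq_fluid = stress.tensor_equilibrium(tau6_f, u_f)
    Geq_wall = stress.tensor_equilibrium(tau6_f, u_w)
    return Geq_wall + G_fluid - Geq_fluid


def apply_walls_f(f: np.ndarray, F: np.ndarray | None, ws: WallSet) -> None:
    """Overwrite wall-node solvent populations in place (post-stream)."""
    ff = f[:, :, ws.yf, ws.zf]                       # (19, nx, nW)
    rho_f = ff.sum(axis=0)
    mom = np.tensordot(lattice._CF.T, ff, axes=([1], [0]))
    if F is not None:
        mom = mom + 0.5 * F[:, :, ws.yf, ws.zf]
    u_f = mom / rho_f
    u_w = np.broadcast_to(ws.u_wall[:, None, :], u_f.shape)
    f[:, :, ws.yw, ws.zw] = wall_populations_f(rho_f, u_f, ff, u_w)


def apply_walls_G(G: np.ndarray, tau6: np.ndarray, u: np.ndarray, ws: WallSet) -> None:
    """Overwrite wall-node tensor populations in place (post-stream)."""
    Gf = G[:, :, :, ws.yf, ws.zf]                    # (6, 19, nx, nW)
    tau_f = tau6[:, :, ws.yf, ws.zf]
    u_f = u[:, :, ws.yf, ws.zf]
    u_w = np.broadcast_to(ws.u_wall[:, None, :], u_f.shape)
    G[:, :, :, ws.yw, ws.zw] = wall_populations_G(tau_f, u_f, Gf, u_w)


def shear_box(u_wall: float, ny: int, nz: int) -> tuple[np.ndarray, WallSet, float]:
    """Counter-moving plane walls: top +U, bottom -U along x; periodic x and z.

    Returns (section mask, wall set, nominal shear rate 2U/gap) with the gap
    taken as the wall-to-wall distance (ny - 1 lattice units).
    """
    section = shear_section(ny, nz)

    def vel(y, z):
        return (u_wall, 0.0, 0.0) if y == ny - 1 else (-u_wall, 0.0, 0.0)

    ws = build_wallset(section, wall_velocity=vel, periodic=(True, False, True))
    gap = float(ny - 1)
    return section, ws, 2.0 * u_wall / gap
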