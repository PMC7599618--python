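"""D3Q19 single-relaxation-time (LBGK) lattice core with Guo forcing.

All quantities are in lattice units (dx = dt = 1, lattice speed c = 1) unless
stated otherwise.  Population fields are stored direction-major:
``f[alpha, x, y, z]``; vector fields component-major: ``u[i, x, y, z]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from viscolb.errors import InvalidStateError, NumericalBlowupError, StabilityError, SubsonicWarning

#: squared lattice sound speed, cs^2 = c^2 / 3
CS2 = 1.0 / 3.0

#: the 19 discrete velocities: rest, 6 axis links, 12 face-diagonal links
DIRECTIONS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0],
        [0, 1, 0], [0, -1, 0],
        [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.int64,
)

#: quadrature weights: 1/3 (rest), 1/18 (axis), 1/36 (diagonal)
WEIGHTS = np.array([1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12)

#: index of the opposite direction for each alpha
OPPOSITE = np.array(
    [int(np.flatnonzero((DIRECTIONS == -c).all(axis=1))[0]) for c in DIRECTIONS]
)

_CF = DIRECTIONS.astype(float)


@dataclass(frozen=True)
class LatticeSpec:
    """Static description of the D3Q19 stencil on a given grid."""

    shape: tuple[int, int, int]
    c: float = 1.0
    directions: np.ndarray = field(default_factory=lambda: DIRECTIONS.copy())
    weights: np.ndarray = field(default_factory=lambda: WEIGHTS.copy())

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise InvalidStateError(f"lattice shape must be 3 positive extents, got {self.shape}")


@dataclass
class DistributionField:
    """Solvent populations plus the derived macroscopic moments."""

    f: np.ndarray          # (19, nx, ny, nz)
    rho: np.ndarray        # (nx, ny, nz)
    u: np.ndarray          # (3, nx, ny, nz)
    lambda_f: float        # relaxation time in units of dt, > 1/2

    def __post_init__(self):
        if self.lambda_f <= 0.5:
            raise StabilityError(f"lambda_f must exceed 1/2, got {self.lambda_f}")


def _wexpand(ndim: int) -> np.ndarray:
    """Weights broadcastable against a (19, ...) array of total rank ndim."""
    return WEIGHTS.reshape((19,) + (1,) * (ndim - 1))


def check_subsonic(u: np.ndarray, c: float = 1.0, warn: float = 0.1, abort: float = 0.3) -> None:
    """Warn above ``warn*c`` and raise above ``abort*c`` (LBGK validity)."""
    umax = float(np.sqrt((u * u).sum(axis=0).max())) if u.size else 0.0
    if umax > abort * c:
        raise StabilityError(f"|u|max = {umax:.4g} exceeds {abort}c; LBGK invalid")
    if umax > warn * c:
        warnings.warn(f"|u|max = {umax:.4g} exceeds {warn}c", SubsonicWarning, stacklevel=2)


def equilibrium_bracket(u: np.ndarray) -> np.ndarray:
    """The shared second-order bracket 1 + 3 c.u + 4.5 (c.u)^2 - 1.5 u^2.

    Parameters
    ----------
    u : (3, ...) velocity field.

    Returns
    -------
    (19, ...) array, also used by the tensor-distribution equilibrium.
    """
    cu = np.tensordot(_CF, u, axes=([1], [0]))  # (19, ...)
    usq = (u * u).sum(axis=0)
    return 1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq


def equilibrium_distribution(rho: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Second-order equilibrium populations for density ``rho``, velocity ``u``.

    The zeroth/first moments reproduce ``rho`` and ``rho*u`` exactly by the
    stencil's moment identities.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0.0):
        raise InvalidStateError("equilibrium requires rho > 0 everywhere")
    br = equilibrium_bracket(np.asarray(u, dtype=float))
    return _wexpand(br.ndim) * rho * br


def force_term(u: np.ndarray, F: np.ndarray, lambda_f: float) -> np.ndarray:
    """Guo forcing populations for body-force density ``F``.

    F_alpha = (1 - 1/(2 lambda)) w_a [3(c_a - u) + 9 (c_a.u) c_a] . F
    """
    if lambda_f < 0.5:
        raise StabilityError(f"lambda_f must be >= 1/2, got {lambda_f}")
    u = np.asarray(u, dtype=float)
    F = np.asarray(F, dtype=float)
    cu = np.tensordot(_CF, u, axes=([1], [0]))       # (19, ...)
    cF = np.tensordot(_CF, F, axes=([1], [0]))       # (19, ...)
    uF = (u * F).sum(axis=0)                         # (...)
    pref = 1.0 - 0.5 / lambda_f
    return pref * _wexpand(cu.ndim) * (3.0 * (cF - uF) + 9.0 * cu * cF)


def macroscopic_moments(f: np.ndarray, F: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Density and half-force-corrected velocity: rho = sum f, rho u = sum c f + F/2."""
    if not np.all(np.isfinite(f)):
        raise NumericalBlowupError("non-finite populations in moment evaluation",
                                   node=_first_bad_node(f))
    rho = f.sum(axis=0)
    mom = np.tensordot(_CF.T, f, axes=([1], [0]))    # (3, ...)
    if F is not None:
        mom = mom + 0.5 * np.asarray(F, dtype=float)
    if np.any(rho <= 0.0):
        raise InvalidStateError("non-positive density encountered")
    return rho, mom / rho


def pressure(rho: np.ndarray, c: float = 1.0) -> np.ndarray:
    """Diagnostic equation-of-state pressure p = cs^2 rho (cs^2 = c^2/3)."""
    return CS2 * c * c * np.asarray(rho)


def viscosity(lambda_f: float, dx: float = 1.0, dt: float = 1.0) -> float:
    """Kinematic viscosity of the LBGK fluid: (1/3)(dx^2/dt)(lambda - 1/2)."""
    return (dx * dx / dt) * CS2 * (lambda_f - 0.5)


def lambda_from_viscosity(nu: float, dx: float = 1.0, dt: float = 1.0) -> float:
    """Invert the viscosity relation; rejects the zero-viscosity boundary."""
    lam = 0.5 + 3.0 * nu * dt / (dx * dx)
    if lam <= 0.5:
        raise StabilityError("zero or negative viscosity: lambda would be <= 1/2")
    return lam


def _first_bad_node(f: np.ndarray):
    bad = ~np.isfinite(f)
    if bad.any():
        idx = np.unravel_index(int(np.argmax(bad)), f.shape)
        return idx[1:]  # spatial part
    return None


def stream(f: np.ndarray, dir_axis: int = 0) -> np.ndarray:
    """Propagate each population one link along its direction (periodic wrap).

    ``dir_axis`` indexes the 19 directions (0 for f, 1 for the tensor field G);
    the last three axes are the spatial grid.  Wall schemes overwrite the
    wrapped values afterwards.
    """
    out = np.empty_like(f)
    sp = tuple(range(f.ndim - 3, f.ndim))
    idx = [slice(None)] * f.ndim
    for a in range(19):
        c = DIRECTIONS[a]
        idx[dir_axis] = a
        sl = tuple(idx)
        out[sl] = np.roll(f[sl], shift=tuple(int(v) for v in c),
                          axis=tuple(s - 1 for s in sp))
    return out


def collide(f: np.ndarray, feq: np.ndarray, lambda_f: float,
            Fa: np.ndarray | None = None) -> np.ndarray:
    """LBGK relaxation toward feq plus the (already weighted) force term."""
    out = f + (feq - f) / lambda_f
    if Fa is not None:
        out += Fa
    return out


def collide_and_stream(f: np.ndarray, rho: np.ndarray, u: np.ndarray,
                       lambda_f: float, F: np.ndarray | None = None) -> np.ndarray:
    """One LBGK step: collide with Guo forcing at (rho, u), then stream.

    ``rho`` and ``u`` must be the refreshed (half-force corrected) moments of
    ``f``.  Boundary handling is applied separately by the caller.
    """
    feq = equilibrium_distribution(rho, u)
    Fa = force_term(u, F, lambda_f) if F is not None else None
    fpost = collide(f, feq, lambda_f, Fa)
    if not np.all(np.isfinite(fpost)):
        raise NumericalBlowupError("population blow-up after collision",
                                   node=_first_bad_node(fpost))
    return stream(fpost)
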