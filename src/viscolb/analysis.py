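"""Dimensionless groups, sector symmetry, trajectory and stress diagnostics.

Cross-section positions are normalised by the half-width and half-height so a
particle location reads as (y, z) in [-1, 1]^2, matching the labels used for
the trajectory maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from viscolb.errors import InvalidStateError
from viscolb.stress import PAIR_INDEX


@dataclass(frozen=True)
class DimensionlessGroups:
    """Re = rho U L / eta_t, Wi = lambda_p U / L, El = Wi/Re, blockage d/h."""

    Re: float
    Wi: float
    blockage: float
    U: float
    L: float

    @property
    def El(self) -> float:
        return self.Wi / self.Re


def dimensionless_groups(rho: float, U: float, L: float, eta_t: float,
                         lambda_p: float, diameter: float = 0.0,
                         h: float | None = None) -> DimensionlessGroups:
    """Evaluate the control parameters from primitive quantities (any unit system)."""
    Re = rho * U * L / eta_t
    Wi = lambda_p * U / L
    blk = diameter / h if h else 0.0
    return DimensionlessGroups(Re=Re, Wi=Wi, blockage=blk, U=U, L=L)


def rotation_angles(P: np.ndarray) -> tuple[float, float, float]:
    """Angles (deg) between the orientation vector P and the x, y, z axes."""
    P = np.asarray(P, dtype=float)
    norm = np.linalg.norm(P)
    if norm == 0.0:
        raise InvalidStateError("orientation vector has zero length")
    return tuple(float(np.degrees(np.arccos(np.clip(c / norm, -1.0, 1.0)))) for c in P)


def rotation_speed(P_prev: np.ndarray, P_next: np.ndarray, dt_steps: float = 1.0) -> float:
    """Rotation rate (rad per step) from two successive orientation vectors."""
    a = np.asarray(P_prev, float) / np.linalg.norm(P_prev)
    b = np.asarray(P_next, float) / np.linalg.norm(P_next)
    return float(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0)) / dt_steps)


def first_normal_stress_difference(tau6: np.ndarray, profile_axis: int = 1) -> np.ndarray:
    """N1 = tau_xx - tau_nn with n the shear-gradient (profile) axis (1=y, 2=z)."""
    if profile_axis not in (1, 2):
        raise InvalidStateError("profile axis must be 1 (y) or 2 (z)")
    txx = tau6[PAIR_INDEX[0, 0]]
    tnn = tau6[PAIR_INDEX[profile_axis, profile_axis]]
    return txx - tnn


# ---------------------------------------------------------------------------
# sector symmetry of the cross-section
# ---------------------------------------------------------------------------

#: mirror group of the square section (8 elements: reflections + diagonal swap)
_SQUARE_OPS = [(sy, sz, sw) for sy in (1, -1) for sz in (1, -1) for sw in (False, True)]
#: mirror group of the rectangular section (4 elements)
_RECT_OPS = [(sy, sz, False) for sy in (1, -1) for sz in (1, -1)]


def _apply(op, y, z):
    sy, sz, swap = op
    y, z = sy * y, sz * z
    return (z, y) if swap else (y, z)


def canonical_sector(yz, square: bool = True):
    """Map a normalised cross-section point into the canonical sector.

    Square: representative with 0 <= z <= y (one of 8 images); rectangle:
    first quadrant 0 <= y, 0 <= z (one of 4).
    """
    y, z = float(yz[0]), float(yz[1])
    y, z = abs(y), abs(z)
    if square and z > y:
        y, z = z, y
    return (y, z)


def mirror_points(yz, square: bool = True) -> list[tuple[float, float]]:
    """Full symmetry orbit of a point (duplicates removed, order deterministic)."""
    ops = _SQUARE_OPS if square else _RECT_OPS
    out, seen = [], set()
    for op in ops:
        p = _apply(op, float(yz[0]), float(yz[1]))
        key = (round(p[0], 12), round(p[1], 12))
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def mirror_trajectories(y: np.ndarray, z: np.ndarray, square: bool = True):
    """Tile one sector trajectory over the full cross-section via the mirror group."""
    ops = _SQUARE_OPS if square else _RECT_OPS
    out = []
    for op in ops:
        yy, zz = _apply(op, np.asarray(y, float), np.asarray(z, float))
        out.append((yy, zz))
    return out


def detect_equilibrium(y: np.ndarray, z: np.ndarray, window: int,
                       tol: float = 0.005):
    """Declare focusing converged when the trailing-window wander is below tol.

    Returns (converged, (y_eq, z_eq)) with the window-mean position.  The
    wander is the maximum distance of any trailing-window sample from the
    window mean, in normalised half-extent units.
    """
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if len(y) < 2 * window:
        return False, (float("nan"), float("nan"))
    yw, zw = y[-window:], z[-window:]
    ym, zm = yw.mean(), zw.mean()
    wander = float(np.sqrt((yw - ym) ** 2 + (zw - zm) ** 2).max())
    return wander < tol, (float(ym), float(zm))


# ---------------------------------------------------------------------------
# trajectory record
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryRecord:
    """Per-sample particle state: step, normalised (y, z), angles, rotation rate."""

    step: list = field(default_factory=list)
    y: list = field(default_factory=list)
    z: list = field(default_factory=list)
    theta_x: list = field(default_factory=list)
    theta_y: list = field(default_factory=list)
    theta_z: list = field(default_factory=list)
    omega: list = field(default_factory=list)

    def append(self, step: int, yz, P, P_prev=None, dt_steps: float = 1.0) -> None:
        tx, ty, tz = rotation_angles(P)
        om = rotation_speed(P_prev, P, dt_steps) if P_prev is not None else 0.0
        self.step.append(int(step))
        self.y.append(float(yz[0]))
        self.z.append(float(yz[1]))
        self.theta_x.append(tx)
        self.theta_y.append(ty)
        self.theta_z.append(tz)
        self.omega.append(om)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": self.step, "y": self.y, "z": self.z,
            "theta_x": self.theta_x, "theta_y": self.theta_y,
            "theta_z": self.theta_z, "omega": self.omega,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrajectoryRecord":
        df = pd.read_csv(path)
        rec = cls()
        for col in ("step", "y", "z", "theta_x", "theta_y", "theta_z", "omega"):
            getattr(rec, col).extend(df[col].tolist())
        return rec
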