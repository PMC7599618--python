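"""Oldroyd-B polymer stress transported by a second D3Q19 distribution set.

Six independent components of the symmetric stress tensor tau are evolved,
each carried by 19 tensor populations ``G[k, alpha, x, y, z]`` (k indexes the
Voigt pairs xx, yy, zz, xy, xz, yz).  The recovered tau feeds the elastic body
force F_V = div(tau) back into the solvent lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from viscolb import lattice
from viscolb.errors import ConfigurationError, NumericalBlowupError, StabilityError
from viscolb.fdiff import masked_derivative

#: Voigt ordering of the independent tensor components
VOIGT = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))

#: tau6 index for each (i, j) pair
PAIR_INDEX = np.array([[0, 3, 4], [3, 1, 5], [4, 5, 2]])


@dataclass(frozen=True)
class PolymerSpec:
    """Oldroyd-B parameters in lattice units.

    beta is the solvent-to-total viscosity ratio; the polymer viscosity is
    eta_p = (1 - beta) eta_t.  lambda_g is the relaxation parameter of the
    tensor distribution; the artificial stress diffusivity it implies is
    nu_tilde = cs^2 (lambda_g - 1/2).
    """

    beta: float
    eta_t: float
    lambda_p: float
    lambda_g: float = 0.51

    def __post_init__(self):
        if not (0.0 < self.beta <= 1.0):
            raise ConfigurationError(f"beta must lie in (0, 1], got {self.beta}")
        if self.lambda_p < 0.0:
            raise ConfigurationError("lambda_p must be non-negative")
        if self.lambda_g <= 0.5:
            raise StabilityError("lambda_g must exceed 1/2")

    @property
    def eta_p(self) -> float:
        return (1.0 - self.beta) * self.eta_t

    @property
    def eta_s(self) -> float:
        return self.beta * self.eta_t

    @property
    def nu_tilde(self) -> float:
        return lattice.CS2 * (self.lambda_g - 0.5)


@dataclass
class StressDistributionField:
    """Tensor populations plus the recovered stress and the cached source."""

    G: np.ndarray           # (6, 19, nx, ny, nz)
    tau: np.ndarray         # (6, nx, ny, nz)
    chi_prev: np.ndarray    # (6, nx, ny, nz)


def tau6_to_matrix(tau6: np.ndarray) -> np.ndarray:
    """(6, ...) Voigt vector -> symmetric (3, 3, ...) tensor view."""
    return tau6[PAIR_INDEX]


def matrix_to_tau6(t: np.ndarray) -> np.ndarray:
    """Symmetric (3, 3, ...) tensor -> (6, ...) Voigt vector (upper triangle)."""
    return np.stack([t[i, j] for (i, j) in VOIGT])


def tensor_equilibrium(tau6: np.ndarray, u: np.ndarray,
                       bracket: np.ndarray | None = None) -> np.ndarray:
    """Equilibrium tensor populations w_a tau_ij [1 + 3c.u + 4.5(c.u)^2 - 1.5u^2].

    Summing over directions returns tau_ij exactly (velocity terms cancel by
    stencil isotropy).  ``bracket`` may be passed to reuse the solvent one.
    """
    if bracket is None:
        bracket = lattice.equilibrium_bracket(np.asarray(u, dtype=float))
    w = lattice.WEIGHTS.reshape((19,) + (1,) * (bracket.ndim - 1))
    return np.asarray(tau6)[:, None] * (w * bracket)[None]


def source_tensor(tau6: np.ndarray, grad_u: np.ndarray, spec: PolymerSpec) -> np.ndarray:
    """Constitutive source chi = tau.grad_u + grad_u^T.tau + (2 eta_p d - tau)/lambda_p.

    ``grad_u`` uses the convention grad_u[k, l] = d u_l / d x_k, so that steady
    shear u = (gdot*y, 0, 0) produces a positive tau_xx (positive N1).
    """
    if spec.lambda_p == 0.0:
        raise ConfigurationError(
            "lambda_p = 0 has no polymer dynamics; run in Newtonian mode instead")
    tau = tau6_to_matrix(np.asarray(tau6, dtype=float))
    A = np.asarray(grad_u, dtype=float)
    # (tau . A)_ij = tau_ik A_kj ; its transpose is A^T . tau
    TA = np.einsum('ik...,kj...->ij...', tau, A)
    d = 0.5 * (A + np.swapaxes(A, 0, 1))
    chi = TA + np.swapaxes(TA, 0, 1) + (2.0 * spec.eta_p * d - tau) / spec.lambda_p
    return matrix_to_tau6(chi)


def weighted_source(chi6: np.ndarray, u: np.ndarray, lambda_g: float) -> np.ndarray:
    """Direction-resolved source chi_ij,alpha = w_a chi_ij [1 + 3 k (c.u)], k=(lg-1/2)/lg."""
    cu = np.tensordot(lattice._CF, np.asarray(u, dtype=float), axes=([1], [0]))
    w = lattice.WEIGHTS.reshape((19,) + (1,) * (cu.ndim - 1))
    kappa = (lambda_g - 0.5) / lambda_g
    return np.asarray(chi6)[:, None] * (w * (1.0 + 3.0 * kappa * cu))[None]


def recover_stress(G: np.ndarray) -> np.ndarray:
    """tau_ij = sum_alpha G_ij,alpha (per node, Voigt layout)."""
    if not np.all(np.isfinite(G)):
        raise NumericalBlowupError("non-finite tensor populations")
    return G.sum(axis=1)


def tensor_collide_and_stream(G: np.ndarray, tau6: np.ndarray, u: np.ndarray,
                              chi6: np.ndarray, chi6_prev: np.ndarray,
                              lambda_g: float,
                              bracket: np.ndarray | None = None) -> np.ndarray:
    """One LBGK step of the tensor distribution.

    Post-collision value: G + (Geq - G)/lg + chi_a + 0.5*(chi_a - chi_a_prev),
    with the time derivative of the source taken by backward difference of the
    tensor chi; then streamed one link per direction.
    """
    Geq = tensor_equilibrium(tau6, u, bracket=bracket)
    chi_eff = chi6 + 0.5 * (chi6 - chi6_prev)
    src = weighted_source(chi_eff, u, lambda_g)
    Gpost = G + (Geq - G) / lambda_g + src
    if not np.all(np.isfinite(Gpost)):
        raise NumericalBlowupError("tensor population blow-up after collision")
    return lattice.stream(Gpost, dir_axis=1)


def velocity_gradient(u: np.ndarray, fluid_mask: np.ndarray,
                      periodic=(True, False, False)) -> np.ndarray:
    """grad_u[k, l] = d u_l / d x_k on the fluid mask (central/one-sided stencils)."""
    out = np.empty((3, 3) + u.shape[1:], dtype=float)
    for k in range(3):
        out[k] = masked_derivative(u, fluid_mask, axis=k, periodic=periodic[k])
    return out


def elastic_force(tau6: np.ndarray, fluid_mask: np.ndarray,
                  periodic=(True, False, False)) -> np.ndarray:
    """F_V = div(tau): (F_V)_j = sum_k d tau_kj / d x_k with the same stencils."""
    tau = tau6_to_matrix(np.asarray(tau6, dtype=float))
    out = np.zeros((3,) + tau.shape[2:], dtype=float)
    for k in range(3):
        out += masked_derivative(tau[k], fluid_mask, axis=k, periodic=periodic[k])
    return out
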