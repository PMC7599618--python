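"""Masked finite-difference stencils on the lattice.

Second-order central differences in the interior of the fluid mask, one-sided
second-order at mask edges (wall-adjacent fluid nodes), first-order where only
a single in-mask neighbour exists, zero on isolated nodes.  Values outside the
mask are never read.
"""

from __future__ import annotations

import numpy as np


def shift(a: np.ndarray, s: int, axis: int, periodic: bool, fill=0):
    """np.roll with the wrapped slab overwritten by ``fill`` when non-periodic."""
    out = np.roll(a, s, axis=axis)
    if not periodic and s != 0:
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(0, s) if s > 0 else slice(s, None)
        out[tuple(sl)] = fill
    return out


def masked_derivative(field: np.ndarray, mask: np.ndarray, axis: int,
                      periodic: bool = False) -> np.ndarray:
    """d(field)/dx_axis on the mask, in lattice units.

    Parameters
    ----------
    field : (..., nx, ny, nz)
    mask : (nx, ny, nz) boolean; True where the field is defined.
    axis : spatial axis 0..2.
    """
    fax = field.ndim - 3 + axis
    max_ = mask.ndim - 3 + axis

    mp = shift(mask, -1, max_, periodic, False)    # neighbour at i+1 in mask
    mm = shift(mask, +1, max_, periodic, False)
    mpp = shift(mask, -2, max_, periodic, False)
    mmm = shift(mask, +2, max_, periodic, False)

    fp = shift(field, -1, fax, periodic, 0.0)
    fm = shift(field, +1, fax, periodic, 0.0)
    fpp = shift(field, -2, fax, periodic, 0.0)
    fmm = shift(field, +2, fax, periodic, 0.0)

    out = np.zeros_like(field, dtype=float)
    central = mp & mm
    fwd2 = mp & mpp & ~mm
    bwd2 = mm & mmm & ~mp
    fwd1 = mp & ~mpp & ~mm
    bwd1 = mm & ~mmm & ~mp

    out = np.where(central, 0.5 * (fp - fm), out)
    out = np.where(fwd2, 0.5 * (-3.0 * field + 4.0 * fp - fpp), out)
    out = np.where(bwd2, 0.5 * (3.0 * field - 4.0 * fm + fmm), out)
    out = np.where(fwd1, fp - field, out)
    out = np.where(bwd1, field - fm, out)
    return np.where(mask, out, 0.0)
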