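"""Snapshot and checkpoint I/O: legacy-ASCII VTK structured grids and HDF5.

VTK snapshots carry the macroscopic fields (rho, u, tau, N1); HDF5
checkpoints store every population for bit-exact restart.
"""

from __future__ import annotations

import numpy as np

from viscolb.stress import PAIR_INDEX

_TAU_NAMES = ("tau_xx", "tau_yy", "tau_zz", "tau_xy", "tau_xz", "tau_yz")


def write_vtk_structured(path, rho: np.ndarray, u: np.ndarray,
                         tau6: np.ndarray | None = None,
                         extra_scalars: dict | None = None) -> None:
    """Legacy ASCII STRUCTURED_POINTS file with point data on the full lattice."""
    nx, ny, nz = rho.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nviscolb snapshot\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\nSPACING 1 1 1\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")

        def scal(name, arr):
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            # VTK structured points iterate x fastest
            np.savetxt(fh, arr.transpose(2, 1, 0).reshape(-1, 1), fmt="%.12g")

        scal("rho", rho)
        fh.write("VECTORS u double\n")
        np.savetxt(fh, np.moveaxis(u, 0, -1).transpose(2, 1, 0, 3).reshape(-1, 3),
                   fmt="%.12g")
        if tau6 is not None:
            for k, name in enumerate(_TAU_NAMES):
                scal(name, tau6[k])
            n1y = tau6[PAIR_INDEX[0, 0]] - tau6[PAIR_INDEX[1, 1]]
            scal("N1_y", n1y)
            n1z = tau6[PAIR_INDEX[0, 0]] - tau6[PAIR_INDEX[2, 2]]
            scal("N1_z", n1z)
        for name, arr in (extra_scalars or {}).items():
            scal(name, arr)


def write_checkpoint(path, *, step: int, f: np.ndarray, G: np.ndarray | None,
                     chi_prev: np.ndarray | None, particles: list[np.ndarray],
                     F: np.ndarray | None = None, config_yaml: str = "") -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["step"] = step
        h5.attrs["config"] = config_yaml
        h5.create_dataset("f", data=f)
        if F is not None:
            # the assembled body force is part of the state: it was built from
            # the pre-advection node positions of the previous step
            h5.create_dataset("F", data=F)
        if G is not None:
            h5.create_dataset("G", data=G)
            h5.create_dataset("chi_prev", data=chi_prev)
        for i, X in enumerate(particles):
            h5.create_dataset(f"particle_{i}", data=X)


def read_checkpoint(path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as h5:
        out["step"] = int(h5.attrs["step"])
        out["config"] = str(h5.attrs["config"])
        out["f"] = h5["f"][...]
        out["F"] = h5["F"][...] if "F" in h5 else None
        out["G"] = h5["G"][...] if "G" in h5 else None
        out["chi_prev"] = h5["chi_prev"][...] if "chi_prev" in h5 else None
        parts = []
        i = 0
        while f"particle_{i}" in h5:
            parts.append(h5[f"particle_{i}"][...])
            i += 1
        out["particles"] = parts
    return out
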