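"""Configuration, lattice calibration, run orchestration and analytic fixtures.

Two layers: :class:`LatticeRun` advances the coupled solver purely in lattice
units (dx = dt = 1) and is what the test fixtures drive directly;
:class:`SimulationConfig` holds the physical parameter block, converts it once
to lattice units, and builds a :class:`Simulation` with trajectory/snapshot
output around a ``LatticeRun``.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from viscolb import analysis, boundaries, ibm, lattice, membrane, output, stress
from viscolb.errors import ConfigurationError, StabilityError

log = logging.getLogger("viscolb")


# ---------------------------------------------------------------------------
# particle state
# ---------------------------------------------------------------------------

@dataclass
class ParticleState:
    """A membrane particle: frozen reference mesh + current (unwrapped) nodes."""

    mesh: membrane.MembraneMesh
    X: np.ndarray
    #: index of the node anchoring the orientation vector P
    anchor: int = 0

    @property
    def centroid(self) -> np.ndarray:
        return self.X.mean(axis=0)

    @property
    def P(self) -> np.ndarray:
        return self.X[self.anchor] - self.centroid


def make_particle(diameter: float, n_faces: int, center,
                  moduli: membrane.ElasticModuli,
                  orient_x: bool = True) -> ParticleState:
    """Build a sphere particle (lattice units) with P initially along +x."""
    mesh = membrane.generate_sphere_mesh(diameter, n_faces, moduli=moduli)
    X = mesh.nodes + np.asarray(center, dtype=float)
    p = ParticleState(mesh=mesh, X=X)
    if orient_x:
        # anchor = node closest to the +x pole of the sphere
        p.anchor = int(np.argmax(mesh.nodes[:, 0]))
    return p


# ---------------------------------------------------------------------------
# lattice-unit solver
# ---------------------------------------------------------------------------

class LatticeRun:
    """The per-step loop of the coupled solver, entirely in lattice units."""

    def __init__(self, shape, section, wallset, lambda_f,
                 accel: float = 0.0, polymer: stress.PolymerSpec | None = None,
                 particles: list[ParticleState] | None = None,
                 periodic=(True, False, False), rho0: float = 1.0,
                 subsonic_warn: float = 0.1, subsonic_abort: float = 0.3,
                 membrane_substeps: int = 1):
        self.shape = tuple(int(n) for n in shape)
        nx, ny, nz = self.shape
        if section.shape != (ny, nz):
            raise ConfigurationError("section mask does not match lattice shape")
        self.section = section
        self.fluid3d = np.broadcast_to(section, self.shape).copy()
        self.wallset = wallset
        self.lambda_f = float(lambda_f)
        if not (0.5 < self.lambda_f < 2.0):
            raise StabilityError(
                f"lambda_f = {self.lambda_f:.4g} outside (1/2, 2); adjust dt or dx")
        self.accel = float(accel)
        self.polymer = polymer
        self.particles = particles or []
        self.periodic = periodic
        self.rho0 = float(rho0)
        self.subsonic_warn = subsonic_warn
        self.subsonic_abort = subsonic_abort
        if membrane_substeps < 1:
            raise ConfigurationError("membrane_substeps must be >= 1")
        self.membrane_substeps = int(membrane_substeps)

        self.f = lattice.equilibrium_distribution(
            np.full(self.shape, self.rho0), np.zeros((3,) + self.shape))
        self.rho = np.full(self.shape, self.rho0)
        self.u = np.zeros((3,) + self.shape)
        if polymer is not None:
            self.G = np.zeros((6, 19) + self.shape)
            self.chi_prev = np.zeros((6,) + self.shape)
            self.tau6 = np.zeros((6,) + self.shape)
        else:
            self.G = None
            self.chi_prev = None
            self.tau6 = None
        self.step_count = 0
        self._refresh_force_and_moments()

    # -- initialisation helpers ------------------------------------------------

    def initialize_fields(self, u: np.ndarray, tau6: np.ndarray | None = None,
                          rho: np.ndarray | None = None) -> None:
        """Start from given macroscopic fields: f = feq(rho, u), G = Geq(tau, u)."""
        rho = np.full(self.shape, self.rho0) if rho is None else rho
        self.f = lattice.equilibrium_distribution(rho, u)
        if self.polymer is not None and tau6 is not None:
            self.G = stress.tensor_equilibrium(tau6, u)
        self._refresh_force_and_moments()

    # -- stepping --------------------------------------------------------------

    def _assemble_force(self) -> np.ndarray:
        """Total body force F_D + F_V + F_A consistent with the current f/G/X."""
        F = np.zeros((3,) + self.shape)
        F[0] = self.accel * self.f.sum(axis=0)
        if self.polymer is not None:
            self.tau6 = stress.recover_stress(self.G)
            F += stress.elastic_force(self.tau6, self.fluid3d, self.periodic)
        for p in self.particles:
            fn = membrane.nodal_forces(p.mesh, p.X)
            F += ibm.spread_forces(self._wrapped(p.X), fn, self.shape,
                                   fluid_mask=self.fluid3d, periodic=self.periodic)
        F *= self.fluid3d
        return F

    def _refresh_force_and_moments(self) -> None:
        self.F = self._assemble_force()
        self.rho, self.u = lattice.macroscopic_moments(self.f, self.F)

    def _wrapped(self, X: np.ndarray) -> np.ndarray:
        out = np.array(X, dtype=float)
        for ax in range(3):
            if self.periodic[ax]:
                out[:, ax] = np.mod(out[:, ax], self.shape[ax])
        return out

    def step(self) -> None:
        """Advance one time step.

        On entry self.F / self.rho / self.u are consistent with self.f (they
        are refreshed at the end of the previous step).  Order: collide and
        stream both distributions -> walls -> recover tau, reassemble forces ->
        refresh moments -> interpolate the new velocity and advect the nodes.
        """
        F, u = self.F, self.u
        lattice.check_subsonic(u, warn=self.subsonic_warn,
                               abort=self.subsonic_abort)
        bracket = lattice.equilibrium_bracket(u)
        if self.polymer is not None:
            grad_u = stress.velocity_gradient(u, self.fluid3d, self.periodic)
            chi = stress.source_tensor(self.tau6, grad_u, self.polymer)
            self.G = stress.tensor_collide_and_stream(
                self.G, self.tau6, u, chi, self.chi_prev,
                self.polymer.lambda_g, bracket=bracket)
            self.chi_prev = chi

        feq = lattice._wexpand(4) * self.rho * bracket
        Fa = lattice.force_term(u, F, self.lambda_f)
        self.f = lattice.stream(lattice.collide(self.f, feq, self.lambda_f, Fa))

        # walls: non-equilibrium extrapolation for both distributions, using
        # post-stream neighbour moments (force/velocity of the completed step)
        boundaries.apply_walls_f(self.f, F, self.wallset)
        if self.polymer is not None:
            tau_post = self.G.sum(axis=1)
            boundaries.apply_walls_G(self.G, tau_post, self.u, self.wallset)

        # new forces and moments, then move the membrane with the new velocity
        self._refresh_force_and_moments()
        k = self.membrane_substeps
        for p in self.particles:
            # optional sub-stepping for stiff membranes: the node path is
            # integrated in k sub-steps against the frozen fluid velocity
            for _ in range(k):
                up = ibm.interpolate_velocity(self.u, self._wrapped(p.X),
                                              periodic=self.periodic)
                p.X = ibm.advect_nodes(p.X, up, dt=1.0 / k)
        self.step_count += 1

    def run(self, n_steps: int, record_every: int = 0, on_record=None) -> None:
        for _ in range(n_steps):
            self.step()
            if record_every and self.step_count % record_every == 0 and on_record:
                on_record(self)

    # -- diagnostics -----------------------------------------------------------

    def mean_velocity(self) -> float:
        """Cross-section mean streamwise velocity over fluid nodes."""
        return float(self.u[0][self.fluid3d].mean())

    def total_mass(self) -> float:
        return float(self.f.sum())


# ---------------------------------------------------------------------------
# physical configuration
# ---------------------------------------------------------------------------

#: particle presets: diameters in metres, element counts of the membrane mesh
PARTICLE_PRESETS = {
    "small": {"diameter": 6e-6, "n_faces": 120},
    "large": {"diameter": 12e-6, "n_faces": 480},
}

PRESET_GEOMETRIES = {
    # standard cross-sections: square 50 um; rectangles h = 40 um, w = h/AR
    "AR1": dict(kind="duct", h=50e-6, w=50e-6),
    "AR1_2": dict(kind="duct", h=40e-6, w=80e-6),
    "AR1_3": dict(kind="duct", h=40e-6, w=120e-6),
    "AR1_4": dict(kind="duct", h=40e-6, w=160e-6),
}


@dataclass
class GeometryConfig:
    kind: str = "duct"          # duct | tube | shear
    h: float = 50e-6            # height (duct) or diameter (tube) or gap (shear)
    w: float = 50e-6            # width; ignored for tube
    dx: float = 1e-6
    length: int = 12            # lattice nodes along the periodic flow axis
    u_wall: float = 0.0         # shear-box wall speed (lattice units)

    @property
    def channel(self) -> boundaries.ChannelGeometry:
        return boundaries.ChannelGeometry(h=self.h, w=self.w, dx=self.dx)


@dataclass
class FluidConfig:
    Re: float = 1.0
    Wi: float = 0.0
    beta: float = 0.3
    nu: float = 1e-6            # total kinematic viscosity (m^2/s)
    dt: float = 1e-7
    rho: float = 1000.0
    lambda_g: float = 0.51


@dataclass
class ParticleConfig:
    diameter: float = 6e-6
    n_faces: int = 120
    position: tuple = (0.0, 0.0)   # normalised cross-section (y, z) in [-1, 1]
    moduli: dict | None = None     # SI moduli; None -> rigid preset


@dataclass
class RunConfig:
    steps: int = 1000
    output_every: int = 1000
    checkpoint_every: int = 0
    outdir: str = "out"


@dataclass
class SimulationConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    particles: list = field(default_factory=list)
    run: RunConfig = field(default_factory=RunConfig)

    def validate(self) -> None:
        g, fl = self.geometry, self.fluid
        if g.kind not in ("duct", "tube", "shear"):
            raise ConfigurationError(f"unknown geometry kind {g.kind!r}")
        if fl.Wi > 0 and not (0 < fl.beta < 1):
            raise ConfigurationError("viscoelastic runs need 0 < beta < 1")
        for pc in self.particles:
            if pc.diameter / 2 + 2 * g.dx >= min(g.h, g.w) / 2:
                raise ConfigurationError(
                    f"particle d={pc.diameter} does not fit the cross-section")

    # -- (de)serialisation -----------------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        raw = yaml.safe_load(text)
        cfg = cls(
            geometry=GeometryConfig(**raw.get("geometry", {})),
            fluid=FluidConfig(**raw.get("fluid", {})),
            particles=[ParticleConfig(**{**p, "position": tuple(p.get("position", (0, 0)))})
                       for p in raw.get("particles", [])],
            run=RunConfig(**raw.get("run", {})),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())


@dataclass(frozen=True)
class Calibration:
    """Derived lattice-unit parameters, logged with every run."""

    lambda_f: float
    lambda_p: float       # polymer relaxation time in steps (0 if Newtonian)
    a: float              # driving acceleration, lattice units
    U: float              # nominal mean velocity, lattice units
    nu_total: float       # total kinematic viscosity, lattice units
    L: float              # characteristic length, lattice units
    eta_t: float          # total dynamic viscosity, lattice units (rho0 = 1)


def lattice_calibration(cfg: SimulationConfig) -> Calibration:
    """Convert the physical block to lattice units.

    The LBGK relaxation time carries the *solvent* viscosity beta*nu; the
    driving acceleration and the dimensionless groups use the total nu.
    """
    g, fl = cfg.geometry, cfg.fluid
    nu_l = fl.nu * fl.dt / g.dx ** 2
    beta = fl.beta if fl.Wi > 0 else 1.0
    lam = lattice.lambda_from_viscosity(beta * nu_l)
    if not (0.5 < lam < 2.0):
        raise StabilityError(
            f"lambda_f = {lam:.4g} outside (1/2, 2): pick dt ~ dx^2/(10*nu)")
    if g.kind == "tube":
        L_l = round(g.h / g.dx)          # characteristic length = diameter
    else:
        L_l = g.channel.L / g.dx
    a_l = boundaries.driving_acceleration(fl.Re, nu_l, L_l)
    U_l = nu_l * fl.Re / L_l
    lam_p = fl.Wi * L_l / U_l if fl.Wi > 0 else 0.0
    return Calibration(lambda_f=lam, lambda_p=lam_p, a=a_l, U=U_l,
                       nu_total=nu_l, L=L_l, eta_t=nu_l)


def build_lattice_run(cfg: SimulationConfig) -> LatticeRun:
    """Assemble the lattice-unit solver for a physical configuration."""
    cfg.validate()
    g, fl = cfg.geometry, cfg.fluid
    cal = lattice_calibration(cfg)
    periodic = (True, False, False)
    if g.kind == "duct":
        ny = round(g.h / g.dx) + 1
        nz = round(g.w / g.dx) + 1
        section = boundaries.duct_section(ny, nz)
        ws = boundaries.build_wallset(section)
    elif g.kind == "tube":
        d = round(g.h / g.dx)
        n = d + 2
        section = boundaries.tube_section(n, radius=d / 2.0 + 0.25)
        ny = nz = n
        ws = boundaries.build_wallset(section)
    else:  # shear
        ny = round(g.h / g.dx) + 1
        nz = round(g.w / g.dx)
        section, ws, _ = boundaries.shear_box(g.u_wall, ny, nz)
        periodic = (True, False, True)
    shape = (g.length, ny, nz)

    polymer = None
    if fl.Wi > 0:
        polymer = stress.PolymerSpec(beta=fl.beta, eta_t=cal.eta_t,
                                     lambda_p=cal.lambda_p, lambda_g=fl.lambda_g)

    particles = []
    for pc in cfg.particles:
        if pc.moduli:
            mod_l = membrane.moduli_to_lattice(
                membrane.ElasticModuli(**pc.moduli), g.dx, fl.dt, rho=fl.rho)
        else:
            # desk-scale rigid preset (already in lattice units): the
            # reference SI moduli exceed the explicit-coupling stability
            # limit when converted at coarse dx/dt
            mod_l = membrane.RIGID_MODULI_LATTICE
        cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
        center = (shape[0] / 2.0,
                  cy + pc.position[0] * (ny - 1) / 2.0,
                  cz + pc.position[1] * (nz - 1) / 2.0)
        particles.append(make_particle(pc.diameter / g.dx, pc.n_faces, center, mod_l))

    accel = cal.a if g.kind != "shear" else 0.0
    return LatticeRun(shape, section, ws, cal.lambda_f, accel=accel,
                      polymer=polymer, particles=particles, periodic=periodic)


# ---------------------------------------------------------------------------
# simulation wrapper with outputs
# ---------------------------------------------------------------------------

class Simulation:
    """Run orchestration: trajectory CSV, VTK snapshots, HDF5 checkpoints."""

    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.cal = lattice_calibration(cfg)
        self.lat = build_lattice_run(cfg)
        self.records = [analysis.TrajectoryRecord() for _ in self.lat.particles]
        self._P_prev = [p.P.copy() for p in self.lat.particles]

    # trajectory positions in normalised half-extent coordinates
    def _norm_yz(self, p: ParticleState):
        _, ny, nz = self.lat.shape
        c = p.centroid
        return ((c[1] - (ny - 1) / 2.0) / ((ny - 1) / 2.0),
                (c[2] - (nz - 1) / 2.0) / ((nz - 1) / 2.0))

    def record(self) -> None:
        for i, p in enumerate(self.lat.particles):
            self.records[i].append(self.lat.step_count, self._norm_yz(p), p.P,
                                   P_prev=self._P_prev[i],
                                   dt_steps=max(1, self.cfg.run.output_every))
            self._P_prev[i] = p.P.copy()

    def run(self, steps: int | None = None, outdir=None) -> dict:
        import pathlib

        rc = self.cfg.run
        steps = rc.steps if steps is None else steps
        out = pathlib.Path(outdir or rc.outdir)
        out.mkdir(parents=True, exist_ok=True)
        cadence = max(1, rc.output_every)
        self.record()
        while self.lat.step_count < steps:
            self.lat.step()
            if self.lat.step_count % cadence == 0:
                self.record()
                if self.lat.step_count % (10 * cadence) == 0:
                    self._digest()
            if rc.checkpoint_every and self.lat.step_count % rc.checkpoint_every == 0:
                self.checkpoint(out / f"checkpoint_{self.lat.step_count}.h5")
        for i, rec in enumerate(self.records):
            rec.to_csv(out / f"trajectory_{i}.csv")
        self.snapshot(out / f"snapshot_{self.lat.step_count}.vtk")
        summary = self.summary()
        with open(out / "summary.yaml", "w") as fh:
            yaml.safe_dump(summary, fh, sort_keys=False)
        return summary

    def _digest(self) -> None:
        lat = self.lat
        msg = (f"step {lat.step_count}: mean u={lat.mean_velocity():.4g}, "
               f"max |u|={np.abs(lat.u).max():.4g}")
        if lat.G is not None:
            msg += f", max |tau|={np.abs(lat.G.sum(axis=1)).max():.4g}"
        for i, p in enumerate(lat.particles):
            y, z = self._norm_yz(p)
            msg += f", particle{i} yz=({y:+.3f},{z:+.3f})"
        log.info(msg)

    def measured_groups(self) -> analysis.DimensionlessGroups:
        """Re/Wi/El recomputed from the simulated mean streamwise velocity."""
        U = self.lat.mean_velocity()
        lam_p = self.lat.polymer.lambda_p if self.lat.polymer else 0.0
        return analysis.dimensionless_groups(
            rho=1.0, U=U, L=self.cal.L, eta_t=self.cal.eta_t, lambda_p=lam_p)

    def summary(self) -> dict:
        fl = self.cfg.fluid
        meas = self.measured_groups()
        return {
            "steps": int(self.lat.step_count),
            "parameters": {"dx": self.cfg.geometry.dx, "dt": fl.dt, "nu": fl.nu,
                           "beta": fl.beta},
            "calibration": asdict(self.cal),
            "nominal": {"Re": fl.Re, "Wi": fl.Wi,
                        "El": (fl.Wi / fl.Re) if fl.Re else 0.0},
            "measured": {"Re": meas.Re, "Wi": meas.Wi,
                         "El": meas.El if meas.Re else 0.0,
                         "U": meas.U},
        }

    def snapshot(self, path) -> None:
        lat = self.lat
        tau6 = lat.G.sum(axis=1) if lat.G is not None else None
        output.write_vtk_structured(path, lat.rho, lat.u, tau6)

    def checkpoint(self, path) -> None:
        lat = self.lat
        output.write_checkpoint(
            path, step=lat.step_count, f=lat.f, G=lat.G, chi_prev=lat.chi_prev,
            particles=[p.X for p in lat.particles], F=lat.F,
            config_yaml=self.cfg.to_yaml())

    @classmethod
    def resume(cls, path) -> "Simulation":
        data = output.read_checkpoint(path)
        sim = cls(SimulationConfig.from_yaml(data["config"]))
        lat = sim.lat
        lat.f = data["f"]
        if data["G"] is not None:
            lat.G = data["G"]
            lat.chi_prev = data["chi_prev"]
        for p, X in zip(lat.particles, data["particles"]):
            p.X = X
        lat.step_count = data["step"]
        if data["F"] is not None:
            lat.F = data["F"]
            lat.rho, lat.u = lattice.macroscopic_moments(lat.f, lat.F)
            if lat.G is not None:
                lat.tau6 = stress.recover_stress(lat.G)
        else:
            lat._refresh_force_and_moments()
        sim._P_prev = [p.P.copy() for p in lat.particles]
        return sim


# ---------------------------------------------------------------------------
# analytic fixtures
# ---------------------------------------------------------------------------

def analytic_poiseuille(y, accel: float, nu_total: float, R: float,
                        beta: float, lambda_p: float, eta_t: float,
                        geometry: str = "pipe"):
    """Steady body-force-driven profile and Oldroyd-B stresses.

    ``y`` is the distance from the centreline; ``R`` the pipe radius (or
    half-gap for the plane case).  Returns (u, tau_xx, tau_xy) with
    tau_xx = 2 lambda_p eta_t (1-beta) (du/dy)^2 and
    tau_xy = eta_t (1-beta) du/dy.
    """
    y = np.asarray(y, dtype=float)
    if geometry == "pipe":
        u = accel * (R * R - y * y) / (4.0 * nu_total)
        dudy = -accel * y / (2.0 * nu_total)
    elif geometry == "plane":
        u = accel * (R * R - y * y) / (2.0 * nu_total)
        dudy = -accel * y / nu_total
    else:
        raise ConfigurationError(f"unknown geometry {geometry!r}")
    tau_xy = eta_t * (1.0 - beta) * dudy
    tau_xx = 2.0 * lambda_p * eta_t * (1.0 - beta) * dudy ** 2
    return u, tau_xx, tau_xy


def analytic_duct_profile(y, z, accel: float, nu_total: float,
                          half_h: float, half_w: float, n_terms: int = 60):
    """Newtonian rectangular-duct profile (Fourier series in the y direction).

    ``y``/``z`` measured from the duct centre; |y| <= half_h, |z| <= half_w.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    b, c = half_h, half_w
    u = np.zeros(np.broadcast(y, z).shape)
    for k in range(n_terms):
        n = 2 * k + 1
        kn = n * np.pi / (2.0 * b)
        # overflow-safe cosh ratio: exp(kn(|z|-c)) (1+e^-2kn|z|)/(1+e^-2kn c)
        az = np.abs(z)
        ratio = np.exp(kn * (az - c)) * (1.0 + np.exp(-2.0 * kn * az)) \
            / (1.0 + np.exp(-2.0 * kn * c))
        term = ((-1.0) ** k / n ** 3) * np.cos(kn * y) * (1.0 - ratio)
        u = u + term
    return 16.0 * accel * b * b / (nu_total * np.pi ** 3) * u
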