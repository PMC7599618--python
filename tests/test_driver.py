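import warnings

import numpy as np
import pytest
import yaml

from viscolb import boundaries, membrane, stress
from viscolb.driver import (
    Calibration,
    LatticeRun,
    ParticleConfig,
    Simulation,
    SimulationConfig,
    analytic_duct_profile,
    analytic_poiseuille,
    build_lattice_run,
    lattice_calibration,
)
from viscolb.errors import ConfigurationError, StabilityError
from tests.conftest import RIGID_LATTICE, centered_particle, make_shear_run


class TestCalibration:
    def test_reference_block_lambda(self):
        # dx = 1e-6 m, dt = 1e-7 s, nu = 1e-6 m^2/s: additive term 3*nu*dt/dx^2
        # equals 0.3, so a Newtonian run has lambda = 0.8; the viscoelastic
        # lattice carries only the solvent share beta*nu
        cfg = SimulationConfig()
        cfg.fluid.nu = 1e-6
        cfg.fluid.dt = 1e-7
        cfg.geometry.dx = 1e-6
        cfg.fluid.Wi = 0.0
        cal = lattice_calibration(cfg)
        assert cal.lambda_f == pytest.approx(0.8, rel=1e-12)
        cfg.fluid.Wi = 0.3
        cfg.fluid.beta = 0.3
        cal2 = lattice_calibration(cfg)
        assert cal2.lambda_f == pytest.approx(0.5 + 0.3 * 0.3, rel=1e-12)

    def test_zero_viscosity_rejected(self):
        cfg = SimulationConfig()
        cfg.fluid.nu = 0.0
        with pytest.raises(StabilityError):
            lattice_calibration(cfg)

    def test_calibration_roundtrip(self):
        cfg = SimulationConfig()
        cfg.fluid.Wi = 0.0
        cal = lattice_calibration(cfg)
        nu_back = (cal.lambda_f - 0.5) / 3.0  # lattice units
        assert nu_back == pytest.approx(cal.nu_total, rel=1e-12)

    def test_wi_sets_lambda_p(self):
        cfg = SimulationConfig()
        cfg.fluid.Wi = 0.3
        cal = lattice_calibration(cfg)
        assert cal.lambda_p == pytest.approx(0.3 * cal.L / cal.U, rel=1e-12)

    def test_particle_fit_validation(self):
        cfg = SimulationConfig()
        cfg.particles = [ParticleConfig(diameter=49e-6)]
        with pytest.raises(ConfigurationError, match="fit"):
            cfg.validate()


class TestConfigSerialisation:
    def test_yaml_roundtrip(self):
        cfg = SimulationConfig()
        cfg.fluid.Wi = 0.2
        cfg.particles = [ParticleConfig(position=(-0.4, -0.3))]
        text = cfg.to_yaml()
        back = SimulationConfig.from_yaml(text)
        assert back.fluid.Wi == 0.2
        assert back.particles[0].position == (-0.4, -0.3)

    def test_from_file(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump({
            "geometry": {"kind": "duct", "h": 40e-6, "w": 80e-6, "dx": 2e-6,
                         "length": 8},
            "fluid": {"Re": 2.5, "Wi": 0.2, "beta": 0.3},
            "run": {"steps": 10},
        }))
        cfg = SimulationConfig.from_file(p)
        assert cfg.geometry.channel.AR == pytest.approx(0.5)

    def test_unknown_kind_rejected(self):
        cfg = SimulationConfig()
        cfg.geometry.kind = "helix"
        with pytest.raises(ConfigurationError):
            cfg.validate()


class TestAnalyticFixtures:
    def test_centreline_stresses_vanish(self):
        u, txx, txy = analytic_poiseuille(0.0, 1e-4, 0.1, 10.0, 0.3, 100.0, 0.1)
        assert txx == 0.0 and txy == 0.0
        assert u > 0

    def test_stress_elimination_identity(self, rng):
        # tau_xx = 2 lam_p tau_xy^2 / (eta_t (1 - beta)) at any position
        y = rng.uniform(-9, 9, 20)
        lam_p, eta_t, beta = 80.0, 0.25, 0.3
        _, txx, txy = analytic_poiseuille(y, 2e-4, 0.25, 10.0, beta, lam_p, eta_t)
        assert np.allclose(txx, 2 * lam_p * txy ** 2 / (eta_t * (1 - beta)),
                           rtol=1e-12)

    def test_newtonian_normal_stress_limit(self):
        y = np.linspace(-5, 5, 11)
        _, txx0, txy0 = analytic_poiseuille(y, 1e-4, 0.1, 6.0, 0.3, 0.0, 0.1)
        _, _, txy1 = analytic_poiseuille(y, 1e-4, 0.1, 6.0, 0.3, 50.0, 0.1)
        assert np.allclose(txx0, 0.0)
        assert np.allclose(txy0, txy1)

    def test_duct_series_matches_plane_limit(self):
        # very wide duct tends to the plane-Poiseuille profile at the centre
        y = np.linspace(-0.9, 0.9, 7)
        u_duct = analytic_duct_profile(y, 0.0, 1e-3, 0.1, 1.0, 25.0)
        u_plane, _, _ = analytic_poiseuille(y, 1e-3, 0.1, 1.0, 1.0, 0.0, 0.1,
                                            geometry="plane")
        assert np.allclose(u_duct, u_plane, rtol=2e-3)


class TestDuctProfile:
    def test_newtonian_duct_matches_series_solution(self):
        # particle-free Newtonian duct reaches the analytic profile within 2%
        ny = nz = 21
        section = boundaries.duct_section(ny, nz)
        ws = boundaries.build_wallset(section)
        nu = 0.1
        half = (ny - 1) / 2.0
        a = boundaries.driving_acceleration(1.0, nu, ny - 1.0)
        lat = LatticeRun((1, ny, nz), section, ws, lambda_f=0.8, accel=a)
        lat.run(5000)
        y = np.arange(ny) - half
        z = np.arange(nz) - half
        yy, zz = np.meshgrid(y, z, indexing="ij")
        ua = analytic_duct_profile(yy, zz, a, nu, half, half)
        us = lat.u[0, 0]
        err = np.abs(us - ua)[section].max() / ua.max()
        assert err < 0.02


class TestNewtonianRecovery:
    def test_beta_one_matches_newtonian_module(self):
        # forcing tau to zero reproduces the Newtonian velocity field at FP level
        ny = nz = 14
        section = boundaries.duct_section(ny, nz)
        ws = boundaries.build_wallset(section)
        a = 1e-5
        newt = LatticeRun((2, ny, nz), section, ws, lambda_f=0.8, accel=a)
        # viscoelastic module enabled but with zero polymer viscosity
        spec = stress.PolymerSpec(beta=1.0, eta_t=0.1, lambda_p=50.0)
        visc = LatticeRun((2, ny, nz), section, ws, lambda_f=0.8, accel=a,
                          polymer=spec)
        newt.run(300)
        visc.run(300)
        assert np.allclose(newt.u, visc.u, atol=1e-13)


class TestRunAndOutputs:
    @pytest.fixture()
    def small_cfg(self, tmp_path):
        cfg = SimulationConfig()
        cfg.geometry.kind = "duct"
        cfg.geometry.h = cfg.geometry.w = 40e-6
        cfg.geometry.dx = 4e-6   # 11 nodes across
        cfg.geometry.length = 4
        cfg.fluid.Re = 0.5
        cfg.fluid.Wi = 0.1
        cfg.fluid.nu = 1e-6
        cfg.fluid.dt = 4e-6  # keeps lambda in range at the coarse dx
        cfg.run.steps = 40
        cfg.run.output_every = 10
        cfg.run.outdir = str(tmp_path / "out")
        return cfg

    def test_zero_steps_snapshot_only(self, small_cfg, tmp_path):
        small_cfg.run.steps = 0
        sim = Simulation(small_cfg)
        summary = sim.run(outdir=tmp_path / "o2")
        assert summary["steps"] == 0
        assert (tmp_path / "o2" / "snapshot_0.vtk").exists()

    def test_summary_reports_nominal_and_measured(self, small_cfg):
        sim = Simulation(small_cfg)
        summary = sim.run()
        assert {"Re", "Wi", "El"} <= set(summary["nominal"])
        assert {"Re", "Wi", "El", "U"} <= set(summary["measured"])
        assert summary["nominal"]["El"] == pytest.approx(0.2)

    def test_vtk_snapshot_readable(self, small_cfg, tmp_path):
        sim = Simulation(small_cfg)
        path = tmp_path / "snap.vtk"
        sim.snapshot(path)
        head = path.read_text().splitlines()
        assert head[0].startswith("# vtk DataFile")
        assert any(line.startswith("DIMENSIONS") for line in head[:8])
        assert any("VECTORS u" in line for line in head)
        assert any("SCALARS N1_y" in line for line in head)
        assert any("SCALARS tau_xy" in line for line in head)

    def test_checkpoint_resume_bit_identical(self, small_cfg, tmp_path):
        sim = Simulation(small_cfg)
        ckpt = tmp_path / "ck.h5"
        sim.run(steps=20, outdir=tmp_path / "a")
        sim.checkpoint(ckpt)
        sim.run(steps=40, outdir=tmp_path / "a")

        sim2 = Simulation.resume(ckpt)
        sim2.run(steps=40, outdir=tmp_path / "b")
        assert np.array_equal(sim.lat.f, sim2.lat.f)
        assert np.array_equal(sim.lat.G, sim2.lat.G)

    def test_identical_configs_identical_outputs(self, small_cfg, tmp_path):
        s1 = Simulation(small_cfg)
        s1.run(steps=30, outdir=tmp_path / "r1")
        s2 = Simulation(small_cfg)
        s2.run(steps=30, outdir=tmp_path / "r2")
        assert np.array_equal(s1.lat.f, s2.lat.f)


class TestPresetsAndDiagnostics:
    def test_geometry_presets(self):
        from viscolb.driver import PRESET_GEOMETRIES

        g = PRESET_GEOMETRIES["AR1_2"]
        ch = boundaries.ChannelGeometry(h=g["h"], w=g["w"], dx=1e-6)
        assert ch.AR == pytest.approx(0.5)
        assert PRESET_GEOMETRIES["AR1"]["h"] == pytest.approx(50e-6)
        assert PRESET_GEOMETRIES["AR1_4"]["w"] == pytest.approx(160e-6)

    def test_pressure_diagnostic(self):
        from viscolb import lattice

        assert lattice.pressure(np.array(1.2)) == pytest.approx(0.4)

    def test_membrane_substeps_knob(self):
        run, _ = make_shear_run(0.02, ny=16, nz=12, nx=12)
        p = centered_particle((12, 16, 12))
        run.particles.append(p)
        run.membrane_substeps = 2
        run._refresh_force_and_moments()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run.run(50)
        assert np.all(np.isfinite(p.X))

    def test_invalid_substeps(self):
        from viscolb.driver import LatticeRun

        section = boundaries.duct_section(8, 8)
        ws = boundaries.build_wallset(section)
        with pytest.raises(ConfigurationError):
            LatticeRun((2, 8, 8), section, ws, lambda_f=0.8,
                       membrane_substeps=0)


class TestCoupledInvariants:
    def test_spread_equals_nodal_total_force(self):
        # action-reaction bookkeeping inside a coupled step
        run, _ = make_shear_run(0.02, ny=20, nz=14, nx=14)
        p = centered_particle((14, 20, 14))
        p.X += np.array([0.0, 1.3, 0.7])  # break symmetry
        run.particles.append(p)
        run._refresh_force_and_moments()
        from viscolb import ibm
        fn = membrane.nodal_forces(p.mesh, p.X)
        FA = ibm.spread_forces(run._wrapped(p.X), fn, run.shape,
                               fluid_mask=run.fluid3d, periodic=run.periodic)
        total_spread = FA.sum(axis=(1, 2, 3))
        total_nodal = fn.sum(axis=0)
        scale = np.abs(fn).max() * len(fn) + 1e-30
        assert np.abs(total_spread - total_nodal).max() < 1e-12 * scale

    def test_centered_particle_stays_on_centerline(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            section = boundaries.duct_section(19, 19)
            ws = boundaries.build_wallset(section)
            a = 2e-5
            p = centered_particle((8, 19, 19))
            lat = LatticeRun((8, 19, 19), section, ws, lambda_f=0.8, accel=a,
                             particles=[p])
            c0 = p.centroid.copy()
            lat.run(2000)
            drift = p.centroid - c0
            # cross-section drift below 0.01 lattice units
            assert np.abs(drift[1:]).max() < 0.01
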