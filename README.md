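# viscolb

Three-dimensional lattice-Boltzmann / immersed-boundary simulation of rigid
spherical particles suspended in an Oldroyd-B viscoelastic fluid in straight
microchannels, with the analysis machinery for elasto-inertial focusing and
size-based separation studies.

## Method

* **Solvent flow** — D3Q19 single-relaxation-time LBGK with Guo forcing;
  periodic inlet/outlet along the flow axis, non-equilibrium extrapolation
  no-slip (or moving) walls.
* **Polymer stress** — the six independent components of the Oldroyd-B stress
  tensor are carried by a second D3Q19 distribution set with a constitutive
  source term; the recovered stress feeds the elastic body force
  `F_V = div(tau)` back into the solvent.
* **Particles** — closed triangulated spheres (120- and 480-element presets)
  with strain, bending, area, and volume energies and exact analytic nodal
  forces; rigidity emerges from large moduli. Two-way coupling uses the
  4-point cosine-kernel immersed boundary method.
* **Analysis** — dimensionless groups (Re, Wi, El), sector reduction/mirroring
  of cross-section trajectories, rotation angles from an anchored orientation
  vector, first-normal-stress-difference profiles, and focusing-equilibrium
  detection.

## CLI

```sh
viscolb run config.yaml            # run a simulation from a YAML config
viscolb mesh --diameter 6 --faces 120 --out particle.off
viscolb validate                   # quick analytic fixture check
viscolb analyze out/trajectory_0.csv --square --plot map.png
```

A configuration file looks like:

```yaml
geometry: {kind: duct, h: 40.0e-6, w: 80.0e-6, dx: 2.0e-6, length: 12}
fluid:    {Re: 2.5, Wi: 0.2, beta: 0.3, nu: 1.0e-6, dt: 4.0e-7}
particles:
  - {diameter: 6.0e-6, n_faces: 120, position: [-0.4, -0.3]}
run:      {steps: 100000, output_every: 1000, outdir: out}
```

Outputs: per-particle trajectory CSV (`step, y, z, theta_x, theta_y, theta_z,
omega` in half-extent-normalised cross-section coordinates), legacy-ASCII VTK
snapshots of `rho`, `u`, `tau`, `N1`, HDF5 checkpoints for bit-exact restart,
and a YAML summary reporting nominal vs measured (Re, Wi, El).

## Notes

* Internal solver units are lattice units (dx = dt = 1); the physical
  parameter block is converted once at setup (`viscolb.driver.lattice_calibration`).
* Full-resolution trajectory maps (millions of steps on 40–50 um
  cross-sections) are cluster-scale; the test suite reproduces the qualitative
  behaviour
  (centreline-ward migration, size-dependent migration speed, Wi-monotone
  particle rotation) on coarse desk-scale grids.
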