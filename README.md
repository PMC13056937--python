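# nmadiel

Dielectric response of biomolecules from normal-mode ensembles.

Starting from per-replica normal-mode frequencies, mass-weighted Cartesian
eigenvectors and per-atom partial charges, `nmadiel` computes:

- **mode dipole variations** — the charge-weighted eigenvector sums
  `sum_i q_i e_{l,i}` whose norms couple each vibrational mode to an external
  electric field, for the whole system or restricted to protein / water /
  ligand components, plus inter-component angle statistics and per-residue
  displacement profiles;
- **complex susceptibility, permittivity, extinction and absorption** in
  absolute units on a frequency grid, via a sum of damped Lorentz
  oscillators with a 1/3 orientational factor, with damping and
  concentration sweeps and ensemble averaging across replicas;
- **vibrational density of states** histograms with per-degree-of-freedom
  normalization;
- **hydration-shell persistence** — assignment of waters to distance bands
  around the protein and the per-frame percentage persisting in a shell for
  at least a threshold time;
- **bound-water mixing corrections** — removed-water fractions, dilute
  linear-mixing deltas on susceptibility and absorption, concentration
  conversions and the shell-overlap concentration estimate.

A synthetic-systems module generates toy harmonic spring networks with
exact analytic Hessians (solvable to closed form for small cases) and
Markov-chain water-shell trajectories with known stay probabilities; these
serve as oracles for every other module and as generators of desk-scale
fixtures in the same text formats the readers accept.

## Test

```sh
python -m pytest -q tests/
```

## CLI

One entry point, `nmadiel`, with subcommands:

```sh
# generate a 2-replica synthetic hydrated ensemble on disk
nmadiel synth modes --topology random --n-atoms 10 --n-replicas 2 \
    --n-shell-particles 4 --seed 1 --out ens/

# damping x concentration sweep of absorption spectra
nmadiel spectra --ensemble-dir ens/ --gamma-ghz 10,100,1000,10000 \
    --conc-mm 0.5 --grid-ghz 1:2000:1 --component whole --out spectra/

# per-mode dipole table, component angle profile, VDOS
nmadiel dipoles --ensemble-dir ens/ --component protein --out dipoles.tsv
nmadiel angles --ensemble-dir ens/ --n-modes 20 --out angles.tsv
nmadiel vdos --ensemble-dir ens/ --bin-ghz 10 --out vdos.tsv

# Markov water-shell trajectory and persistence statistics
nmadiel synth trajectory --n-waters 500 --n-frames 1500 \
    --stay-probability 0.7 --seed 7 --out traj.tsv
nmadiel hydration --trajectory traj.tsv --threshold-ps 20 --out persist.tsv

# bound-water accounting
nmadiel mixing --nb 1124 --conc-mm 0.517 --water-molarity 55.345

# full pipeline from a YAML config
nmadiel run config.yaml
```

`nmadiel run` consumes a YAML config (unknown keys are rejected); see
`nmadiel.cli._CONFIG_DEFAULTS` for the full key list.  Outputs are TSV
tables plus a `manifest.json` recording every parameter and the constants
table version; rerunning the same config reproduces the outputs
byte-for-byte.

## File formats

- Frequency files: XVG-dialect text (`#`/`@` comments, `index value`
  columns), wavenumbers in cm^-1 by default.
- Eigenvector files: TSV with `mode_index  atom_index  ex  ey  ez`
  (kg^-1/2).  GROMACS binary eigenvector output can be exported to this
  layout with `gmx anaeig -v eigenvec.trr` followed by a trivial reshape.
- Atom metadata: TSV with `atom_index  mass_amu  charge_e  component
  residue_index` (+ optional `x_nm y_nm z_nm`), or a companion PDB/GRO file
  for coordinates.
- Shell trajectories: TSV with `frame  water_index  shell`.

All internal quantities are SI (Hz, kg, C, m); conversions happen only at
file boundaries, with CODATA-2018 constants pinned in
`nmadiel.constants`.

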