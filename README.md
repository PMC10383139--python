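# sorbscreen

Screening and sorption analytics for pesticide capture by
calcium–alginate–chitosan (CAC) polyelectrolyte nanoparticles — and, more
generally, for any workflow that docks a ligand library against an ensemble
of receptor conformations and then watches the winners adsorb in molecular
dynamics.

The package covers three stages of that workflow as a tested library plus a
`sorbscreen` command-line tool:

1. **Consensus ranking of ensemble-docking scores.**  Each ligand is docked
   against many receptor conformations × grid boxes × poses, giving a vector
   of docking energies DE₁…DEₙ (kcal/mol, negative = favourable).  Five
   fusion statistics are computed per ligand —

   - minimum value: min(DE₁…DEₙ)
   - arithmetic mean: (1/n) Σ DEᵢ
   - geometric mean (signed-magnitude): −(Π |DEᵢ|)^{1/n}
   - harmonic mean: n / Σ DEᵢ⁻¹
   - median

   — each is ranked across the library (rank 1 = most negative), and a
   ligand is *selected* when the statistical mode of its five ranks lies in
   the first `top_k` (default 5) positions **and** that mode occurs in at
   least `min_metrics` (default 3) of the five metrics.

2. **Trajectory sorption analytics.**  Per-frame capture counts (a ligand
   copy is captured when its nearest-atom distance to the matrix is
   ≤ 3.5 Å under the minimum-image convention), capture half-times with
   linear interpolation, axis-binned mass density profiles (default 240
   windows over [−120, 120] Å), mean square displacement with the Einstein
   diffusion coefficient D = slope/6, RMSD (Kabsch-aligned) and radius of
   gyration series, hierarchical RMSD clustering with per-cluster
   representative frames, hydrogen-bond / salt-bridge counts, and a
   pooled-variance Student's t-test for comparing capture across systems.

3. **Promolecular NCI grids.**  The electron density is approximated as a
   sum of exponential free-atom fits; the reduced density gradient
   s = |∇ρ| / (2(3π²)^{1/3} ρ^{4/3}) is evaluated on a regular grid, points
   with low ρ and low s are flagged as non-covalent interaction regions and
   classified by sign(λ₂)·ρ (attractive / van der Waals / repulsive), and
   the fields are exported as Gaussian cube files for standard NCI viewers.

A fourth module, `sorbscreen.fixtures`, generates every input the analyses
consume — sphere-packed bead nanoparticles built from 16-mer alginate
(G8/M8-block and (GM)8-block) and chitosan (C16) chains with Ca²⁺ ions,
docking-score tables with planted top candidates, Brownian trajectories
with a known diffusion coefficient, and approach-and-stick trajectories
with constructed capture counts.  All generators are seed-deterministic.

## Worked example

The `pipeline` subcommand chains all stages on seeded fixtures:

```sh
sorbscreen pipeline          # defaults; or: sorbscreen pipeline --config my.yaml
```

With the default configuration and seed 1
(`run_pipeline({"seed": 1, "outdir": "readme_out"})`) the report contains:

```json
{
  "consensus": {
    "planted":   ["L0000", "L0001", "L0002", "L0003", "L0004"],
    "selected":  ["L0000", "L0001", "L0002", "L0003", "L0004"],
    "planted_recovered": ["L0000", "L0001", "L0002", "L0003", "L0004"]
  },
  "capture":   {"half_time_ns": 30.0, "max_captured": 8, "n_copies": 10,
                "cutoff_A": 3.5},
  "diffusion": {"d_input_A2_per_ns": 0.1,
                "d_est_A2_per_ns": 0.10276732470894255,
                "d_est_cm2_per_s": 1.0276732470894255e-08},
  "density":   {"total_mass_Da": 4800.0, "expected_mass_Da": 4800.0,
                "peak_density_Da_per_A3": 0.0216},
  "clusters":  {"n_clusters": 5, "sizes": [5, 4, 7, 6, 8]}
}
```

Reading: the five ligands planted with more favourable docking energies are
exactly the ones the consensus rule selects; half of the ten ligand copies
are in contact with the matrix by 30 ns and at most 8 ever are; the
diffusion coefficient fitted from the MSD (0.103 Å²/ns) recovers the
generator's 0.1 Å²/ns within 3 %; the density profile integrates back to
the exact fixture mass; and the 30-frame Brownian segment splits into the
requested 5 clusters.  Rerunning with the same config reproduces the report
byte for byte.

Individual stages are available as `sorbscreen fuse`, `consensus`,
`campaign`, `capture`, `density`, `msd`, `cluster`, `interactions`, `nci`
and `simulate {scores,brownian,capture,pack}`; see `--help` on each.

## Layout

```
src/sorbscreen/
  consensus.py    score parsing, fusion metrics, ranking, consensus, campaigns
  trajectory.py   capture, density, MSD/diffusion, RMSD/Rg, clustering, HB/SB
  nci.py          promolecular densities, reduced gradient, cube files
  fixtures.py     seeded generators for all synthetic inputs
  pipeline.py     end-to-end run with JSON report
  io.py           multi-model PDB, XYZ, selection configs, CSV writers
  cli.py          the `sorbscreen` command
docs/methods.md   models, conventions, parameter choices, limitations
```
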