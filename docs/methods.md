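# Methods

This note records the models implemented in `sorbscreen`, the conventions
and defaults chosen where more than one reasonable option exists, what the
synthetic fixtures do and do not emulate, and the known limitations.

## Consensus ranking of ensemble-docking scores

Ensemble docking produces one energy per (ligand, receptor conformation,
grid box, pose).  Poses are aggregated per ligand before fusion:

- **best-per-run** (default): one energy per (conformation, grid) run, the
  minimum over its poses.  This is the standard way docking results are
  consumed — the engine's pose ranking already identifies the best pose —
  and for a 20-conformation × 4-grid campaign yields 80 energies per
  ligand.
- **all-poses**: every pose energy enters the metrics (≤ 720 per ligand at
  9 poses/run).  Available as a config/CLI option.

Ligands whose campaigns are incomplete (failed dockings) are excluded with
a warning when fewer than half of the expected runs are present
(`min_coverage`, configurable).

The five fusion statistics assume strictly negative energies.  Two require
a convention for negative input:

- **Geometric mean**: Π DEᵢ^{1/n} is ill-defined for negative DE and even
  n; the signed-magnitude form −(Π |DEᵢ|)^{1/n} is used (computed via
  logarithms for stability).
- **Harmonic mean**: n / Σ DEᵢ⁻¹ is evaluated directly on the signed
  energies; for all-negative input this equals the negated harmonic mean
  of the magnitudes.  A zero energy makes it undefined and is rejected, as
  are mixed-sign vectors.

On magnitudes the textbook ordering |HM| ≤ |GM| ≤ |AM| holds and is
enforced by property tests.

Ranking uses competition ("min") ranks — rank 1 is the most negative
metric value, ties share the smaller rank — and tables are processed in
lexicographic ligand order so reruns are bit-identical.  The consensus
rule selects a ligand when the mode of its five per-metric ranks is ≤ 5
and occurs in ≥ 3 metrics; when a rank vector is multimodal the smallest
(best) mode is used, which errs toward selection.

**What the selection rule guarantees.**  The exact-integer mode rule is
deliberately conservative: a genuinely strong candidate whose five ranks
never agree three times is dropped.  On fixture tables with five planted
candidates at the full campaign layout, the rule selects only planted
ligands (no background false positive was observed in any repetition) and
a majority of them in every repetition, but all five in only ~90 % —
rank order under min vs means vs median occasionally disagrees for
statistically exchangeable top candidates, independent of the noise
scale.  "Recovery" in the tests therefore means: non-empty selection,
no background ligand, majority of the plants.

Campaign bookkeeping (`enumerate_campaign`) is exact integer arithmetic:
624 ligands × 20 conformations × 4 grids = 49,920 runs, × 9 poses =
449,280 evaluations; 7 systems × 3 replicas × 100 ns = 2.1 µs.

## Trajectory analytics

The in-memory container is a plain frames × atoms coordinate array (Å)
with per-atom masses (Da), named index groups, an orthorhombic box and
uniformly spaced frame times (ns).  Multi-model PDB files are read through
MDAnalysis; masses, groups, box and times come from a YAML selection
config, because the bead fixtures are not real elements and mass guessing
from atom names would be wrong.

**Capture.**  A ligand copy is captured when its minimum atom-to-matrix
distance is ≤ the cutoff (default 3.5 Å, inclusive), under the
minimum-image convention.  The default contact definition is nearest atom;
a centre-of-mass mode is available.  The production path queries a
periodic k-d tree per frame; a brute-force all-pairs path exists solely as
a cross-check and the two are asserted equal on every fixture.  The
capture half-time is the first time the count reaches ⌈n/2⌉, linearly
interpolated between the bracketing frames; +∞ when never reached.

**Density profile.**  The profiled axis range (default 240 windows over
[−120, 120] Å) is divided into half-open slabs [lo, hi), final upper edge
closed.  The primary output is the physical slab density — window mass /
(thickness × box cross-section), Da/Å³ — which conserves mass by
construction: Σ density × slab volume equals the mean in-range selected
mass.  A per-length linear density (Da/Å, window mass / thickness) is
emitted alongside, because axis-projected profiles are often reported in
that normalisation and the two differ by the cross-sectional area.
Atoms outside the range are excluded and tallied.

**MSD and diffusion.**  MSD(τ) averages |r(t+τ) − r(t)|² over all selected
particles and all sliding time origins (stride configurable).  Periodic
jumps larger than half the box are unwrapped first (raw mode available).
The diffusion coefficient comes from a least-squares line on the
[20 %, 80 %] fraction of the lag range, D = slope/6 (Einstein relation in
3-D), reported in Å²/ns and cm²/s (1 Å²/ns = 10⁻⁷ cm²/s).  **Fitting
convention:** the maximum lag is kept well below the trajectory length —
the analyses here use max_lag = 5 % of the frames — because long lags are
averaged over few origins and dominate the fit noise; at max_lag = half
the trajectory the recovered D fluctuates by ~15–20 % on the 50-particle
reference fixture, versus < 5 % at the 5 % setting.

**RMSD and Rg.**  RMSD to a reference frame is computed after Kabsch
superposition by default (align=False reproduces drift-inclusive
profiles); residuals are evaluated directly from the rotated coordinates
rather than from the singular values, which would lose ~7 digits to
cancellation.  Rg is the mass-weighted RMS distance from the centre of
mass.

**Clustering.**  Frame-frame RMSD matrices are clustered agglomeratively
(average linkage by default; single/complete available) and the dendrogram
is cut after n_frames − k merges (`scipy.cluster.hierarchy.cut_tree`),
which guarantees exactly k non-empty clusters — a max-cluster threshold
cut can return fewer on tied merge heights.  One representative frame per
cluster is drawn uniformly with the given seed.

**Hydrogen bonds and salt bridges.**  No universal geometric criteria
exist, so both are fully configurable and echoed into every output: the
defaults are H…A ≤ 2.8 Å with a D–H…A angle ≥ 120° (approximating common
MD-suite defaults) and a 4.0 Å charged-atom cutoff with one salt bridge
counted per charged-group pair.  A donor hydrogen farther than 1.6 Å from
its heavy atom is rejected as unbound.

**Capture statistics.**  Systems are compared by a two-sample
pooled-variance Student's t-test on per-frame counts pooled across
replicates (each frame is one observation); two-sided p.  Zero pooled
variance with equal means returns t = 0, p = 1 by convention.  Pooling
frames treats them as independent, which MD frames are not — see
limitations.

## Promolecular NCI

Atomic densities are multi-exponential fits ρ_atom(r) = Σ cⱼ e^{−r/ζⱼ}
(atomic units) for H–Ar; the promolecular density, its gradient and its
Hessian are analytic sums over atoms.  Elements beyond Ar (e.g. Ca, Br in
the systems of interest) fall back to the Ar terms scaled by electron
count, with a warning — adequate for locating interaction regions, not
for quantitative densities.  The nuclear cusp is clamped at r ≥ 10⁻⁶ bohr;
NCI regions of interest are low-density, far from nuclei.

The reduced density gradient s = |∇ρ| / (2(3π²)^{1/3} ρ^{4/3}) is zero at
density critical points; grid points with ρ < 0.05 a.u. and s < 0.7 are
flagged as NCI regions and classified by sign(λ₂)·ρ (λ₂ = middle Hessian
eigenvalue): < −0.01 attractive, within ±0.01 van der Waals, > +0.01
repulsive.  The isovalue matches the rendering convention used for such
plots; the ρ cutoff and ±0.01 bin edges are community conventions and
configurable.

Auto-generated grids are centred on the atoms' bounding box with odd point
counts, so a symmetric system samples its interaction midplane with an
exact lattice plane.  This matters: promolecular tails are steep, and at
rare-gas van der Waals separations the s < 0.7 basin can be thinner than
any practical grid spacing — a grid that straddles the midplane between
two planes misses the contact entirely.  Tests that need a volumetric,
resolution-convergent basin use a soft closed-shell model atom (valence
amplitude with physical asymptotic decay) rather than pretending the Ne
fit behaves that way.

Fields are exported as Gaussian cube files (bohr, Z-fastest ordering,
7 significant digits — enough to round-trip within 10⁻⁶ relative).

## Synthetic fixtures

The generators emulate the *shape* of the real inputs, not their physics:

- **Sphere packing**: rigid random placements (uniform rotation + uniform
  centre in a ball or shell) accepted when all atoms stay inside the
  sphere and every inter-molecule atom pair is ≥ the tolerance (default
  4.0 Å) apart.  Rejection sampling with an attempt cap (default 10⁵ per
  molecule) — no Packmol-style optimisation, adequate at fixture
  densities.
- **CAC bead nanoparticle**: one bead per monomer, 16-mer chains on a
  compact helix (5 Å bead spacing, self-distances ≥ 4 Å) so chains fit
  inside a 40 Å packing sphere; G/M beads 176 Da, charge −1 (ionised
  uronate), C beads 161 Da, charge +1 (protonated glucosamine), Ca²⁺
  40.08 Da — nominal fixture constants.  Default composition 25 + 25
  alginate chains, 50 chitosan chains, 640 Ca²⁺ in a 70 Å sphere; the
  capture-scale system is (10, 10, 20, 320) at 40 Å.
- **Docking scores**: background energies N(−5.7, 0.6) truncated strictly
  negative (centred on the typical library median), poses sorted
  best-first within each run; planted candidates draw their energies
  shifted by Δ = −5 kcal/mol.
- **Brownian trajectories**: independent Gaussian steps of variance 2 D dt
  per axis; D = 0 gives static frames.  No interactions, no hydrodynamics.
- **Approach-and-stick trajectories**: each copy moves radially along a
  box axis so its distance to a single matrix bead equals the 3.5 Å cutoff
  *exactly* at its scheduled frame, then sticks — the inclusive boundary
  is exercised with exact arithmetic, and the per-frame ground-truth
  counts are constructed, not measured.

Passing tests on these fixtures demonstrates that the analysis code
computes what it claims on inputs with known answers.  It does not
demonstrate force-field realism, solvent effects, polymer conformational
statistics, or that real pesticide–nanoparticle systems behave like the
fixtures.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng(seed)`; every
  stochastic operation is bit-reproducible given a seed.
- Rank ties: competition ranking; multimodal rank vectors: smallest mode.
- Empty score vectors, zero energies, mixed signs, overlapping atom
  groups, empty selections, non-square or asymmetric distance matrices,
  max_lag ≥ trajectory length, and degenerate fit windows all raise
  informative errors rather than propagating NaNs.
- Capture cutoffs are inclusive (≤); density windows are half-open with
  the final edge closed (`numpy.histogram` convention).
- Problem sizes used by the test suite and the acceptance script (e.g.
  30-ligand libraries at the full 20 × 4 × 9 per-ligand layout, 50
  Brownian particles × 2000 steps, 25-frame clustering) are chosen so the
  statistical criteria they check are comfortably resolved at desk scale.

## Known limitations

- The package analyses trajectories; it does not run docking or MD.
- Bead-level fixtures cannot validate atomistic selections (e.g. real
  donor/acceptor chemistry); HB/SB counting is purely geometric.
- The t-test on pooled frames ignores temporal autocorrelation, so its
  p-values are optimistic on correlated trajectories; replica-level
  aggregation before testing is the conservative alternative.
- Promolecular densities are qualitative by construction; heavy-element
  fallback scaling is a locator, not a density model.
- Orthorhombic boxes only; triclinic cells are not supported.
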