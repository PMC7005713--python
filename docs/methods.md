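# Methods

## χ1 measurement and rotamer bins

χ1 is the signed torsion about Cα–Cβ, computed from atoms N, Cα, Cβ, Cγ with
the IUPAC convention (cis = 0°; looking from Cα to Cβ, clockwise positive);
values lie in (−180°, +180°]. Rotamer classes use a fixed half-open
partition centred on the canonical conformers −60°/+60°/180°:

| class   | bin              | canonical χ1 |
|---------|------------------|--------------|
| gauche− | [−120°, 0°)      | −60°         |
| gauche+ | [0°, +120°)      | +60°         |
| trans   | remainder        | 180°         |

Lower edges are inclusive, so the partition is total and deterministic at
boundaries (exactly +120° is trans, exactly 0° is gauche+). Away from the
three edges the assignment coincides with nearest-canonical-rotamer
classification, which the test suite verifies by a 0.1° sweep of the circle.
The sign convention for "gauche−" is not universal across the literature;
`RotamerPartition.mirrored()` provides the opposite convention, but the
default is the IUPAC/penultimate-library one (gauche− ≈ −60°, "m") and all
shipped results use it.

## Structures, altlocs and metadata

Coordinate files (PDB or mmCIF, via gemmi) are flattened into per-residue
views addressed by author numbering — the numbering used in publications
(e.g. HK853 His260). Alternate conformers matter here: two survey entries
model the phosphoacceptor His in both gauche− and trans in the same crystal.
Each altloc group with occupancy ≥ 0.2 yields an independent rotamer call;
lower-occupancy conformers are logged and skipped. Double-conformed subunits
therefore contribute two calls to the class counts (required for the
27/39 per-subunit tally) while marking the structure "mixed-altloc" for
concordance.

Crystallization pH comes from REMARK 280 free text (PDB) or
`_exptl_crystal_grow` (mmCIF). A missing or malformed token is reported as
missing — never defaulted to 7 — and excluded (with an explicit count) from
association testing. A stated range becomes its midpoint with the range
recorded (the survey's one ranged entry, 7.6–8.6, is used as 8.1). For the
packaged survey the manifest's curated pH is the source of truth, since
deposited headers occasionally disagree with the conditions actually used
(one entry's final pH was adjusted after mixing); header-extracted values
remain available for auditing.

## The survey manifest and concordance

The packaged manifest lists 28 HisKA-family structures with per-subunit
rotamer notation (`gauche-/gauche- & trans` = second subunit
double-conformed) and pH. Tallying it gives 66 subunit calls: 27 gauche−,
39 trans, 0 gauche+. Per-structure concordance is: *identical* if every
subunit carries one label and all agree; *mixed-altloc* if any subunit
carries two labels; *distinct* otherwise; single-subunit structures are not
evaluated. Under this rule the tally is 17 identical / 9 distinct / 2
mixed-altloc. Published prose tallies of 15 identical / 10 distinct for the
same table do not reconcile with any row-by-row counting rule we could
state; we report our own tally and note the discrepancy rather than tune the
rule to match.

Coordinate-derived calls are designed to be regression-checked
entry-by-entry against the manifest labels. Offline, the test suite performs
this check on generator-built fixtures that reproduce the manifest's
label/pH profile; on a directory of the actual deposited files the same code
path performs the real comparison.

## Exact association test

The pH–rotamer association is a two-sided Fisher exact test on the 2×2 table
(pH ≤ threshold vs >) × (gauche− vs trans), with the threshold defaulting to
6.5 — the upper edge of the claimed gating window (5.2–6.5). The p-value
sums hypergeometric probabilities (computed from log-gamma) of all tables
with the observed margins that are no more probable than the observed one,
with a 1e-7 relative tie tolerance; a zero margin gives p = 1 and a
degeneracy flag. The implementation is validated against direct
combinatorial enumeration for all small tables and against
`scipy.stats.fisher_exact`. Only the single pre-registered threshold is
tested by default; the unit of analysis is the subunit call, matching the
per-subunit notation of the survey. On the packaged survey the table is
[[11, 15], [16, 24]] and p = 1.0 — no evidence that the rotamer tracks pH.

## Superposition and contacts

Cα sets are paired by (chain, residue number) after an optional
user-supplied chain correspondence map — no sequence alignment, since
compared complexes share author numbering. The optimal rigid superposition
is the standard Kabsch SVD solution with reflection correction (det +1);
RMSD is the root-mean-square residual over pairs. Degenerate (rank < 2)
point clouds are rejected. Optimality is property-tested against a 10⁴-trial
random-rotation search and cross-checked against
`scipy.spatial.transform.Rotation.align_vectors`.

His–anion coordination is a heavy-atom distance criterion: any O/S atom of a
sulfate (or configured anion/polyol residue, glycerol and phosphate by
default) within 3.6 Å — a typical hydrogen-bond upper bound, configurable —
of the called conformer's Nδ1 or Nε2.

## Decay kinetics

Phospho-decay time courses (minutes, positive arbitrary units, first point
t = 0) are normalized to 100% at t = 0 and fit by OLS of ln(signal) on time
— the semilog linear fit, not nonlinear least squares, matching how such gel
quantifications are conventionally analysed. k = −slope; t½ = ln 2 / k.
Non-positive readings (a band can quantify as zero) are dropped with a
warning and at least three points must survive. A slope ≥ −1e−10/min reports
k = 0 and t½ = ∞ ("no measurable decay"), which `compare_conditions`
renders as a stable reference rather than a ratio.

## Synthetic data

The generator is the pipeline's data source in all offline tests.

- **Structures.** Residues are built from internal coordinates (bond length,
  bond angle, torsion; NeRF placement), so the target χ1 is exact by
  construction — the build/measure round trip is the module's defining
  invariant, tested on a 5° grid. Ideal geometry defaults: N–Cα 1.46 Å,
  Cα–Cβ 1.53 Å, Cβ–Cγ 1.50 Å; N–Cα–Cβ 110.5°, Cα–Cβ–Cγ 113.8°. The
  imidazole beyond Cγ is completed planar at a fixed χ2 = −75° (a common His
  value) solely so Nδ1/Nε2 exist for contact geometry. Chains are offset on
  a non-collinear lattice so multi-chain fixtures support Cα superposition.
  An optional sulfate is placed with its nearest oxygen at a prescribed
  distance from Nε2 along the nitrogen's in-plane lone-pair direction, the
  other three oxygens tetrahedral and strictly farther. Fixtures are written
  as minimal PDB (REMARK 280 with the declared pH, ATOM/HETATM, 10⁻³ Å
  precision) and read back through the ordinary parser. The survey-batch
  builder draws χ1 uniformly within ±20° of the canonical centre of each
  manifest label (staying inside the bin), so coordinate-mode classification
  must recover the labels exactly.
- **Decay curves.** signal(t) = 100·2^(−t/t½)·e^ε, ε ~ N(0, σ²) i.i.d. per
  point — multiplicative lognormal noise, because gel signals are positive
  with intensity-proportional error. Defaults: σ = 0.05, grid
  (0, 1, 3, 5, 15, 30) min. All randomness flows through an explicit numpy
  seed; identical specs produce bitwise-identical output.

What the synthetic fixtures do **not** emulate: real protein context
(packing, hydrogen-bond networks, crystallographic disorder beyond discrete
altlocs), experimental coordinate error, or model bias in deposited
structures. Passing the synthetic regression therefore demonstrates the
correctness of the measurement/classification machinery, not the accuracy of
any particular deposited model.

## Problem sizes and reproducibility

The test suite and the reproduction script are sized for a single CPU:
200 replicates per kinetics condition, 10⁴ rotation trials in the optimality
check, a 707-point cloud (the size of the compared HK–RR complexes) in the
superposition-scale check, and the 28-entry survey throughout. The
reproduction script derives one child seed per condition from the
command-line seed via `numpy.random.SeedSequence.spawn`, so conditions are
independent and the whole run is deterministic given `--seed`.

## Known limitations

- Comparisons against deposited PDB entries (entry-by-entry classifier
  concordance on real coordinates, complex-vs-complex RMSD values) require
  those files locally; no download client is included.
- The χ2/ring-flip state of His and rotamer-library probabilities are out of
  scope; classification is χ1-only.
- The selector configuration records phospho-His residue numbers per kinase
  for coordinate mode; entries not stated in the primary literature we
  curated should be verified against the deposition before use.
- pH parsing of free-text crystallization remarks is a token heuristic;
  curated manifest values take precedence for survey statistics.
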