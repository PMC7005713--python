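# dhpscan

Structural and kinetic analysis tools for the phosphorylatable histidine of
HisKA-family sensor histidine kinases.

## The problem

Bacterial two-component systems pair a sensor histidine kinase (HK) with a
response regulator (RR). The HK's DHp domain carries a phosphorylatable His
(His260 in *Thermotoga maritima* HK853) whose side-chain χ1 rotamer —
*gauche−* (χ1 ≈ −60°), *gauche+* (≈ +60°) or *trans* (≈ 180°) — has been
proposed to act as a pH-gated switch controlling phosphatase activity, with
the transition placed between pH 5.2 and 6.5. `dhpscan` provides the tooling
to test that proposition against crystal structures and phospho-decay
kinetics:

- **χ1 rotamer classification** per subunit and per alternate conformer,
  with χ1 = torsion(N, Cα, Cβ, Cγ) and half-open bins
  gauche− = [−120°, 0°), gauche+ = [0°, +120°), trans = the rest of the
  circle;
- **survey compilation** joining rotamer calls to crystallization pH
  (REMARK 280 / `_exptl_crystal_grow`), with a curated 28-entry HisKA survey
  manifest shipped as package data;
- **exact association testing**: a two-sided Fisher exact test on the 2×2
  table (pH ≤ threshold vs >) × (gauche− vs trans), computed by
  hypergeometric enumeration from log-factorials;
- **His–anion coordination**: sulfate/glycerol contacts of the imidazole
  Nδ1/Nε2 within a 3.6 Å heavy-atom cutoff;
- **Kabsch superposition** of Cα sets matched by chain and residue number,
  reporting RMSD;
- **phospho-decay kinetics**: the acid-labile P–N bond of phospho-His decays
  first order; signals normalized to 100% at t = 0 are fit by ordinary least
  squares on the semilog scale, k = −slope, t½ = ln 2 / k;
- **a synthetic generator** building idealized dimer structures at exact,
  prescribed χ1 (internal-coordinate placement) and noisy exponential decay
  curves, so the entire pipeline is testable without downloading a single
  structure.

## Worked example

Tally the packaged survey and test the pH association:

```bash
$ dhpscan survey --manifest-only --json summary.json
28 structures, 66 calls: 27 gauche-, 0 gauche+, 39 trans
concordance: {'identical': 17, 'distinct': 9, 'mixed-altloc': 2}
pH association at threshold 6.5: p = 1.0000, odds ratio = 1.1
```

Across 28 deposited HisKA structures the 66 per-subunit His calls split 27
gauche− / 39 trans; the exact test at the claimed pH 6.5 boundary is far from
significance (p = 1.0, odds ratio ≈ 1.1), i.e. the rotamer does not track
crystallization pH.

Simulate a decay time course and fit its half-life:

```bash
$ dhpscan simulate decay --half-life 10 --sigma 0.05 --reps 3 --seed 1 --out tc.csv
wrote tc.csv (3 replicates, t1/2 = 10.0 min)
$ dhpscan kinetics fit --input tc.csv
rep1: k = 0.0687/min, t1/2 = 10.09 min, r^2 = 0.9976
rep2: k = 0.06869/min, t1/2 = 10.09 min, r^2 = 0.9994
rep3: k = 0.06913/min, t1/2 = 10.03 min, r^2 = 0.9992
```

With 5% multiplicative noise on a 0–30 min grid, the semilog fit recovers the
10 min ground-truth half-life to within a few percent per replicate.

Build a synthetic dimer (one gauche− and one trans subunit, sulfate 3.2 Å
from the gauche− subunit's Nε2) and inspect it:

```bash
$ echo '{"chains": [["gauche-"], ["trans"]], "ph": 7.5, "sulfate_distance": 3.2}' > spec.json
$ dhpscan simulate structure --spec spec.json --out fix.pdb
$ dhpscan rotamer fix.pdb --residue 260
A/260: chi1 -60.0 deg -> gauche-
B/260: chi1 +180.0 deg -> trans
$ dhpscan contacts fix.pdb --chain A --residue 260
A/260 gauche-: anion-coordinated (cutoff 3.6 A)
```

Coordinate mode (`dhpscan survey --structures DIR`) applies the same χ1
classifier to local PDB/mmCIF files, and `dhpscan superpose REF MOBILE`
reports the Cα RMSD between two complexes.

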