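# eif2btools

Quantitative analysis toolkit for the antagonistic allostery between ISRIB and
phosphorylated eIF2 on their common target, the decameric guanine nucleotide
exchange factor eIF2B.

Phosphorylation of eIF2α serine 51 converts eIF2 from the substrate of eIF2B
into its inhibitor, triggering the integrated stress response (ISR); the small
molecule ISRIB binds a single pocket at the eIF2B β/δ–β′/δ′ interface and
blunts the ISR. The structural and biochemical signature of this antagonism
lives in three kinds of measurements, and this package implements all three as
a tested, reusable pipeline:

1. **Conformational metrics between cryo-EM models** (`structure_io`,
   `conformetrics`): multi-chain mmCIF/PDB entries are parsed with gemmi,
   chains are mapped to subunit roles by sequence identity and split into the
   two protomers, and structure pairs are superposed (Kabsch/SVD) on
   configurable frames. Reported metrics: mean Cα displacement and
   helical-axis rotation of eIF2Bδ helix α3 (residues 247–267) relative to the
   β/δ C-terminal-domain frame, with a toward/away-from-eIF2Bβ direction
   label, and the relative shift of the two βδ half-shells of the
   ISRIB-binding pocket (Cα atoms within 10 Å of the ligand in an
   ISRIB-bound reference entry).
2. **Binding and kinetics regressions** (`binding_models`): the seven model
   equations used in the underlying assays — single-phase exponential decay,
   one-site total binding, four-parameter logistic inhibition, two-phase
   association/decay, one-site specific binding, and hyperbolic
   agonist–response — fitted by unweighted nonlinear least squares with
   t-based 95% CIs, R², and derived quantities (t₁/₂ = ln 2 / K, %Fast,
   IC50/EC50).
3. **An equilibrium linkage simulator** (`allostery`): one ISRIB site and two
   eIF2(αP) regulatory sites with pairwise coupling factors, giving species
   populations, GEF activity, competition curves, desensitised-mutant
   transforms, and quasi-equilibrium phosphorylation time courses. It doubles
   as the synthetic-data generator (`synthetic`) that lets the entire test
   suite run without downloading anything.

## Worked example

Simulate a fluorescent-ISRIB displacement time course at the reported off-rate
(k_off = 0.74 min⁻¹, 2% noise) and fit it back:

```bash
$ eif2btools simulate --kind trace --model one_phase_decay --seed 4 --out decay.csv
$ eif2btools fit --model one_phase_decay decay.csv
{
  "model": "one_phase_decay",
  "params": { "Y0": 199.87, "Plateau": 50.20, "K": 0.7435 },
  "ci95":   { "K": [0.6805, 0.8065], ... },
  "r_squared": 0.9940,
  "derived": { "half_life": 0.9322, ... }
}
```

The fitted rate (0.74 min⁻¹, 95% CI 0.68–0.81) and its half-life
(ln 2 / K ≈ 0.93 min) recover the generating values. The linkage model does
the same for the steady-state competition readout:

```bash
$ eif2btools simulate --kind competition --seed 1 --out comp.csv
# apparent IC50 = 0.2008 uM, Hill slope = 1.73
```

A Hill magnitude well above 1 falls out of the model structure alone — ISRIB
exclusion coupled preferentially to the second eIF2(αP) site — with no
cooperativity fitted in. The structural stage runs the same way from a config:

```bash
$ printf 'synthetic_demo: true\nseed: 11\n' > demo.yaml
$ eif2btools run-all --config demo.yaml --out report --no-network
```

`report/metrics.tsv` then contains one row per comparison; for the synthetic
demo (a toy decamer whose δ-α3 helix was rotated 7.9° and shifted, and whose
second βδ half-shell was translated):

```text
  comparison  unit1_displacement_A  unit1_rotation_deg unit1_direction
        self              0.000000                 0.0
probe_motion              3.251438                 7.9  away_from_beta
pocket_shift              2.144761
```

which matches the generator's analytic ledger to ~1e-8. With the deposited
entries on disk, `eif2btools run-all --config configs/deposited_comparisons.yaml`
produces the same table for the real complexes, and
`eif2btools validate --report report/metrics.tsv --targets configs/deposited_targets.yaml`
checks it against the published values (±0.3 Å, ±1.5°).

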