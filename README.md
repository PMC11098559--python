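# myostates

Resting skeletal-muscle myosin is not idle: its heads cycle ATP even in
relaxed fibers, split between a *disordered-relaxed* (DRX) state with fast
turnover and a *super-relaxed* (SRX) state, folded against the thick
filament, that turns ATP over 5–10× more slowly. Shifts between the two
states retune a fiber's basal energy consumption and heat production — a
mechanism of particular interest in hibernating mammals, where muscle must
cut or boost ATP demand with body temperature. `myostates` is a pipeline
for quantifying these states from single-fiber experiments:

- **Mant-ATP chase analysis** (`myostates.mant_atp`): ROI extraction from
  image stacks, background subtraction and t = 0 normalization, and
  multi-start nonlinear least-squares fitting of the decay
  `F(t) = 1 − P1(1 − e^(−t/T1)) − P2(1 − e^(−t/T2))`, reporting DRX/SRX
  amplitudes (percent), lifetimes (s), standard errors and QC flags.
- **Energetics** (`myostates.energetics`): per-fiber myosin ATP consumption
  `(P1/100)·220·(60/T1) + (P2/100)·220·(60/T2)` µM·min⁻¹ (head
  concentration 220 µM, configurable), warm/cold temperature-sensitivity
  ratios on matched animal means, signed percent differences vs a baseline
  condition.
- **Group statistics** (`myostates.group_stats`): animal-level aggregation
  (the animal, not the fiber, is the experimental unit), one-way and
  two-way ANOVA, Šídák-adjusted pairwise comparisons.
- **X-ray reflection quantification** (`myostates.xray`): Gaussian + local
  baseline fits of the equatorial 1,0/1,1 and meridional M3/M6 reflections
  on 1-D diffraction profiles, exact Bragg conversion between detector
  radius and lattice spacing (λ = 0.10 nm, camera length 2.14 m defaults),
  integrated-intensity ratios I₁,₁/I₁,₀.
- **Omics statistics** (`myostates.omics`): log2 transform, valid-value
  filtering, MinProb-style left-censored imputation (shift 1.8, width 0.3),
  per-feature t-tests with Benjamini–Hochberg FDR and the FC ≥ 2 &
  FDR < 0.05 significance rule, PTM-site z-scores, sample PCA.
- **Synthetic data** (`myostates.synthetic`): seeded generators for every
  input above — hierarchical condition → animal → fiber studies, image
  stacks, diffraction profiles, abundance matrices — so the whole chain is
  testable without any experimental download.

## Worked example

Simulate a two-condition study (summer-active vs torpor, 5 animals each,
8–12 type II fibers per animal) in which torpor shortens the DRX lifetime
to 0.65× and the SRX lifetime to 0.73×, then fit and analyze it:

```yaml
# study.yaml
seed: 42
design:
  conditions: [SA, torpor]
  animals_per_condition: 5
  fibers_per_animal: [8, 12]
  fiber_type_proportion: 1.0
effects:
  t1_multipliers: {"torpor:II": 0.65}
  t2_multipliers: {"torpor:II": 0.73}
```

```bash
myostates simulate   --config study.yaml --out run
myostates fit        --config study.yaml --traces run/traces.csv --out run
myostates energetics --config study.yaml --fits run/fits.csv --out run
myostates report     --out run
cat run/summary.txt
```

```
Myosin metabolic-state analysis summary
========================================
Fibers: 96 fit, 96 accepted, 0 rejected by QC

Type II fibers at 20 C:
  atp_consumption_uM_per_min: SA=254, torpor=373 | vs baseline: torpor +46.8% | ANOVA p=0.000649 ***
  p1_pct: SA=24.1, torpor=23.2 | vs baseline: torpor -3.9% | ANOVA p=0.466 ns
  p2_pct: SA=50.1, torpor=50 | vs baseline: torpor -0.2% | ANOVA p=0.725 ns
  t1_s: SA=14.7, torpor=9.69 | vs baseline: torpor -34.2% | ANOVA p=9.34e-05 ****
  t2_s: SA=194, torpor=140 | vs baseline: torpor -27.8% | ANOVA p=0.00262 **
```

Reading it: the fitted state proportions (P1 ≈ 24%, P2 ≈ 50%) are unchanged
between conditions, but both lifetimes are significantly shorter in torpor
(the −34.2% recovered for T1 matches the simulated 0.65× multiplier), so
per-fiber myosin ATP consumption *rises* by ~47% — faster turnover at
unchanged state occupancy costs energy. The p-values are one-way ANOVAs on
the five per-animal means in each group, never on pooled fibers.

The same stages run on real data: `fit` takes any tidy trace CSV
(fiber_id, animal_id, condition, fiber_type, temperature_C, time_s,
raw_fluor, background_fluor), `xray` takes long-format profile CSVs, and
`omics` takes an abundance matrix + sample annotation.

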