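# empdcc

Dimensional toxicology of elongate mineral particles (EMPs): per-particle
metrics, population habit classification, and mesothelioma potency models,
with a synthetic particle-population generator so the whole pipeline is
testable without a raw dimensional database.

## The problem

Amphibole minerals such as tremolite occur in two growth habits with very
different health implications: the **asbestiform** habit (long, thin,
flexible fibres grown in place — a potent mesothelioma hazard) and the
**non-asbestiform** habit (blocky cleavage fragments produced by crushing
massive rock — dimensionally overlapping with fibres but toxicologically
closer to nuisance dust). Regulators, exposure scientists and
mineralogists need to tell the two apart from the one thing a microscope
count reliably gives: the lengths L and widths W of the particles (µm).

## What the package computes

Per particle (`empdcc.metrics`):

- thickness `Th` by an empirical per-class rule (asbestiform/mixed
  amphiboles: `log10 Th = 0.692 log10 W − 0.493`; erionite `Th = W`;
  other non-serpentine `W/1.9`; …),
- surface area `SA = 2LW + 2L·Th + 2W·Th` (serpentine: `0.5πW² + πWL`),
- Timbrell aerodynamic diameter `AD = 66 W (AR/(2+4AR))^2.2 (ρ/ρ₀)^0.5`,
- the criteria-particle score `2.99 log10 L − 5.82 log10 W − 3.80`
  (≥ 0 ⇒ dimensions associated with asbestiform habit), and
- the **Dimensional Coefficient of Carcinogenicity**
  `DCC = 1 − exp(−A·SA^K / (B·W^T + C))`, a [0, 1) score with fitted
  coefficients A = 0.11, K = 1, B = 1000, T = 3, C = 1.

Per dataset (`empdcc.population`, `empdcc.classify`, `empdcc.potency`):

- criteria fraction (CF), Pearson index (PI = corr(log L, log W)), EMPA
  (fraction of EMPs > 5 µm long that are ≤ 0.15 µm wide), mean DCC;
- the habit decision boundary — **asbestiform iff CF ≥ 0.58·PI + 0.12** —
  with "undetermined" rules for possibly mixed samples, an aspect-ratio-5
  variant, and a Mahalanobis-distance classifier against reference
  particle clouds;
- two potency models on the Hodgson–Darnton scale (R_M, %):
  `R_M = −0.012 + 0.011·EMPA(%)` and
  `log10 R_M = 0.04 + 1.15 log10(Biosolubility) + 2.15 log10(DCC)`,
  plus the cytotoxicity link `log10 HC50 = −1.06 + 17.12·DCC` and the rat
  intrapleural link `1.26 + 0.48 log10 R_M`.

`empdcc.calibration` reproduces the Monte-Carlo selection of the DCC
coefficients (objective `Coef = R·U_asb^¼ / U_nonasb^½`), and
`empdcc.synthetic` generates log-normal particle populations with
habit-dependent length–width correlation, parameterised from the published
dataset summaries.

## Worked example

```python
from dataclasses import replace
from empdcc import (ASBESTIFORM_DEFAULT, generate_population, summarize,
                    classify_boundary, estimate_potency)

pop = generate_population(replace(ASBESTIFORM_DEFAULT, n=2000, seed=1))
s = summarize(pop)
print(f"n={s.n_particles}  CF={s.criteria_fraction:.3f}  PI={s.pearson_index:.3f}  "
      f"EMPA={s.empa:.3f}  mean DCC={s.mean_dcc:.4f}")
call = classify_boundary(s.criteria_fraction, s.pearson_index)
print(f"habit: {call.label.value}  (margin {call.boundary_margin:+.3f})")
print({k: round(v, 3) for k, v in estimate_potency(s.empa, s.mean_dcc).items()})
```

prints

```
n=1815  CF=0.942  PI=-0.004  EMPA=0.034  mean DCC=0.0480
habit: asbestiform  (margin +0.824)
{'rm_empa': 0.025, 'rm_dcc': 0.141, 'rm_mean': 0.083}
```

Of the 2000 generated particles, 1815 fall in the main counting window
(L > 5 µm, 0.05 ≤ W ≤ 3 µm, AR ≥ 3). 94 % of those are criteria
particles and log-width is uncorrelated with log-length (PI ≈ 0), so the
population sits far on the asbestiform side of the boundary
(margin +0.82). The two potency estimates bracket a mesothelioma potency
of ~0.03–0.14 % on the Hodgson–Darnton scale — between amosite and
crocidolite levels for this thin-fibre tremolite population.

There is also a CLI:

```sh
empdcc simulate --habit table5 --n 2000 --seed 0 --out particles.csv
empdcc classify particles.csv
empdcc potency particles.csv --model both --mineral tremolite
empdcc calibrate --draws 2000 --seed 0
empdcc reproduce          # fast fixture-based checks
empdcc reproduce --full   # adds the synthetic-population checks
```

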