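# Methods

## Scope and data model

All computations operate on particle tables: one row per elongate mineral
particle (EMP) with `length_um`, `width_um` (microscope-measured longest
dimension and the longest perpendicular dimension, µm), an optional
mineral class, density (g/cm³) and dataset id. Units are micrometres
end-to-end; nothing downstream converts units.

## Counting windows

Every population metric is defined over an explicit counting window:

| profile | length | width (µm) | aspect ratio |
|---|---|---|---|
| `main_emp` | > 5 µm (strict) | 0.05–3 inclusive | ≥ 3 |
| `pearson` | > 2 µm (strict) | 0.05–3 inclusive | ≥ 3 |
| `empa_numerator` | > 5 µm | 0.05–0.15 inclusive | ≥ 3 |
| `*_ar5` | as above | as above | ≥ 5 |

The Pearson window is deliberately wider in length than the main window:
the length–width correlation is a property of the whole fibre population,
while the toxicity-oriented metrics restrict to particles long enough to
matter biologically. EMPA's denominator is the main window (including its
width bounds), its numerator the ≤ 0.15 µm subset.

## Per-particle model

Thickness is the unobserved third dimension, inferred from width by an
empirical per-class rule (asbestiform and mixed amphiboles:
`log10 Th = 0.692 log10 W − 0.493`; erionite Th = W; balangeroite W/1.1;
fibrous talc W/3; other non-serpentine W/1.9). The rules are treated as
exact assignments. Note the amphibole power law crosses Th = W at
W ≈ 0.025 µm, far below any measured fibre width, so Th < W holds
throughout the observed range. Amphiboles *without* asbestiform habit are
intentionally mapped to the blockier W/1.9 rule: cleavage fragments have
near-rectangular cross sections, while the power law describes fibril
bundles.

Surface area uses a rectangular-prism model `2LW + 2(L+W)·Th`
(serpentine: cylinder with end caps, `0.5πW² + πWL`). The aerodynamic
diameter is Timbrell's fibre formula with density from a small editable
mineral configuration (e.g. tremolite 3.0, crocidolite 3.4, chrysotile
2.55 g/cm³); density only enters as a square root, so literature values
are adequate.

The criteria-particle score `2.99 log10 L − 5.82 log10 W − 3.80` is a
fixed published discriminant; the boundary (score = 0) counts as a
criteria particle.

The DCC, `1 − exp(−A·SA^K/(B·W^T + C))`, is clamped strictly below 1 at
float resolution so the documented [0, 1) invariant holds even for
pathological inputs. Defaults (A = 0.11, K = 1, B = 1000, T = 3, C = 1)
are the fitted coefficients; B is a pure scale convention.

## Habit classification

The default classifier is the fixed published boundary
`CF ≥ 0.58·PI + 0.12`, with two inclusive "undetermined" rectangles
(PI ∈ [0.3, 0.5] ∧ CF ∈ [0.2, 0.3]; PI ∈ [0.4, 0.5] ∧ CF ∈ [0.1, 0.2])
capturing mixtures that a pure two-class boundary would under-call.
Interval bounds are taken inclusive — the natural reading of decision
rules quoted with `>=`/`<=`. The aspect-ratio-5 variant
(`CF* ≥ 5.8·PI* − 2.02`) has no published undetermined zone and gets
none.

The Mahalanobis classifier compares a dataset's main-window (length,
width) centroid with reference asbestiform and non-asbestiform particle
clouds under the pooled (n−1 weighted) covariance of the two compared
groups. Raw micrometre coordinates are the default (a log-space option
exists behind a flag, since the choice of coordinates is a genuine
modelling degree of freedom); exact distance ties return undetermined.
When a reference dataset is evaluated against pooled references, it is
excluded from its own reference pool (leave-one-out), avoiding an
optimistic bias.

Refitting the linear margin is opt-in: a soft-margin linear SVM with
penalty C = 1000 in (PI, CF) space, reported in the same
`CF ≥ slope·PI + intercept` form. The fixed published boundary remains
the default method.

## Potency models

EMPA enters the linear model in percent (0–100); dataset tables store it
as a fraction. This convention is forced by the published per-dataset
potency values (e.g. EMPA fraction 0.648 → 64.8 % → R_M 0.701). Negative
outputs of the linear model are reported verbatim and interpreted as
negligible potency. The DCC model exponentiates a log-linear fit in
biosolubility (years; 49 for any tremolite population) and population
mean DCC. The arithmetic mean of per-particle DCC is the population
statistic throughout; note that the DCC of the mean (SA, W) differs from
the mean DCC, and only the latter is used.

The width maximising the DCC expression for compact particles has the
closed form `(2KC/(B(T−2K)))^(1/T)`, requiring T > 2K; at the defaults it
is 0.126 µm, consistent with the 0.1–0.2 µm band where width is most
potency-predictive.

Regression refits (DCC ~ criteria fraction, HC50 ~ DCC, rat potency ~
log R_M) use OLS via statsmodels on the embedded tables. Reported R is
the Pearson correlation (signed by the slope) for one predictor and the
multiple correlation √R² otherwise; the p-value is the overall-fit F
test (the per-coefficient alternative is not meaningfully different for
these small fits). Exact coefficient reproduction is not expected —
published inputs are rounded to 2–3 decimals — so comparisons are
tolerance-banded rather than digit-exact.

## DCC coefficient calibration

Candidate vectors (A, K, T, C) are drawn uniformly within A ∈ [0.10, 2],
K ∈ [1, 5], T ∈ [0.5, 5], C ∈ [1, 10] (B fixed at 1000) under a seeded
generator; continuous sampling is used (nothing suggests an
integer-constrained search), with optima reported at full precision. For
each draw, the per-mineral mean DCC feeds the two-predictor log-linear
potency fit; R is taken as +√R² and fits with a non-positive DCC
coefficient are rejected, as are draws that order the habit groups the
wrong way (U_asb ≤ U_nonasb). The objective is
`Coef = R·U_asb^¼ / U_nonasb^½`; it is scale-consistent in the sense
that rescaling all DCC values by c multiplies it by c^(−¼).

The per-mineral populations are synthetic: geometric-mean width from the
published per-mineral mean width, and geometric-mean length solved in
closed form so that the geometric-centre particle's surface area equals
the published per-mineral mean surface area. With 2000-particle
populations, the fitted vector (A = 0.11, K = 1, T = 3, C = 1) scores
above the entire 2000-draw random trace — a considerably stronger
statement than the top-decile property the test asserts.

## Synthetic populations

The generator emulates the dimensional structure the analysis assumes,
not any particular raw dataset:

- **asbestiform**: log10 L ~ N(log10 gm_length, log10 1.8), log10 W drawn
  independently ~ N(log10 gm_width, log10 1.6) — independence is the
  defining dimensional signature of in-place fibre growth;
- **non-asbestiform**: log10 W = 0.6·(log10 L − log10 gm_length) +
  log10 gm_width + N(0, 0.2) — comminution couples the two dimensions.

The residual SD 0.2 was chosen so the generated non-asbestiform Pearson
index lands at the observed central value (~0.6) given slope 0.6 and
length GSD 1.8; the implied marginal width GSD (≈1.8) is consistent with
the pooled non-asbestiform width coefficient of variation. Per-dataset
specs use the published mean length/width as geometric means; the
published per-dataset "standard deviation" columns are not used to set
spread because their scale is ambiguous (they are too small to be
arithmetic SDs and < 1, so not geometric SDs; plausibly standard errors).
Initially-unclassified datasets use their a-posteriori habit to choose
the generation branch. Draws are rejection-resampled into L ≤ 200 µm,
W ≤ 5 µm.

What the generator does **not** emulate: the heavy criteria-particle tail
observed in some real non-asbestiform datasets (real criteria fractions
reach 0.27 where the log-normal model with a realistic Pearson index
produces ≈ 0.1), measurement error, within-dataset mineral heterogeneity,
and byssolitic intermediates. Passing synthetic tests therefore
demonstrates that the pipeline recovers habit and potency structure from
populations with the assumed log-normal geometry — not that it would
reproduce any specific raw dataset's numbers.

### Mixture and subsampling experiments

Mixtures draw each particle from the pooled asbestiform or pooled
non-asbestiform synthetic testing populations with probability equal to
the mixing fraction (binomial composition). The mixture experiment runs
200 seeded mixtures of n = 2000 particles with nominal fractions uniform
on [0, 1] — mixtures across the full fraction spectrum — and labels each
by its *realized* asbestiform share; mixtures with nominal fraction
≥ 1 % carry a "contaminated" flag. The asserted property is that no
mixture with ≥ 20 % realized asbestiform content is ever called
non-asbestiform (such mixtures land either above the boundary or in the
undetermined rectangles). The margin at exactly 20 % is small (~0.03 in
criteria fraction), which is precisely why the undetermined zone exists;
n = 2000 matches the population sizes used throughout and keeps metric
noise below that margin.

The subsampling experiment repeatedly draws fixed-fraction subsets
without replacement and records the Pearson index of each; at a 10 %
subset of a 2000-particle population the asbestiform and non-asbestiform
index distributions are essentially disjoint (< 5 % of paired draws
overlap), showing the habit signal survives small counts.

## Numerical choices and degenerate inputs

- Welch's t (unequal-variance form, n−1 denominators) for group
  comparisons; identical constant groups give t = 0, zero-variance groups
  with differing means give ±∞ flagged degenerate.
- The Pearson index requires ≥ 3 particles and non-zero variance in both
  log dimensions; inside `summarize` an undefined index becomes NaN
  rather than failing the counting metrics.
- Boundary classification validates CF ∈ [0, 1] and PI ∈ [−1, 1];
  Mahalanobis references require symmetric positive-definite 2×2
  covariances; the SVM refit rejects single-class input and degenerate
  orientations.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; population generation, mixing, subsampling and calibration are
  bit-reproducible under a fixed seed.

## Problem sizes

Synthetic checks use 2000 particles per population (24 dataset analogues,
pooled testing groups of 16 000 and 16 000), 200 mixtures of 2000
particles, 100 subsampling repetitions, and 2000 calibration draws.
These sizes keep every population statistic's sampling noise well inside
the asserted tolerance bands while the full suite runs in seconds.

## Known limitations

- Published per-dataset EMPA values are stored at 3-decimal precision, so
  the EMPA-linear potency column can be reproduced only to within one
  unit in its last printed digit for a few datasets; the same
  input-rounding caveat applies to the per-mineral DCC potency column
  (exact for crocidolite).
- The thickness rules, criteria score, decision boundary and DCC
  coefficients are published constants validated on tremolite and close
  amphibole relatives; applying them to other mineral systems is an
  extrapolation.
- Potency estimates carry no uncertainty intervals (none are defined for
  the underlying fits), and the HC50 mg/ml ↔ fibre-count conversion is
  not modelled (conversion factors unavailable).
- Rigidity/elasticity of fibres, a recognised co-determinant of
  biological behaviour, is outside the dimensional model.
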