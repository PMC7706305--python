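# Methods

## Scope

`phenoheat` implements the complete analysis chain of a daily-imaging heat
stress screen on Arabidopsis rosettes — trait derivation, temporal
statistics, cross-time correlation and genotype classification — together
with a synthetic experiment generator that stands in for the (non-public)
raw instrument data. The generator is first-class, tested code: its role is
to produce data with the known statistical structure the analyses assume,
so every downstream claim can be checked against injected ground truth.

## The synthetic experiment

Design: 2 genotypes (WT, *hsp101*) × 4 treatments (control, 3 h, 6 h, 9 h
at 45 °C) × `n_reps` replicates (default 20 → 160 plants), laid out on
trays of 20 pots with genotypes alternating, imaged at DAS −1 … 7 (stress
day = DAS 0, imaging one hour after the plants return from the heat
chamber).

**Growth.** True rosette area follows the discrete logistic map
`A(d+1) = K / (1 + (K/A(d) − 1)·e^(−r_d))` with carrying capacity
`K = 3000 mm²`, baseline rate `r = 0.25 d⁻¹` and initial area 300 mm² at
DAS −1 (a realistic three-week-old rosette). From DAS 0 the rate carries a
multiplicative treatment penalty (0.17 / 0.33 / 0.50 for 3 / 6 / 9 h —
roughly proportional to stress hours) plus an extra *hsp101* penalty (0.08 /
0.12 / 0) that vanishes at 9 h, where the stress overwhelms both genotypes.
An acute shrinkage of 2.5 % per stress hour on DAS 0 models turgor loss, so
treated plants are already measurably smaller one hour after the stress.
Per-day multiplicative rate noise (lognormal, σ = 0.03) and a per-plant
vigor factor (lognormal, σ = 0.05, applied to the initial area) provide
biological variability. Because the logistic step is exactly invertible
(`r = log((K/A_d − 1)/(K/A_{d+1} − 1))`), tests recover the injected
penalty without bias.

**Chlorophyll fluorescence.** A plant's light curve is built from a
baseline `F₀ = 200 a.u.` (a plant-mean signal, deliberately independent of
rosette size) and dark-adapted quantum yield `QYmax = 0.80`, so
`Fm = F₀/(1 − QYmax)`. Heat depresses Fm multiplicatively by 5 % per
stress hour (×1.8 for *hsp101*), capped at 45 % so the 9 h regime saturates
both genotypes; the per-plant depression is additionally scaled by a
lognormal damage-heterogeneity factor whose σ grows with √hours — severe
stress produces erratic damage, which is what makes the 9 h group a poor
genotype discriminator. The deficit decays linearly to zero over a
per-genotype delay (WT 1 day, *hsp101* 2 days), reproducing the observed
recovery asymmetry. Per step k the light-adapted maxima follow
`Fm′ = Fm/(1 + NPQ_k)` with an NPQ profile rising over the six actinic
steps (0.10 … 1.20); `F₀′` uses the standard Oxborough–Baker relation
`F₀′ = F₀/(Fv/Fm + F₀/Fm′)`; and `Ft′ = Fm′ − qP_k (Fm′ − F₀′)` with a qP
profile falling from 0.87 to 0.47 across steps. Stress reduces qP on DAS 0
(by 25/40/50 % for WT, more for *hsp101* except at 9 h) recovering over
1/2/3 days (+1 day for *hsp101*), and reduces NPQ by 3 % per stress hour.
All emitted signals receive 2 % multiplicative Gaussian noise; the
noiseless construction guarantees `Fm > F₀` and `Fm′ > Ft′ ≥ F₀′`, and the
rare noise-induced ordering violation is redrawn so derivations stay in
domain.

**Latent tolerance.** Each plant carries a uniform(0, 1) tolerance
variable that (i) moderates its DAS 0 qP drop and (ii) scales its
post-stress growth rate (coupling coefficient 0.6, spans 0.5 / 0.6). This
single mechanism generates the screen's key signature: in stressed groups,
photochemical quenching right after stress correlates with rosette area a
week later (r ≈ 0.5–0.8) while the same-day correlation is near zero;
setting the coupling to 0 removes the effect. In the control group the
tolerance variable is inert.

**Thermal and morphology.** Leaf temperature sits at ambient (22 °C) minus
transpiration cooling (1.2 °C) plus, on DAS 0 only, 0.25 °C per stress
hour — no genotype difference, matching the observation that leaf cooling
did not separate the genotypes. Rosettes are rendered as a centre disk
plus elliptic leaf lobes; stress reduces the leaf aspect ratio (slender →
rounder, more so in *hsp101* at 3/6 h) and opens the rosette, which moves
SOL, compactness and isotropy in the directions seen in real screens. The
lobe radius is solved iteratively so mask pixel area matches the true area
within 2 %.

**Failures.** 5 % of plants are "runts" (grow at a tenth of the rate);
under the 9 h regime plants die with probability 0.1 on DAS 0 (≈ 4 of 40)
and emit no further records. Both classes are flagged in the registry and
removed across all days by the exclusion filter, mirroring the screening
rule of the original experiment.

What the generator does *not* emulate: photorealistic images, pixel-wise
fluorescence heterogeneity (plant-mean signals only), leaf-angle responses
(invisible in top view), within-day kinetics, humidity/CO₂ covariates, and
tray-position effects. Passing tests therefore demonstrate that the
*analysis* is correct and sensitive under the assumed structure, not that
real data will show effects of these exact sizes.

## Trait definitions (morphometry dialect)

The commercial platform's formulas for compactness, isotropy, RMS and SOL
are unpublished, so this package pins its own standard, fully testable
dialect (versioned `phenoheat-1`): crack-convention perimeter (exposed
pixel edges; exact closed forms on rectangles), convex-hull area as the
polygon area over pixel corners (compactness exactly 1 for rectangles),
eccentricity/isotropy from the second-moment eigenvalues, RMS as the mean
Jaccard overlap with k−1 = 7 nearest-neighbour centroid rotations, and SOL
as (topological-thinning skeleton length)²/area with √2 weighting for
diagonally-linked skeleton pixels. Each is monotone in the same direction
as the platform's usage; numerical agreement with the platform is not
claimed. Components use 8-connectivity; holes are filled; the largest
component is kept.

## Statistics

Group comparisons use the classic equal-variance two-sample t-test
(two-sided; Welch behind a flag) with the ∗ (p<0.05) … ∗∗∗∗ (p<0.0001)
star notation, with no multiple-testing correction by default (per-day
starring, as is conventional for time-course figures); Benjamini–Hochberg
is available. The interaction model
`trait ~ genotype + treatment + genotype:treatment` is fitted by OLS via
normal equations with reference coding (WT, control) separately for each
heat level against control; on balanced noiseless data its interaction
coefficient equals the 2×2 cell-mean contrast exactly. Pearson
correlations carry t-distribution p-values with n−2 df; cross-time
correlations pair plants across days within genotype × treatment strata
and omit strata with fewer than 3 complete plants. Dead plants drop out
listwise.

The *recovery day* of QY max is the first DAS ≥ 0 from which the treated
group stays indistinguishable from control — non-significant at α = 0.05
*or* mean deficit below a practical-equivalence margin of 0.02 (a quarter
of the smallest injected dip). The equivalence arm keeps the estimate
stable against the 5 % false-positive rate a pure significance rule would
suffer on fully recovered days.

## Classification

The lasso-logistic objective `mean log-loss + λ‖w‖₁` (intercept
unpenalised) is minimised by two in-package solvers — monotone proximal
gradient with backtracking, and cyclic coordinate descent with a
per-coordinate quadratic majoriser (curvature bound ¼·mean xⱼ²) — which
agree to 1e−6 and satisfy the KKT conditions to 10× the convergence
tolerance (checked against finite differences and scikit-learn's saga in
tests). λ ≥ λ_max = ‖∇loss(0, b̂₀)‖∞ provably zeroes all weights.

Accuracy is estimated by nested cross-validation with *plant-level*
stratified fold assignment: all days of a plant share a fold, so the
pooled plant-day samples never leak between train and test. Per outer fold
(k = 5), an inner 3-fold grouped CV picks λ from a log-spaced grid
(λ_max → λ_max/100, 6 points, warm-started down the path; ties favour the
stronger penalty), the model is refitted on the outer training set, and
standardisation is always estimated on the training partition only. Trait
ranking sorts nonzero weights by |standardised weight|, ties broken
lexicographically.

## Numerical choices and problem sizes

- Mask rendering on a 180×180 grid at 0.6 mm/px (plants up to the 3000 mm²
  carrying capacity fit with margin); renders are bit-reproducible per
  (state, seed).
- Rotations for RMS use exact nearest-neighbour inverse mapping about the
  binary centroid on a zero-padded grid, so no foreground is clipped.
- All randomness flows from integer seed sequences (per plant, day and
  modality), making every stage byte-deterministic for a fixed seed; the
  pipeline manifest records SHA-256 hashes of all outputs.
- Solver defaults: coordinate descent, tol 1e−8 (single fits) / 1e−5
  (cross-validation), max 5000 / 800 iterations; non-convergence is
  reported via a warning and a flag on the returned model, which matters
  only for near-separable tiny groups at near-zero penalty.
- The test suite runs the full default screen once (160 plants, 9 days,
  ~96k trait values, ≈ 25 s) and shares it across the headline checks;
  generator property tests use 8–12 replicates of reduced designs. The
  acceptance script repeats the full screen plus eight nested-CV runs in a
  few minutes on one CPU.

## Known limitations

- The morphometry dialect is self-consistent but not numerically
  exchangeable with the commercial platform's unpublished formulas.
- The interaction model ignores tray effects (fixed-effects OLS only), as
  in the original analysis; a mixed model would be the natural extension.
- Logistic classification is binary (tolerant vs. susceptible); screens of
  many genotypes need multiclass or quantitative models.
- F₀′ is generated (and consumed) as a measured signal; instruments that
  estimate it from the Oxborough–Baker relation rather than measuring it
  will differ only through measurement noise, which the generator already
  models.
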