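# Methods

`nmrmetab` implements the analysis chain used in ¹H NMR urinary
metabonomics case–control studies: spectral preprocessing (region
exclusion, probabilistic quotient normalization, recursive segment peak
alignment, unit-variance scaling), two-class PLS-DA / O-PLS-DA with
cross-validated Q² and permutation validation, STOCSY-based peak
assignment, and the accompanying univariate statistics. Because raw
cohort spectra of this kind are rarely shareable, the package ships a
synthetic-spectrum generator with recorded ground truth, so every stage is
testable as a parameter-recovery problem.

## The synthetic urine cohort

A spectrum is a sum of Lorentzian multiplets on a shared ppm grid
(descending, 0.5–9.5 ppm by default). Each named metabolite is a set of
multiplets (`center_ppm`, relative intensity, number of lines, J-spacing,
width); line intensities inside a multiplet follow the binomial pattern of
first-order coupling. Line positions are nominal literature values for
urine at pH ≈ 7 and are configurable; they are defaults, not measurements,
and no test asserts an absolute chemical shift.

The nuisance structure mirrors what the preprocessing chain exists to
remove, and its defaults are chosen once as a realistic operating point
for a 600 MHz, 256-scan urine acquisition:

- **Dilution** — each spectrum is multiplied by a log-normal factor
  (log-SD `dilution_sigma`, default 0.4): urine concentration varies
  several-fold between voids. This is the target of PQN.
- **Position jitter** — each compound's lines shift by a per-sample
  Gaussian offset (SD `jitter_sd_ppm`, default 0.002 ppm), mimicking
  pH/ionic-strength dependent drift. This is the target of RSPA.
- **Crowded matrix** — besides the ~15 named metabolites, 150 minor
  unassigned singlets (positions and scales drawn once per cohort, kept
  clear of named line positions) and 8 broad macromolecular envelope
  components cover the spectrum. This matters statistically: real urine
  carries correlated biological variance at essentially every frequency,
  and a generator without it produces thousands of near-empty columns that
  unit-variance scaling would blow up into i.i.d. noise, making any
  full-resolution latent-variable model fail at cohort-scale n — contrary
  to how such models behave on real urine.
- **Co-regulated biology** — log-concentrations decompose into shared
  variation carried by 6 latent axes (diet, microbiome, renal function …)
  plus compound-unique variation. Named metabolites load on the axes with
  per-factor scale `met_factor_sigma` (0.08) on top of unique log-SD
  `conc_sigma` (0.15), giving a total CV of ≈ 25%; background compounds
  are factor-dominated. Concentrating most variance in a few shared
  components is both what is observed in urinary NMR and the premise of
  orthogonal signal correction.
- **Baseline, solvent, noise** — a smooth random cubic baseline
  (amplitude 0.05), an optional residual water hump at 4.8 ppm, and white
  noise with SD 1e-3 of a unit named-metabolite peak (256-scan spectra
  resolve major peaks at SNR ≥ 10³).
- **Grid** — 9000 points over 9 ppm (1.0 mHz/0.001 ppm spacing) so the
  0.003 ppm default linewidth is sampled by ~3 points; on coarser grids,
  sub-grid line placement aliases apex heights and artificially destroys
  apex-level correlations.

Class effects are fold-changes applied to class mean concentrations of
designated metabolites. The paper-style studies report loading
correlations, not fold-changes, so effect sizes are free parameters; the
package's reference scenario uses 1.5-fold on three discriminators, which
lands the fitted models in the Q² ≈ 0.2–0.5 regime such studies report.
`GroundTruth` records dilution factors, per-compound jitter, the effect map
and each metabolite's apex (strongest-line) position.

The generator does **not** simulate the time domain (no FID, apodization or
phasing), true J-coupling physics, 2D experiments, or matrix differences
between human and mouse urine. Passing recovery tests therefore show that
the algorithms do what they claim under the stated nuisance model — not
that they are robust to every artefact of real spectra.

## Preprocessing

Default order: region exclusion → PQN → RSPA → unit-variance scaling.

**Region exclusion** removes all columns inside a union of closed ppm
intervals; the human default is the residual-water window 4.7–4.9 ppm.
Study-specific signal removal (e.g. xenobiotic metabolite resonances) is
expressed as additional regions in configuration, not code.

**PQN** divides each spectrum by the median of its point-wise ratios to a
reference (cohort median spectrum by default), taken over columns where the
reference exceeds 5% of its maximum — the signal-bearing columns; with a
near-zero threshold, baseline columns dominate the median of ratios and
the quotient estimate collapses. The quotient estimates the sample's
dilution up to a cohort-wide constant. Its accuracy is limited by biology,
not arithmetic: with effective compound groups G contributing ratio
columns and per-compound log-SD σ_bio, the quotient error is
≈ 1.25·σ_bio/√G, a few percent under realistic variation. The recovery
test therefore isolates dilution (biological variation ≈ 2%), where
correlation with truth exceeds 0.999.

**RSPA** aligns each spectrum to a pooled reference by recursive
segmentation: a segment is shifted by the integer offset (within a limit)
maximizing Pearson correlation with the reference, then split at the
reference's intensity minimum in its middle third, recursing until
`min_segment_points` (64) or the depth cap. Points shifted off an edge are
filled with the edge value; the point count never changes. Two estimation
details matter:

- *Reference*: the cohort **mean** spectrum, recomputed over `n_iter`
  (3) passes. For a symmetric shift distribution the mean profile's centre
  of mass sits at the true position; a median reference or a designated
  sample anchors the consensus to a biased location.
- *Coarse-to-fine matching*: shifts are estimated on Gaussian-smoothed
  copies of both reference and spectrum (initial SD ≈ half the smallest
  segment's shift limit, quartered per pass) and applied to the raw data.
  Without smoothing a sharp line locks onto the tallest bump of the pooled
  profile — a noisy mode of the cohort's shift distribution — which can
  displace a whole consensus position by up to the jitter SD.

Even so, reference-based alignment cannot beat the cohort's own consensus:
the residual apex error floor is ≈ 1.25·σ_jitter/√n plus half a grid step.
At the study-scale n = 90 and 0.01 ppm jitter this floor is ≈ 0.001 ppm,
an ~7-fold improvement over the unaligned error of ≈ 0.008 ppm.

**Unit-variance scaling** mean-centres each column and divides by its SD
(n−1 denominator); zero-variance columns are dropped and recorded so
loadings can be mapped back (`backscaled = p · sd`). The transform is an
exact bijection on kept columns given its `ScalingState`.

## PLS-DA / O-PLS-DA

Two-class discrimination is PLS1 regression of the 0/1 class dummy on the
scaled spectra. With a single y the NIPALS inner loop has a closed form
per component: w ∝ Xᵀy (unit norm), t = Xw, c = yᵀt/tᵀt, p = Xᵀt/tᵀt,
deflate. O-PLS-DA first removes `n_orth` orthogonal components
(w_orth ∝ p − (wᵀp)w; scores exactly orthogonal to centred y by
construction) and then fits one predictive component; with `n_orth = 0` it
equals one-component PLS-DA to machine precision. R²X counts predictive
plus orthogonal components against total initial variance; R²Y uses only
the predictive component. Because w ∝ Xᵀy, the predictive score is
positively correlated with the class dummy, so recoding classes flips
score signs only — c is invariant.

`n_orth` is a per-model configuration input (the studies report 2–3 per
model without stating a selection rule; no automatic selection is
provided). On the synthetic cohorts ~5 orthogonal components are needed
before per-variable correlations reach their univariate values, matching
the simulator's count of large shared-variance components (latent axes,
envelopes, normalization residual); an analyst should set `n_orth` to the
scale of the structured y-orthogonal variance of their data.

## Validation

**Q²Y** comes from stratified 7-fold cross-validation with scaling refit
inside every training split (no leakage); Q² = 1 − PRESS/TSS with TSS
around the overall class mean. Folds are redrawn (bounded) if a training
split would lose a class; repeated samples from one subject can be kept in
one fold via a `groups` argument.

**Model validity** is a label-permutation test: the full procedure (folds,
per-fold scaling, fit, prediction) is recomputed under `n_perm` label
shuffles, and p = (1 + #{null ≥ observed})/(1 + n_perm) — one-sided with
the +1 correction, so p is never 0 and the floor at 1000 permutations is
1/1001 ≈ 0.001. "Top 5% of the null" is exactly p < 0.05. The test is
exchangeable by construction and verified calibrated on i.i.d. and on
simulated null cohorts.

**Per-variable significance** compares each variable's observed |r|
(correlation between predictive score and scaled column) with its own
label-permutation null, +1-corrected, flagged at α = 0.05 per variable to
match the reporting rule of such studies; an optional Benjamini–Hochberg
flag exists but is off by default. Scaling does not depend on the labels,
so it is fit once.

## STOCSY and univariate layer

STOCSY correlates the driver column (nearest grid point to the requested
ppm) with every column, returning Pearson r (for colouring) and covariance
(for the spectrum-like profile). It should be run on normalized spectra:
on raw urine the shared dilution factor correlates everything with
everything. With one predictive component and no orthogonal filtering,
STOCSY r and the model's loading correlations agree up to the sign of the
driver's own loading (both are correlations against essentially the same
latent direction); agreement is asserted at |ρ| > 0.9 in the tests.

Univariate pieces: Mann–Whitney U with midranks, exact by enumeration over
all group assignments when the pooled n ≤ 10 (valid under ties) and
otherwise a tie-corrected normal approximation with continuity correction;
Spearman via midrank-Pearson with the t-approximation; Welch (default) or
pooled t-tests, optionally on logs, one- or two-tailed (one-tailed =
observed-direction tail); Pearson χ² without continuity correction by
default; geometric means with t-based CIs on the log scale; and logistic
regression of outcome on metabolite + covariate (maximum likelihood via
Newton/IRLS) with Wald p-values and explicit perfect/quasi-separation
flags.

## Numerical and reproducibility choices

- One RNG stream per simulated cohort, seeded from the design; the draw
  order is documented in `simulate_cohort` and identical designs are
  bit-identical.
- Integer-point alignment shifts only; ties in the shift search break
  toward zero, so self-alignment is exactly the identity.
- All validation seeds are explicit arguments; derived seeds come from
  `numpy.random.SeedSequence` and stay below 2³¹.
- Spectra CSVs round-trip at 12 significant digits; report JSON is
  versioned, sorted and byte-stable for fixed seeds.
- Degenerate inputs fail loudly with the offending sample/column named:
  empty classes, all-zero-variance matrices, non-positive values under log
  transforms, zero-variance STOCSY drivers, separated logistic fits.

## Problem sizes used in tests and the acceptance script

Recovery and power properties are stochastic, so they are evaluated on
simulated cohorts at fixed sizes chosen to make the property identifiable:
dilution recovery at n = 40 with biology quieted; alignment recovery at
n = 90 (jitter SD 0.01 ppm) on isolated-singlet apexes — multiplet apexes
flip between equal-height lines under argmax and consensus bias shrinks
with √n; effect recovery at 20 vs 20 with three 1.5-fold metabolites over
20 replicates (Q² and permutation p summarized by medians — single-cohort
Q² ranges roughly 0.1–0.55 across draws); null calibration over 100
cohorts of 12 vs 12 at 99 permutations on a reduced grid, since
permutation calibration depends only on exchangeability, not spectral
richness.

## Known limitations

- Integer-shift alignment cannot correct sub-grid misalignment; on coarse
  grids this leaves apex-height variance that looks like biological noise.
- The quotient normalization inherits PQN's bias under heavy, asymmetric
  biological change (it estimates the median ratio, not the dilution).
- The per-variable permutation null is computed under label permutation;
  variables riding strong shared components have wide nulls when `n_orth`
  is set below the structured-variance count, costing power.
- Two-class models only (as in the motivating studies); no multiclass
  O-PLS-DA, no automatic orthogonal-component selection, no CV-ANOVA.
- The logistic adjustment reports separation rather than resorting to
  penalized fits.
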