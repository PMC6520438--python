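# Methods

This note records the models implemented in `srbindex`, the defaults and
numerical choices behind them, and what the synthetic-data generator does
and does not emulate. It is the design record; empirical behaviour is
established by the test suite and `scripts/acceptance.py`, not asserted
here.

## 1. Segmentation

**Background.** Each channel's background is the modal intensity of its
full-image histogram (bin width 1 intensity unit; the reported value is
the mean of the pixels in the modal bin, which keeps the estimate sensible
for float images). The mode is subtracted as a constant and the result
clipped at zero. Rationale: in plate-reader fields the cell-free background
is the single most populated narrow intensity level, and no spatial
background model is warranted at 4x magnification. The estimator assumes a
genuine background region exists; on degenerate images whose only sharp
histogram peak is a perfectly uniform foreground level (possible with
noise-free synthetic renders, not with acquired data) the caller should
pass the known background explicitly (`AnalysisConfig.hoechst_background` /
`srb_background`).

**Threshold.** Ridler–Calvard intermeans (isodata): iterate
`T ← (mean(I ≤ T) + mean(I > T))/2` from the global mean until the update
falls below 0.5 intensity units (max 100 iterations). At convergence T lies
strictly between the two class means. A constant image has no threshold and
raises a degenerate-input error; `build_nuclear_mask` converts that into an
*empty mask plus a logged warning*, because blank wells are legal on a
plate. The implementation is cross-checked in the tests against
scikit-image's `threshold_isodata` on bimodal images.

**Particles.** Connected components with 8-connectivity. Touching nuclei
deliberately remain a single particle — the elongation of a fused pair is
precisely the signal used to recognise binucleate myocytes, so no watershed
splitting is done. Components smaller than `min_area` (default 20 µm²,
debris) are dropped. Border-touching particles are kept by default
(`exclude_border=True` to drop them): plate-reader fields are large and
routine exclusion would bias density estimates. Axis lengths are those of
the ellipse with the same normalised second central moments as the pixel
set (scikit-image `regionprops`); the short axis is floored at one pixel so
the circularity ratio (long/short ≥ 1) stays finite for degenerate
single-row components. Areas are always reported in µm²
(pixel count × pixel_size²); coordinates are 0-based (x = column, y = row).

## 2. Cell-type census

Three classes: mononucleated myocytes, binucleated myocytes (one cell, one
elongated particle), fibroblasts (large round nuclei).

**Area cutoff.** A two-component Gaussian mixture is fitted to log(area);
the cutoff is the equal-posterior point between the component means (the
quadratic in x from equating the weighted component log-densities, with a
dense-scan fallback). The fit is declared *degenerate* — and a fixed
fallback cutoff used (default 90 µm², i.e. twice the typical mononucleate
median area of 45 µm²) — when either (a) the component means are closer
than 0.5 pooled standard deviations, or (b) the fitted mixture density has
no interior dip between the means. Check (b) matters because EM on a
unimodal population happily returns two *nested* components (similar means,
different spreads) that pass a means-separation test while describing one
population.

**Circularity mixture.** Particles above the cutoff are split by a
two-component Gaussian mixture on log(circularity ratio), fitted with a
hand-rolled 1-D EM: deterministic median-split initialisation, tolerance
1e-8 on the log-likelihood, max 500 iterations, component order fixed by
mean (component 1 = rounder = fibroblast). The EM exposes its per-iteration
log-likelihood trajectory, which the tests assert is non-decreasing, and is
cross-checked against scikit-learn's `GaussianMixture` on shared data.
Non-convergence returns the best iterate flagged `converged=False`.

**Classification.** Area ≤ cutoff → mononucleate; otherwise maximum
posterior under the circularity mixture, ties broken toward fibroblast.
`n_cells` counts each binucleate particle once and *includes* fibroblasts
by default (no further correction factors are applied to the index); a flag
restricts the count to myocytes. Models are intended to be fitted per plate
on pooled control wells and applied plate-wide (`run_plate` does this);
per-well fitting requires ≥ 50 particles (cutoff) and ≥ 30 large particles
(mixture).

Closely abutting but non-touching nucleus pairs are *not* merged: only
physically connected components can be classified binucleate, so the
binucleate count is, if anything, an undercount and the cell count a
corresponding overcount.

## 3. Ratiometric index

`partition_srb` background-corrects the SRB channel (independently of the
Hoechst channel) and splits it at the nuclear mask. The extra-nuclear total
deliberately includes cell-free background pixels — after constant
background subtraction they contribute ≈ 0 and the field total stays
proportional to biomass as cells spread. The nuclear reference is the
*unweighted* mean over particles of each particle's mean SRB (not the
pixel-pooled mean), which de-weights the few large fibroblast nuclei; the
choice is recorded in the partition object. No correction is made for the
sliver of cytoplasm above/below nuclei (an < 5% effect at typical density).

`index = eSRB_total / (mean nSRB × n_cells)`, undefined (error) when there
are no cells or no nuclear signal. The index is exactly invariant under a
common multiplicative gain on both channels below saturation; with
background and noise present the invariance is limited only by the
background re-estimation at each gain.

Percent-of-control responses are computed within (isolation, duration)
strata — each treated mean is divided by its time-matched control mean
within the same biological isolation, then summarised across isolations so
each isolation counts once. A stratum without a control well is a hard
error naming the stratum.

## 4. Pharmacology

**Hill model.** `R0 + Rhyp·dⁿ/(EC50ⁿ + dⁿ)`, fitted by bounded least
squares (`scipy.optimize.least_squares`, tolerances 1e-15) with bounds
R0 > 0, Rhyp ≥ 0, n ∈ (0, 5], EC50 ∈ [1e-4, 1e3] µM and quartile-based
initialisation (R0 = min response, Rhyp = span, EC50 = dose at half-span,
n = 1). Zero-dose controls enter at dose 0 and anchor R0 exactly. Weights:
inverse per-dose sample variance when every dose has ≥ 3 replicates, else
unweighted; explicit weights override. Landing on a bound sets a flag and
warns. Noiseless self-generated data round-trip to better than six
significant digits (asserted in tests). Standard errors are Gauss–Newton
asymptotics from the Jacobian at the optimum. Fits operate on
percent-of-control responses or raw indices alike — the model is
scale-free; `max_growth_percent = 100·(R0+Rhyp)/R0`.

**Inhibition.** `growth(I) = floor + (G0 − floor)/(1 + I/Ki)` — one-site
hyperbolic inhibition; at I = Ki the inhibitable component is halved. The
floor (residual growth at full inhibition) is fixed at 0 by default and
freed with `fit_floor=True`; the functional form is recorded in the fit
object since other forms (e.g. Hill-type inhibition) are plausible.

**Onset.** Per-timepoint two-sided Welch t-tests of treated vs time-matched
control replicates, Bonferroni-corrected across timepoints; the onset is
the earliest timepoint that is significant with all later timepoints also
significant (a single spurious early hit does not count), and the slope is
the least-squares slope of treated values on time from the onset onward.
On flat null simulations the spurious-onset rate stays at or below the
Bonferroni-controlled level (asserted at ≤ 7% for α = 0.05).

**Density.** `index = A·exp(−k·density)` with k ≥ 0 enforced; an
increasing trend clamps k to 0 with a warning.

## 5. Hierarchical statistics

Wells from one isolation are correlated; treating them as independent
(pseudo-replication) inflates false positives. `hierarchical_anova`
averages technical repeats within each (condition, isolation) cell and runs
the one-way ANOVA across conditions on those cluster means — duplicating
wells changes nothing (asserted), and each isolation counts once
(unweighted cluster means under imbalance). The tests demonstrate the
calibration claim at the level where it is testable: on two-level null
simulations with ICC 0.5 the cluster-mean test rejects at ~5% while the
naive well-level ANOVA exceeds 10%. A design-effect variant (well-level F
deflated by Kish's 1 + (m̄−1)·ICC with cluster-based df) is available as
`method="design_effect"` for comparison.

Variance components come from one-way expected mean squares with the
unbalanced-design n₀; negative between-isolation estimates truncate to
zero, so ICC = σ²_b/(σ²_b+σ²_w) ∈ [0, 1] always. Within
`hierarchical_anova` the components are estimated on condition-centred
values so a real treatment effect is not booked as between-isolation
variance. Bonferroni adjustment is `min(1, m·p)`.

Full mixed-model REML machinery is deliberately out of scope; the
cluster-mean estimator is the simplest procedure consistent with the
nesting structure.

## 6. Synthetic data

The generator emulates a control NRVM monolayer field:

| parameter | default | meaning |
|---|---|---|
| field_size, pixel_size | 1500×1500 px, 1 µm/px | plate-reader field of view |
| n_cells_by_type | (1925, 400, 175) | 77/16/7% mono/binucleate/fibroblast, 2500 particles — the 2000–3500/field regime |
| area medians (log-sd) | 45 / 45 / 120 µm² (0.12) | mononucleate vs fibroblast nuclear size separation; a binucleate particle carries ~1.85× the mononucleate area (two fused nuclei minus overlap) |
| circularity medians (log-sd) | 1.08 / 2.2 / 1.10 (0.12) | binucleate elongation ≫ 1 |
| nuclear_srb_mean | 200 | size-independent by construction |
| biomass_per_cell | 60000 | integrated cytoplasmic SRB per cell; baseline index = 60000/200 = 300, the ~0.3×10³ control scale |
| background, noise_sd | 10 per channel, 2 | additive offset, Gaussian read noise |
| gain | 1 | multiplies both channels after noise; clipping at the bit ceiling afterwards |
| halo_sigma | 6 µm | spread of the cytoplasmic Gaussian halo |
| density_decay | 2.2e-4 /particle | per-cell biomass suppression with seeding density (on the reference 1500² µm area; area-rescaled by `spec_for_density`), giving a >2-fold index span from ~1000 to ~4500 particles/field |

Nuclei are rendered as non-overlapping bright ellipses (a binucleate cell =
two overlapping circles forming one elongated component, centres 1.3 radii
apart), with a 2-px clearance between distinct cells so particles never
fuse across cells. Each cell's cytoplasmic biomass is deposited as a
Gaussian halo over **extra-nuclear pixels only**, renormalised over its
in-field support, so the field's total extra-nuclear SRB equals
`n_cells × biomass_per_cell × hypertrophy_factor` exactly and the
generator's analytic index is `biomass × hypertrophy / nuclear_srb_mean`
— independent of cell number and gain. Halos from neighbouring cells add.
Placement is rejection sampling with bounded retries; infeasible densities
raise a density error rather than silently under-filling.

Plate simulation crosses conditions × doses × isolations × technical
repeats. Dose effects multiply the hypertrophy factor through a Hill curve
(`1 + (Rhyp/R0)·dⁿ/(EC50ⁿ+dⁿ)`); isolation effects are log-normal
multipliers whose log-variance is set from a target ICC given the well
noise (`σ_b = σ_w·√(ICC/(1−ICC))`); per-well cell-type fractions scatter as
truncated normals around (0.77, 0.16, 0.07) with SDs (0.12, 0.14, 0.03),
clipped at 1% and renormalised — the three SDs are mutually incompatible
with a single Dirichlet concentration, and the truncation shifts pooled
means by under two percentage points. Everything is bit-reproducible given
(spec, seed).

**What the generator does not emulate** — and hence what passing tests do
not certify about acquired data: optical point-spread and defocus blur,
illumination-field inhomogeneity, staining-batch variation within a well,
genuinely overlapping nuclei, fibroblast proliferation dynamics, z-stacks,
and the (real) weaker SRB binding of fibroblasts. Tests passing on
synthetic plates show the *analysis* is correct and calibrated under the
stated statistical structure, not that the biology of any particular
culture matches the defaults.

## 7. Problem sizes

Image-based tests run on scaled-down fields (512² px / 200 cells, plate
tests 220² px / 40 cells across 96 wells) with the same per-area density
and identical analysis settings as the full-scale defaults; Monte-Carlo
calibration checks use 500–1000 replicates; classifier-recovery runs use
300 wells × 350 particles (~105 000 particles pooled). The acceptance
script's simulated designs are stated in its docstring.

## 8. Known limitations

- The histogram-mode background estimator needs a populated background
  level; it mis-locks on noise-free uniform-foreground renders (see §1).
- Binucleate cells whose nuclei are close but not touching are counted as
  two mononucleate cells (undercount of binucleates by construction).
- The equal-posterior area cutoff assumes log-area bimodality; heavily
  skewed single-population wells fall back to the fixed cutoff.
- EC50 recovery at shallow cooperativity (n ≈ 0.5) carries an intrinsic
  ~16% relative standard error under the simulated 16-replicate design;
  single-run estimates at that design scatter accordingly.
- The inhibition floor and the choice of one-site (rather than
  cooperative) inhibition are conventions, flagged in the fit output.
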