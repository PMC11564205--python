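# Methods

This note documents the models, estimators and design choices behind
`tribomove`, the assumptions they make, and what the synthetic-data tests
do and do not establish about real tracking data.

## Trajectory model and conventions

A *track* is a time-ordered sequence of planar pixel coordinates with
strictly increasing integer frame indices. Coordinates follow the image
convention (x rightward, y downward, 0-based frames); this is fixed, not
configurable, because it matches what video trackers export. Gaps inside
a track are allowed: a step spanning missing frames contributes its
straight-line chord to distance and its true elapsed time to duration,
the simplest treatment that biases neither numerator nor denominator of a
rate. A *replicate recording* groups the tracks of one arena with its
design metadata (line, selection regime, temporal block, camera), the
frame rate (default 25 fps) and an optional mm-per-pixel scale.
Operations that need physical units (the edge margin) fail loudly when
the scale is absent rather than assuming a calibration.

Replicate-level exclusions (e.g. dropping one camera in one block after
outlier screening) are config entries applied by `exclude_records`, never
hard-coded, so any omission is visible and reproducible.

## Movement metrics

**Path-length rate** is total Euclidean distance over elapsed time,
pooled across tracks as total distance / total tracked seconds. The
pooling is duration-weighted deliberately: individual identities are not
reliable in group recordings, so the quantity of interest is a
population-level rate, and weighting by tracked time makes the replicate
value exactly that. Tracks with fewer than two detections (configurable
minimum) are dropped per-metric with a logged reason, not imputed.

**Rediscretization** resamples a polyline at a constant chord length
`p`: from the current anchor, the next point is the first intersection,
walking forward, of the polyline with the circle of radius `p` centred on
the anchor (chord-based construction; an arc-length variant would be a
deliberate alternative, not an accident of implementation). `p` is in
coordinate (pixel) units, with defaults 10 and 20. Numerics: the
"reached the circle" test tolerates 1e-9 relative so that a path already
sampled at constant step `p` is returned vertex-for-vertex — without the
tolerance, 1-ulp noise in large coordinates makes the walker cut corners
and inflates the apparent turn concentration. Chord lengths are constant
to better than 1e-9·p; agreement with an independent dense-resampling
oracle is tested at 1e-6·p.

**Sinuosity** uses the tortuosity estimator

    S = 2 [ p ((1 + c)/(1 − c) + b²) ]^(−1/2)

with `c` the mean cosine of turning angles of the rediscretized path and
`b` its step-length coefficient of variation (identically 0 after
rediscretization, and clamped to exactly 0 when chords are constant to
1e-9 relative). Limits: `c → 1` returns 0 (straight path); `c = −1` with
`b = 0` is a degenerate path and is signalled, not silently patched.
Replicate sinuosity is the unweighted mean over tracks with a defined
estimate — the estimator is scale-free per track, so duration weighting
would only import nuisance variation. Turning angles are signed heading
changes wrapped to (−π, π].

Estimates at p = 10 and p = 20 agree within a few percent on paths that
are well resolved at both scales (sampling step well below `p`); when the
sampling step equals `p` itself the p = 20 estimate compounds pairs of
turns and sits systematically lower — the package therefore reports each
`p` separately rather than averaging them.

**Edge affinity** is the proportion of detections (pooled over tracks,
not averaged per track — the population-level reading again) within a
physical margin (default 10 mm, converted through mm-per-pixel) of the
arena boundary, the boundary being the min/max coordinate extremes of the
whole recording. Degenerate extents (a single detection, a collinear
axis) make the metric undefined. Because the boundary is the axis-aligned
extent of the data, the metric's exact symmetry group is the set of rigid
motions preserving axis-aligned boxes (translations, quarter-turn
rotations, axis reflections); path rate and sinuosity are invariant under
all rigid motions, and path rate scales linearly, sinuosity as s^(−1/2),
under spatial scaling by s. All of these are property-tested.

**Ground-truthing** of a tracker against human-annotated clips is a
Pearson correlation with a Fisher-z 95% CI (no finite CI at n = 3).

## Assay scoring

Dispersal propensity is scored at the line level as the mean number of
realised dispersals per individual out of three opportunities, because
density dependence makes individual events non-independent; tallies over
the classes {0,1,2,3} are validated to sum to the population size.
Individuals at 3/3 are the dispersive phenotype, 0/3 non-dispersive,
intermediates discarded where classes are needed. Surface-affinity counts
are carried as stated minima (animals obscured by the medium are missed);
no correction model is applied and the caveat travels with the result
type. The one-generation selection response compares offspring of
surface- vs sub-surface-collected parents as a class difference in mean
proportion plus the fixed-effect contrast from a proportion ~ parent
class model with a block random intercept when blocks exist.

## Morphometrics

Repeatability is Spearman's rank correlation (midranks for ties) between
first and repeat measurements paired by individual; traits below a
retention threshold are flagged for exclusion. The threshold defaults to
0.9 — retained traits in this kind of screen are "highly repeatable"
(ρ ≳ 0.95) while the first tarsus segment sits far lower (ρ ≈ 0.7), so
any cutoff in a wide band separates them identically; 0.9 is configurable.

The body-size axis is PCA on the trait **correlation** matrix
(standardized traits, eigen-decomposition; equivalent to R's
`prcomp(..., scale.=TRUE)`), on complete cases only, since the
decomposition cannot handle missing values. PC1's sign is fixed so its
loadings sum positive: eigenvector signs are arbitrary, and with all
traits loading on a common size factor this convention makes larger
scores mean larger bodies, deterministically (rerunning on permuted rows
gives identical loadings and scores). Variance fractions are eigenvalues
over the trait count and sum to 1; the PC1 score variance equals the
leading eigenvalue. Leg length is femur + tibia (mm), undefined when
either part is missing; the relative-leg-length analysis uses PC1 as the
size covariate.

## Regime-comparison models

All eight standard analyses are Gaussian identity-link fits: fixed-only
designs by OLS, designs with random factors as linear mixed models by
REML. Proportions are modelled on the raw scale — a documented caveat,
not an endorsement: with proportions in the interior of (0,1) and
balanced designs the Gaussian fit is serviceable, but it is not a count
model. Random structure is independent intercepts only; multiple
(crossed) factors are handled as variance components under a single
all-encompassing group, the standard crossed-random-intercept device.
Singular fits (a variance component estimated at ~0) are retained and
flagged, with the solver's warnings recorded — the fixed-effect estimates
then coincide with the simpler model's.

Pairwise regime contrasts (low−high, low−control, high−control) are
linear combinations of the fitted coefficients, so they are exact for any
reference coding and need no refits; with an interaction in the model
they are simple contrasts at the reference level of the interacting
factor. Mixed-model p-values are Wald z; for the small line-level
designs these are mildly anti-conservative relative to
Satterthwaite-degree-of-freedom t tests, which is why the type-I
calibration is demonstrated on the one analysis fitted by OLS (exact t
p-values). The interaction-pruning rule drops *all* interaction terms and
refits only when every interaction's joint Wald p ≥ α (default 0.05);
α ≥ 1 prunes unconditionally (boundary semantics: nothing is significant
at level 1).

## Synthetic-data generator

The generator produces every pipeline input with known ground truth, at
the study's design sizes by default: populations of 10 beetles recorded
600 s at 25 fps; 16 high / 16 low / 12 control lines split over two
temporal blocks and 12 cameras (2 recordings per line by default, ≈ 88 —
the study tracked 110 clips without stating the per-line split);
dispersal and surface populations of 200; morphometrics of 15 beetles per
sex for lines 1–10 (high, low) and 1–6 (control), 780 individuals, with a
90-individual re-measurement subset.

Movement is a correlated random walk: heading increments ~ von Mises(0, κ),
step lengths ~ Gamma with configurable mean and CV, walls handled by
specular reflection (implemented as coordinate folding, which is exactly
the reflected path of the straight-line continuation). The real study
fits no movement model, so the CRW is a stand-in chosen for its known
moments: the mean turn cosine is the Bessel ratio I₁(κ)/I₀(κ), giving an
analytic plug-in sinuosity against which the estimator is validated
(median over 200 15,000-step κ = 1 tracks within 5%; observed ≈ 0.2%).
Thigmotaxis is not emergent from a CRW; an optional wall-following
probability (align heading with the nearest wall tangent while inside the
edge zone) is off by default and enabled modestly in the `paper_like`
scenario so edge zones are occupied above chance.

`paper_like` effect sizes mimic the published regime means: per-
opportunity dispersal probabilities 0.813 / 0.233 / 0.647 (3p = 2.44 /
0.70 / 1.94), speeds 129 / 111 / 125 px s⁻¹, surface proportions 0.785 /
0.290 / 0.496 (counts of 200), offspring surface shift 0.15, and
line-level jitters sized so simulated standard errors resemble the
published ones. The morphometric generator draws a latent size factor
z ~ N(regime + sex + line shifts, 1) and builds each trait as a common
loading on z plus trait noise and measurement error; the measurement
error SD is 0.176 of the between-individual trait SD for the four
reliable traits (repeatability ≈ 0.97) and 0.608 for the first tarsus
(≈ 0.73, mirroring why that trait is dropped). The loading (1.55 residual-SDs, communality ≈ 0.78) is set
so PC1 recovers the latent factor with correlation > 0.95 at the design's
sample sizes; the consequence is a simulated PC1 variance share of ≈ 0.82
rather than the ≈ 0.74 seen in the real data — faithful factor recovery
was prioritised over mimicking the variance share, and both numbers are
reported, not asserted. Femur values go missing completely at random at
rate 0.577 (≈ 330 complete cases of 780); the real missingness mechanism
(residual thorax tissue) is unknowable from the data and is *not* MCAR in
any verifiable sense — a stated approximation.

Determinism: one run seed spawns independent child streams per stage, so
identical seeds give byte-identical outputs and any stage is reproducible
alone. `null` sets every regime effect equal for calibration.

## Problem sizes in tests and the acceptance script

Unit and property tests run the generators at reduced durations and
track counts (seconds to minutes of simulated recording) — chosen as the
smallest sizes at which the tested expectation has comfortable
Monte-Carlo margin (3 SE unless the quantity is exact). The
sinuosity-recovery experiment runs at its stated scale (200 tracks of
15,000 steps). The acceptance script's end-to-end study uses 2 recordings
per line at 120 s; assays and morphometrics run at full design sizes. The
type-I calibration uses 500 null datasets, for a binomial 95% band of
0.031–0.069 around the nominal 0.05.

## What passing tests do and do not show

The synthetic generator reproduces the statistical *structure* the
analysis assumes — independent CRW movement, binomial assay counts, a
single latent size factor, MCAR missingness — with effect sizes at the
published values. Passing tests therefore show the estimators and models
are correct and calibrated under those assumptions. Real tracking data
violate several of them: identity swaps and detection dropouts, autocorrelated
measurement noise (which inflates apparent turning at small `p`),
thigmotaxis with structure richer than tangent-following, non-binomial
overdispersion of dispersal counts (a beta-binomial knob exists but
defaults off), and informative femur missingness. None of these failure
modes is exercised by the suite, and results on real exports should be
read with that in mind.

## Known limitations

* No identity-swap correction; metrics are deliberately population-level.
* Mixed-model p-values are Wald z (see above); variance-component CIs are
  not reported.
* Proportions and counts are modelled as Gaussian, as in the source
  analyses; a GLM family layer would be a natural extension.
* The CLI's `run` command always simulates; analysing real data end to
  end means running `metrics` / `score` / `morph` / `models` on your own
  CSVs, which the readers accept by design.
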