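# Methods

`arousalnet` implements a preoperative resting-state analysis linking
whole-brain network segregation and ascending-arousal (locus coeruleus,
LC; nucleus basalis of Meynert, nbM) connectivity to a binary
postoperative-delirium outcome.  Because the clinical fMRI/EEG/blood
data this kind of study uses are ethics-restricted, the package ships a
first-class synthetic cohort generator that reproduces the statistical
structure each stage assumes, so the complete pipeline is testable and
reproducible from nothing but a seed.

## Input data model

The pipeline consumes, per subject, a `T x N` parcel-averaged BOLD
matrix (default `T = 210` TRs of 2.6 s; `N = 402` = 400 cortical
parcels in 17 canonical networks plus the two nucleus columns `LC` and
`nbM`), a region-to-network partition table, unit-sphere parcel
centroids with hemisphere labels (needed only for spatial null tests),
per-subject group labels and covariates (EEG slow-wave delta-power
change; a pTau blood-biomarker surrogate), and a region x gene
expression matrix.  All files are plain TSV; readers validate strictly
and refuse rather than impute.

## Denoising

Post-preprocessing denoising is confound regression followed by
band-pass filtering.  Regression uses exactly the confound columns the
caller supplies (plus an intercept); derivative or quadratic expansion
is deliberately left to the caller, since published confound lists are
rarely exact about it.  The filter is a zero-phase forward-backward
Butterworth band-pass, order 2 per direction, 0.01-0.1 Hz by default.
With a 2.6 s TR the effective amplitude response keeps a 0.05 Hz
sinusoid within ~1.2% of its amplitude and attenuates 0.004 Hz or
0.19 Hz content by more than 95%.  Near the band edges the response
rolls off (as any finite-order filter must); the documented amplitude
contract applies to the mid-band.

## Dynamic connectivity (MTD)

Time-resolved coupling uses the multiplication of temporal derivatives:
first-difference each region's series, z-score the derivative series
over the whole run (population SD), multiply pairwise per derivative
sample, and smooth with a trailing moving average of `w = 5` TRs
(stride 1, frames indexed by window start, `W = T - w` frames).

Numerical conventions, chosen so the documented identities hold
exactly:

* derivatives are **centered** as well as scaled.  The derivative mean
  of a run is tiny (`(x_T - x_0)/(T-1)`), but centering makes the
  `w = 1` time-mean coupling equal the Pearson correlation of the
  derivative series to machine precision, which is the natural
  time-average interpretation of the statistic;
* the SD carries no window subscript: it is a whole-run constant;
* a region with zero derivative variance contributes coupling 0, with
  a warning;
* coupling is invariant to positive affine rescaling of any region's
  signal.

A seed-row variant computes one region's `W x N` coupling without
materialising the full `W x N x N` tensor; it equals the corresponding
rows of the full tensor exactly.

## Participation coefficient and brain states

For each coupling frame and region, the participation coefficient is
`B_i = 1 - sum_s (K_is / K_i)^2` over the module partition, using
positive weights only and excluding self-connections; zero positive
strength gives `B_i = 0`.  `B` lies in `[0, 1 - 1/n_M]`.  The default
partition is the fixed a-priori 17-network table; a seeded Louvain
partition of the positive static-connectivity graph is available as an
option (weighted Newman-Girvan modularity; a partition whose modularity
is not positive collapses to a single module with `Q = 0`, the
modularity of the trivial partition, since the graph is then
structureless).

Integrated vs segregated brain states come from k-means (`k = 2`,
k-means++ seeding, 100 restarts, Euclidean distance on raw PC values)
over stacked `(subject, frame)` rows of regional PC; the cluster with
the higher mean PC is "integrated".  A tie (never observed in
practice) resolves to the lower cluster index as segregated, with a
warning.  Occupancy is the fraction of a subject's frames labelled
segregated, averaged per group.

## Seed discriminant analysis

Seed coupling frames are concatenated across subjects and time
(frames inherit the subject's group), z-scored per column, and
separated with a two-class Fisher discriminant computed by
eigen-decomposition of the pooled within-class covariance with
shrinkage toward its diagonal.  The shrinkage intensity is chosen
analytically (Ledoit-Wolf) unless given; shrinkage is needed because
stacked frames are numerous but serially correlated, so the nominal
sample size flatters the covariance estimate.  Class priors are
balanced at (0.5, 0.5) regardless of group sizes, and the axis is
oriented so the delirious class mean score is positive.  With
shrinkage 0 on well-conditioned data the axis equals the closed-form
`S_w^{-1}(mu_1 - mu_0)` direction.

The top `ceil(0.05 x frames)` frames by |score| are the maximally
discriminating time points (ties break toward earlier frames); the
group contrast map is the delirious-minus-non-delirious mean seed
coupling over those frames.  If one group is absent from the selection
the contrast falls back to that group's full-run mean and the result is
flagged.

## Phasic peaks and peak-locked profiles

Phasic events in a nucleus BOLD series are samples at or above the run
mean plus 2 SD (whole-run moments), excluding the first and last 10
TRs, with candidates closer than 10 TRs resolved in favour of the
larger value (earlier index on ties).  The peak-locked profile is the
mean of the z-scored global (region-mean) PC trace at TR lags -5..+5
around the peaks; peaks whose lagged index leaves the run are skipped
for that lag, and constant traces or empty peak sets yield a flagged
zero profile.  BOLD peak indices map onto the coupling-frame axis by
subtracting the first-difference offset of 1 (window-start indexing
absorbs the rest); this convention is pinned by a planted-lag test.
Per-lag group differences use a Welch t statistic with a two-sided
permutation p-value from group-label shuffles (add-one convention).

"Cross-correlation" is operationalised as peak-triggered averaging —
the minimal statistic consistent with locking a window of +/-5 TRs to
each peak; z-scoring the trace makes the profile invariant to affine
rescaling of the PC.

## Group inference

Edge-wise group differences use Welch t per edge with a permutation
null (default 1000 shuffles), vectorised via permutation-indicator
matrix products and chunked over permutations so the full 402-region
problem (~81k edges) stays within a laptop's memory.  Welch rather
than pooled t because group sizes need not be equal.  Optional
family-wise control uses the permutation distribution of the maximum
|t| across edges; pointwise p-values are the default and outputs say
which was used.

Outcome models are binomial GLMs fitted by IRLS: delirium ~ predictor,
~ covariate, ~ both, ~ both plus product.  Predictor and covariate are
standardized first (coefficients are per SD; the raw scales mix PC in
[0,1] with dB units).  Zero-variance terms are dropped with a flag, so
an all-zero predictor/covariate pair degrades to the intercept-only
model (log-likelihood `n ln 0.5` for balanced outcomes).  Perfect
separation is flagged, never reported as a valid fit.  Models are
ranked by AIC (`-2 loglik + 2k`, re-verified on every fit), comparable
only across identical subject sets.

## Gene-expression association

Per gene: outlier-robust scaled-sigmoid normalisation
(`sigmoid((x - median)/(IQR/1.35))`, min-max rescaled, then z-scored
across regions); the IQR/1.35 scale matches a normal SD so moderate
values map almost linearly while outliers saturate.  PCA of the
z-scored panel keeps the smallest k with cumulative explained variance
>= 80% (eigenvalues of the population covariance of z-scored columns,
so they sum to the gene count); component signs are fixed by making
each loading vector's largest-|value| entry positive.

Component score maps are correlated with the regional mean-PC map
(Spearman by default — both offered and the choice recorded) against a
spin null: uniformly random 3-D rotations applied to right-hemisphere
centroids and x-mirrored to the left, with rotated centroids matched
back to originals by optimal (Hungarian) assignment per hemisphere.
Assignment rather than greedy nearest-centroid guarantees the
reassignment is a bijection.  The null is well calibrated when parcels
are dense relative to the map smoothness (at 400 parcels and a 0.6 rad
length-scale, nominal 5%); very sparse grids make the bijective
reassignment slightly liberal because the local shuffle erodes the
null maps' autocorrelation.  p-values use the add-one convention, and
Benjamini-Hochberg FDR is applied across components.

Dependent correlations (components share the PC map) are compared
pairwise with Williams' t (`df = n - 3`); with k = 8 retained
components that is 28 comparisons, FDR-corrected.  Effect sizes are
classed negligible/small/medium/large at |r| = 0.1/0.3/0.5.

The default 24-symbol cholinergic panel covers nicotinic subunits
(CHRNA1-7, CHRNB1-4), muscarinic receptors (CHRM1-5), synthesis and
transport (CHAT, SLC18A3, SLC5A7, SLC44A1/2/5) and degradation enzymes
(ACHE, BCHE); it is user-editable.

## The synthetic cohort

`CohortConfig` defaults define the study conditions: 60 delirious + 60
non-delirious subjects, 210 TRs of 2.6 s, 400 parcels in 17 networks
plus LC and nbM.  Per subject, the series is multivariate normal with a
block covariance — within-module correlation 0.35, between-module 0.12
in controls and 0.06 in the delirious group (plants segregation) —
repaired to the nearest PSD matrix by eigenvalue clipping when the
planted shifts break positive-definiteness.  The between-module
coupling is additionally jittered per subject (SD 0.06): without that
heterogeneity every subject's measured global PC sits essentially at
its deterministic group value, the groups separate perfectly and the
outcome-model stage degenerates.  The default jitter makes the group
PC distributions overlap the way real cohorts do (full-scale Cohen's
d ≈ 0.7, group difference ≈ 0.005 against a subject SD several times
larger) while keeping the group test's power above the generator's
0.8 contract at n = 120.  Nucleus columns couple to
cortex at baseline r = 0.10; in the delirious group the nbM row gains
+0.15 on the 30 most posterior parcels and the LC row loses 0.15 on
the 30 most anterior parcels (cholinergic hyper-, noradrenergic
hypo-connectivity).  A Poisson number (mean 8 per run) of phasic bursts
— half-cosine bumps, 3 TRs wide, amplitude 4 x noise SD so the 2-SD
detector finds them reliably — is added to each nucleus column; one TR
after each LC burst a shared global signal is injected into all
cortical columns (raises between-module coupling, hence integration),
and after each nbM burst module-confined signals with independent
random signs (raise within-module coupling, hence segregation).

The outcome is generated against the subject's *measured* segregation,
not the planted parameter, so downstream recovery is honest: the
summary is the global PC of the subject's time-averaged coupling
matrix (equal to the correlation matrix of the derivative series; this
avoids building the ~265 MB full coupling tensor inside the generator,
and is the time-average of the same statistic the pipeline resolves in
time).  The covariate is drawn conditionally on group and measured PC
(`C = (2D-1) * (beta/2) * z(PC) + N(0,1)`), which makes the conditional
law of the outcome given (PC, C) exactly logistic with interaction
coefficient `beta` on `z(PC) x C` — so the interaction stage recovers a
known truth.  The default `beta = -1.5` (PC falls and slow-wave change
rises together with delirium risk) is the weakest value at which the
AIC model-selection stage picks the interaction model in at least 90%
of cohorts at n = 120 — the package's own power target, since no
real-cohort effect size exists to copy.  The pTau
surrogate is mean nbM connectivity plus noise (planting the positive
biomarker correlation).

Gene maps are Gaussian-process draws over geodesic distance between
centroids (squared-exponential kernel, eigen-clipped square root) plus
white noise, with an optional anterior-posterior gradient shared by a
gene subset.  Centroids are a Fibonacci lattice folded onto the right
hemisphere, mirrored to the left, and rotated about the x-axis by a
seed-dependent angle.

What the generator does **not** emulate: scanner artifacts, head
motion, multi-site effects, hemodynamic convolution, heavy-tailed BOLD
noise, anatomical geometry (a sphere stands in for the cortical
sheet), and transcriptomic covariance structure beyond smooth spatial
fields.  Passing tests therefore demonstrate the correctness and
calibration of the statistics, not clinical validity on real data.

## Problem sizes used in tests

Unit tests run on reduced cohorts (typically 40-60 regions, 60-80 TRs,
6-16 subjects) chosen so every planted effect is still comfortably
detectable; the calibration checks pool hundreds of reduced
replicates; the end-to-end smoke test runs the full default cohort
(120 subjects, 210 x 402) through every stage with the production
permutation counts (1000).  These sizes are the package's own test
design and are stated here so results are interpretable.

## Known limitations

* The bijective spin reassignment is slightly anticonservative on
  sparse parcel sets (see above); use dense parcellations or interpret
  borderline spin p-values cautiously.
* The eigen-mode LDA is descriptive, as in the analysis it implements:
  no cross-validated accuracy is claimed, and in-sample scores on
  over-parameterised stacks are optimistic by construction.
* Louvain on near-structureless graphs is resolution-dependent;
  the fixed a-priori partition is the default for exactly that reason.
* Permutation p-values are bounded below by `1/(n_perm + 1)`; FDR on
  1000-permutation p-values therefore saturates at small counts.
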