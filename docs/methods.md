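# Methods

`bbbmri` re-implements, as a tested pipeline, a semi-automated workflow for
quantifying abnormal brain tissue (ABT) and blood–brain-barrier dysfunction
(BBBD) on multimodal MRI of neurocritical-care patients, together with the
electrocorticography (ECoG) burden metrics and the prognostic statistics
built on top of those quantities.  Raw clinical studies of this kind are not
publicly distributable, so every stage is exercised on synthetic head
phantoms and synthetic cohorts with known ground truth; this note records the
models, the defaults and the design decisions, and states explicitly what
the synthetic data do and do not establish.

## Tissue segmentation model

A study comprises co-registered T1w, DWI and FLAIR volumes restricted to a
skull-peeled volume of interest (VOI), the union of the grey-matter (GM),
white-matter (WM) and CSF probability maps thresholded at 0.5 with the
largest connected component kept.

**Z-score space.** Each image is standardised over the VOI,
`z = (I − μ)/σ`.  For patient FLAIR the estimation of μ/σ discards the top
λ = 3% of intensities (large hyperintense lesions would otherwise inflate
both), but the transform is applied to *every* VOI voxel — trimming affects
estimation only.  Controls are lesion-free by construction and use λ = 0.

**Outlier initialisation.** Templates are the voxelwise mean and unbiased
(n−1) variance of the z-scored images of 21 healthy controls, variance
floored at 10⁻⁶ so distances stay finite.  The per-modality distance
`d_m(v) = |z(v) − mean_m(v)| / sqrt(var_m(v))` is a one-dimensional
Mahalanobis distance: the template covariance is estimated per modality
across control subjects, so nothing couples modalities at this stage (a
deliberate reading; the multimodal coupling happens later in the mixture
model).  A voxel seeds the candidate lesion when `d_m ≥ 3` in *any*
modality.  The candidate set is split by k-means (k = 2) on DWI intensities
into DWI-hyperintense and iso-/hypointense classes; initial centroids are
the minimum and maximum intensity, making the split deterministic, and the
degenerate case (< 2 distinct values) collapses to the iso class with a
warning.

**Mixture segmentation.** The feature matrix (one row per VOI voxel, one
column per modality, columns re-standardised) is projected by PCA; components
explaining ≥ 5% of total variance are retained (always ≥ 1).  A K = 5
Gaussian mixture (GM, WM, CSF, two ABT classes) is initialised from the
label statistics and refined by EM with full covariances regularised by
10⁻⁶·I, until the relative log-likelihood change falls below 10⁻⁶ or 100
iterations.  The log-likelihood is recorded per iteration and is asserted
non-decreasing in the tests.  Voxels take the maximum-posterior class, ties
broken to the lowest class index.

If the outlier stage yields too few voxels to estimate two lesion-class
covariances (fewer than M+1 per class), the study is reported lesion-free
instead of erroring: there is nothing abnormal for the mixture to model.
This is the pipeline-level behaviour; `em_gmm` itself still rejects an
under-populated class so the invariant is visible at the unit level.

**Spatial refinement.** The ABT object (classes 4 ∪ 5) is grown into
8-connected in-slice neighbours currently labelled GM/WM/CSF when any of
three posterior criteria holds: `max γ − γ₄ < 0.1`, `max γ − γ₅ < 0.1`, or
`γ₄ + γ₅ ≥ 0.5` (the sum bound is inclusive, the gap bounds strict).  Grown
voxels take the ABT class with the larger posterior.  Updates are synchronous
per sweep, so the fixed point is independent of voxel order; growth is
monotone and bounded by the VOI, hence terminates.  Morphological polish
then (1) deletes 3-D 26-connected components below 3 mm³ of physical volume,
(2) applies slice-wise closing with a 2-pixel disc, and (3) slice-wise fills
enclosed non-ABT regions below 16 mm².  "8-connected" is read as
two-dimensional within axial slices throughout, consistent with the
slice-wise morphology; only the small-component filter is 3-D because its
threshold is a physical volume.  The final object is re-split by DWI k-means
into hyperintense versus iso-/normointense parts.

## BBBD mapping

Relative enhancement is `E = (post − pre)/pre` on voxels with positive
pre-contrast signal (the single place the enhancement definition lives, so
alternatives can be swapped in).  Three reference regions calibrate the
thresholds: the mid-vitreous body (non-enhancing), temporal muscle
(physiologically enhancing) and a venous-sinus blood ROI (tracer-rich).
Gaussians are fitted to each ROI's enhancement histogram by least squares on
Freedman–Diaconis bins, initialised at and falling back to sample moments.
τ₁ is the density intersection of vitreous and muscle, τ₂ of muscle and
vessel — always the root strictly between the two means (equal SDs give the
midpoint).  Seed voxels satisfy τ₁ ≤ E ≤ τ₂ (inclusive); slice-wise
8-connected clusters under 4 voxels are removed; the object is then grown
into the expanded band 0.5τ₁ ≤ E ≤ 1.5τ₂ through 8-connected neighbours to a
fixed point.  The final map re-assigns each BBBD voxel its enhancement,
min–max normalised to 0–1 over the mask.

## Compartments and vicinity rings

The intracranial volume (ICV) is partitioned into normal brain tissue (NBT =
GM ∪ WM), ABT and CSF; NBT and ABT are each split by the BBBD mask, giving
the five percentages NBT_iBBB%, NBT_BBBD%, ABT_iBBB%, ABT_BBBD% and CSF%,
which sum to 100 by construction.  For the vicinity analysis each NBT voxel
receives its Euclidean distance in physical mm (anisotropy respected) to the
nearest ABT voxel — distance to the ABT *set*, which equals distance to the
ABT edge for voxels outside the object — and is binned into half-open,
lower-inclusive rings [0,1), [1,2), [2,3) cm.  Per zone (ABT plus three
rings) the tissue volume, BBBD volume and BBBD fraction are reported.

## ECoG burden metrics

Annotated events are reduced to daily totals: TDDD (total
spreading-depolarisation-induced depression duration per day, minutes) and
the SD count, TSDD (total electrographic-seizure duration) and the seizure
count.  Day 0 is the first 24 h after the initial haemorrhage
(`day = floor(hours/24)`); an event belongs wholly to its onset day — no
midnight splitting, since annotation conventions do not define one.  Peaks
(PTDDD, peak_SD, PTSDD, peak_seizure) are maxima over *recorded* days, taken
from an explicit recording interval so unmonitored days are excluded rather
than counted as zero.  The validator enforces what annotations can express:
seizures must last ≥ 10 s (the definitional minimum), durations and onsets
must be non-negative; waveform-level detection is out of scope.

## Prognostic statistics

Binary logistic models are fitted by maximum likelihood (statsmodels), with
Wald z² tests per coefficient and 95% CIs `exp(β ± 1.96·SE)`.  Separation is
detected (diverged coefficients or exploding standard errors) and reported
as a non-converged result rather than an exception, mirroring how clinical
tables mark such rows.  Univariate screens over the 15-predictor panel use
Bonferroni correction at α/15 with an inclusive cutoff.  Forward selection
enters the candidate with the smallest Rao score-test p-value while it is
below p_in = 0.05 and prunes included variables whose Wald p exceeds
p_out = 0.10 — score entry and Wald removal being the convention of the
major clinical statistics packages; ties break by panel order, cycles
(possible under separation) terminate the loop, and separated fits skip
Wald pruning because those p-values are meaningless.

Missing predictors are handled by chained-equations multiple imputation:
continuous columns are imputed by normal linear draws with parameter
uncertainty, binary columns by Bernoulli draws from a logistic fit, five
sweeps per imputation, 500 imputations by default (analyses here use 20, a
deliberate scale-down with the default preserved in config).  WFNS and RMS
must be complete — they anchor the missing-at-random assumption and enter
every conditional model.  With no missing values the imputed tables are
bit-identical copies of the input.  Coefficients pool by Rubin's rules;
leave-one-out probabilities pool as the per-patient mean across imputations.

The leave-one-out AUC holds each patient out in turn, imputes the fold
(training rows plus the held-out predictors, never the held-out outcome),
runs forward selection and the logistic fit per completed table, and stores
the averaged held-out probability; an empty selection yields the
intercept-only event rate.  The AUC over stored probabilities carries a 95%
CI from the DeLong variance (config-switchable to Hanley–McNeil); the AUC
itself is the Mann–Whitney statistic, hence invariant under monotone
transforms of the probabilities.

Descriptive tests: Pearson χ² on 2×2 tables without continuity correction;
two-sided Mann–Whitney (exact for tie-free samples up to n = 20, otherwise
tie-corrected normal approximation); Spearman rank correlation with tie
handling.  The detectable effect size for a two-sided two-sample t-test is
the smallest Cohen's d whose exact noncentral-t power (noncentrality
`d·sqrt(n₁n₂/(n₁+n₂))`, df `n₁+n₂−2`) reaches the target, found by
bisection; underflow of the noncentral-t tail at extreme noncentrality is
treated as power 1.  Published power values for this design vary with the
approximation convention, so only the package's own convention is asserted.

## Synthetic data: what it emulates and what it does not

**Phantom.** The head is an ellipsoid (semi-axes 55 × 58 × 52 mm) of CSF
rim, GM shell and WM core with a central ventricular CSF space, on a default
64 × 64 × 24 grid at 2 × 2 × 5 mm — thick-slice clinical geometry at desk
scale.  Class mean intensities (arbitrary units) follow the qualitative
clinical ordering: CSF dark on T1w/FLAIR, WM brightest on T1w, lesions
hyperintense on FLAIR, DWI-hyperintense lesions bright on DWI while iso
lesions match WM.  Noise is additive Gaussian, SD 3 per modality (≈ 10–15%
of inter-class contrast).  Lesions and leakage regions are ellipsoidal blobs
overwriting the anatomy (later blob wins on overlap, logged).  The default
lesion is a single 10-mm-radius DWI-hyperintense blob; the default leakage
amplitude sits midway between the analytic τ₁ and τ₂ of the reference ROIs
(vitreous N(0.02, 0.01), muscle N(0.15, 0.03), vessel N(0.60, 0.08) —
ordered as real tissue enhancement must be).  Reference ROIs are 7-mm
spheres outside the brain ellipsoid, as they would be drawn on real scans.
A master seed spawns per-subject and per-stage child generators via
`numpy.random.SeedSequence`, so every generator is reproducible and
insensitive to cohort ordering.

The phantom deliberately omits bias fields, partial-volume mixing beyond
discretisation, motion, anatomy-dependent texture and multi-scanner
harmonisation.  Consequently the phantom Dice (≥ 0.98 at default noise) is
an upper bound on clinical performance and validates the *algorithmic*
chain — standardisation, outlier seeding, EM labelling, growing, morphology —
not robustness to real-world artefacts.  Control-template demographics
(age/sex structure) are likewise not modelled: templates differ from
patients only by noise and pathology.

**Cohorts.** The 15-predictor panel mirrors the clinical variable set
(initial severity scores WFNS and RMS, four compartment percentages per MRI
time point, four ECoG burden metrics, post-monitoring Modified Rankin
Scale).  Marginal distributions are chosen to resemble the published
summary statistics (e.g. PTDDD gamma with median ≈ 100 min, seizure metrics
zero-inflated).  The outcome follows a logistic model whose only nonzero
slope, 0.737 per percentage point on post-monitoring ABT_BBBD%, matches the
reported primary-analysis coefficient, with the intercept set for a ≈ 40%
event rate; the generating coefficients ride along in `attrs` for recovery
tests, and the attainable AUC of the generating model is computed by
large-sample Monte Carlo.  Missingness is missing-at-random conditional on
the complete WFNS and RMS: the marginal per-variable rates (≈ 12% early-MRI,
≈ 5% post-monitoring MRI, 3–4% ECoG/MRS) are tilted multiplicatively by
`exp(0.4·(z_WFNS + z_RMS))`, so sicker patients lose more data.

**ECoG streams.** Poisson events per recording day (defaults: 4 SDs/day,
0.2 seizures/day, near the published per-patient averages), depression
durations gamma(2, 7.5) min, seizure durations 10 s plus an exponential
tail.

## Problem sizes used in the checks

The shipped analyses run at sizes chosen to make each property measurable
with comfortable margins on a single CPU: one 64 × 64 × 24 phantom
(≈ 35 000 VOI voxels) for segmentation and BBBD recovery; 10⁴ draws per ROI
for threshold recovery; 50 seeded three-component fits for EM monotonicity;
brute-force oracle grids up to 20³ for region growing and distance rings;
100 replicates at n = 1000 for coefficient recovery; and a 200-patient
cohort with 20 imputations per fold for the leave-one-out AUC.

## Known limitations

- The per-modality Mahalanobis reading means cross-modality covariance is
  exploited only inside the mixture model, not during outlier seeding.
- The histogram Gaussian fit assumes approximately unimodal ROI enhancement;
  strongly bimodal ROIs fall back to moment estimates (documented, tested).
- Imputation draws from approximate posterior covariances (diagonal for the
  logistic case); adequate for the pooling performed here, not a general
  Bayesian imputation engine.
- The stepwise selection procedure inherits the known instabilities of
  stepwise methods; it is implemented because the downstream leave-one-out
  analysis is defined in terms of it.
- Clinical effect estimates from the original cohort (odds ratios, AUC CIs)
  depend on non-public patient data and are not reproduced here; the
  statistics layer is validated by recovery on synthetic cohorts instead.
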