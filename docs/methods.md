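# Methods

This note documents the models implemented in `mmnds`, the parameters that
matter, what the synthetic cohort does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Coordinate conventions

World coordinates are MNI-style RAS millimeters; `GridSpec.origin_mm` is
the world position of the *center* of voxel (0,0,0) and
`world = origin + index · voxel_size`. A world point maps to the voxel with
the nearest center, ties broken toward the lower index, so published
coordinates land on reproducible voxels. `mni_grid(v)` tiles the standard
MNI bounding box (x −90…90, y −126…90, z −72…108 mm): 181×217×181 at 1 mm,
61×73×61 at 3 mm. NIfTI I/O accepts only diagonal-plus-translation affines
with positive steps — the pipeline operates strictly in an
already-normalized template space, and nonlinear registration is out of
scope.

## Quantification

**PET.** `SUV = activity/(dose/weight)`; `SUVR = SUV / mean_brain(SUV)`,
so dose, weight and any scanner gain cancel and the in-mask SUVR mean is
exactly 1. The whole-brain mask is a threshold at 0.35 × the mean of
positive voxels of the smoothed SUV image — a convention chosen for
artifact-free template-space data, not a published rule; the fraction is a
parameter.

**ASL.** The single-compartment pCASL consensus model with labeling
duration τ = 1.5 s (the protocol's RF-train length), labeling efficiency
α = 0.85, blood T1 = 1.65 s, partition coefficient λ = 0.9 mL/g, optional
background-suppression factor (default 1). All constants live in
`ASLQuantParams`; rCBF (normalization to the whole-brain mean) is invariant
to every one of them except through the PLD-dependent exponential.
Label/control pairs are averaged per PLD before subtraction (equivalent to
pairwise subtraction by linearity; surround subtraction is not
implemented), the M0 image is smoothed with the same 8 mm kernel before
division to stabilize low-signal voxels (switchable), and the three per-PLD
rCBF maps are averaged with equal weights, matching the equal pair counts
per PLD.

**DTI.** Log-linear least squares per voxel, `ln S = ln s0 − b gᵀDg`, via a
pinned pseudo-inverse of the 7-column design matrix; voxels with any
non-positive signal are skipped (NaN). Negative eigenvalues are clamped to
zero (count logged) rather than reflected, which keeps FA ≤ 1 provable. FA
uses the standard closed form and returns 0 for all-zero triples.

**Age correction.** FA declines with age, so corrected maps are
`FA + s·(age − age_ref)` with a single global slope estimated by regressing
in-mask mean FA on age in the SCD control-analogue group. With only a
handful of controls the OLS slope is noise; because age and diagnosis are
strongly confounded in dementia cohorts, an unstable slope would propagate
into every FA feature as a spurious group signal (observed as near-perfect
null-cohort classification before the safeguard). The slope is therefore
applied only when |slope| ≥ 2 standard errors, otherwise the correction is
the identity. Voxel-wise slopes are intentionally not implemented.

**Processing order.** quantify → normalize (SUVR/rCBF) → smooth 8 mm;
FA: fit → FA → smooth → age-correct. Smoothing after the ratio keeps the
normalization reference sharp; the order is configurable only by composing
the primitives.

## Whole-brain statistics

Per-voxel two-sample t (Student default, Welch available), with exact
handling of degenerate voxels (zero variance in both groups → t = 0,
p = 1). Voxels non-finite in any subject are excluded and do not count
toward the FDR family. FDR is Benjamini–Hochberg at α = 0.05
(Benjamini–Yekutieli behind a flag); the cluster filter removes connected
components smaller than 256 mm³ — stated in voxels on a 1 mm grid in the
reference protocol and converted through the voxel volume here, so the
criterion is grid-independent. Face connectivity (6) is the default since
the threshold is motivated by the smoothing-kernel scale; 18/26 are
options. Under a global null (smoothed-noise groups), the chain shows any
surviving voxel in ≤ 10 % of seeds — BH's level plus a margin for
smoothing-induced dependence — verified over 100 seeds in the tests.

## ROI features

Sphere membership is voxel-center Euclidean distance ≤ radius (inclusive);
the rule is documented because "spherical" alone does not fix boundary
behavior, and the inclusive rule makes counts and reflection symmetry
exact. On the 1 mm grid the 30 mm sphere matches brute-force lattice
enumeration and is within 1.5 % of the continuous volume. FA averages use
only voxels with FA strictly > 0.2; an ROI where no voxel qualifies is an
explicit missing value and excludes the subject from that syndrome's
classifier (logged), never a silent zero. Bilateral loci stay separate
features — that is what makes the per-syndrome dimensionalities land at
AD 5, bvFTD 5, svPPA 5, nfvPPA 3, lvPPA 3. The svPPA perfusion locus is
left-only in the published table and is taken verbatim, without
symmetrization.

## Classification

Features are standardized with training-set statistics only (leakage-free
A2). The SVM is a scalar-product-kernel soft-margin machine; the slack
penalty weights the **mean** hinge loss (per-sample C = regularization/n),
so the fit depends on the empirical distribution rather than the sample
count and is invariant to duplicating the data — the per-sample convention
is not. Default regularization 1.0; no value is published for the
reference analysis. A decision value of exactly 0 predicts the negative
class, which favors specificity, consistent with A1's objective.

**A1.** Intercept tuning searches the midpoints between consecutive sorted
decision values (finite, brute-force verifiable): maximize training
specificity subject to training sensitivity ≥ 0.5, ties broken toward
higher sensitivity. When 100 % specificity is unreachable under the
constraint the best attainable operating point is used with a warning —
the reference cohort shows the same behavior in a minority of separations.
The "vs SCD" confusion is the tuned hyperplane on its own training set
(the protocol's SCD comparison *is* the training step); "vs all" applies
the frozen hyperplane to syndrome vs all remaining subjects including SCD.
Under a null cohort the protocol's pooled vs-all accuracy does **not**
converge to the majority-class rate: training subjects are re-scored and
the sensitivity floor holds ≥ 50 % of them above threshold by
construction. The tests therefore check the exchangeability property that
does hold (held-out groups are accepted at the same rate as fresh draws
from the same distribution).

**A2.** Per run: stratified split (round-half-up of the 70 % share per
class), plain SVM, confusions on the training set, the validation set, and
— as the "summary" — the pooled predictions over all subjects of the run.
The reference tables' summary-row semantics are not defined precisely;
pooled train+validation is the implemented reading. Runs that empty a
class are skipped (error if > 5 %). Aggregates are means ± SD over runs in
percent. Note the run-to-run SD measures split noise only, not
cohort-level sampling variability.

**Categorization.** Each subject is offered to every syndrome's A1
model; correct means the clinical label is among the accepting models
(SCD: no model accepts). `C` is the percentage of correct subjects.

## Published-table arithmetic

Printed accuracy cells are rounded percentages of integer confusion
counts, so each cell is recoverable from its printed
sensitivity/specificity and the group sizes:
`tp = round(sens·n_pos)`, `tn = round(spec·n_neg)` (round half up),
`acc = (tp+tn)/(n_pos+n_neg)`. All 30 cells reconstruct exactly at the
printed precision; `accuracy·N = tp + tn` holds as integer arithmetic.
Caption averages are unweighted five-syndrome means; one published average
(MRI-only vs SCD) prints 87.1 while its cells average to 87.2, a rounding
inconsistency in the source table, which is why the caption-average check
runs at one-printed-decimal tolerance. The published per-syndrome
accuracies themselves are **not** simulation targets: the synthetic
effect sizes are free parameters with no published physical magnitudes.

## Synthetic cohort

The generator emulates study *conditions*, not anatomy. Baselines are
smooth soft-ellipsoid phantoms (brain and an inner white-matter region)
carrying SUVR-, CBF- and FA-like values; raw data are produced by the exact
forward models the quantification stage inverts (PET scaling by
dose/weight; ΔM from the consensus ASL model, 12 label/control pairs per
PLD; DWI signals from axially symmetric SPD tensors over a seeded
electrostatic-repulsion 64-direction scheme, b = 1000 s/mm², Gaussian noise
with a Rician option). Noiseless round-trips are identities to machine
precision, which pins the quantification code to the simulators.

Per subject and modality the truth field is
`baseline + Σ_ROI β·bump_ROI`, where `bump_ROI` is a Gaussian profile
(default FWHM 40 mm) at a catalog locus, normalized so its mean over the
ROI sphere is 1. β combines (i) a heterogeneity draw N(0, sd_mod) present
in *every* group at *every* catalog locus — local rather than global,
because whole-brain intensity normalization cancels global components
exactly — and (ii) for lesioned groups, a reduction of
`effect_size_sd · sd_mod · severity`, with per-subject severity
N(1, 0.4). The sphere-mean normalization makes the injected effect
directly comparable to the ROI features downstream, so effect-size
recovery is well defined; between-subject SDs default to 0.05 SUVR,
2.5 mL/100g/min, 0.03 FA. Where catalog loci of different syndromes
overlap (the AD and lvPPA inferior-parietal spheres are ~5 mm apart),
feature variances add — deliberate, as co-varying anatomy, and the reason
parameter-recovery checks use an isolated locus. MMSE is drawn from the
reference group means/SDs minus `slope·effect·(severity−1)` (slope default
6 points per SD), clipped to [0, 30], with per-group missingness matching
the reference completion fractions; ages are truncated normals at the
reference means/SDs. Demographics, latent fields and noise all derive from
one master seed through per-subject `SeedSequence` children, so any
subject regenerates bit-identically in isolation.

What the generator does **not** model: anatomical atlases, partial-volume
effects, motion or susceptibility artifacts, arterial-transit-time
variation, scanner physics. Passing tests therefore certify the analysis
chain's arithmetic, invariances, error control and parameter recovery
under these idealized conditions — not clinical performance on real data.

## Problem sizes and runtime

The demonstration configuration runs the six reference group sizes
(76 subjects) on the 3 mm MNI grid with 2 SD effects; it completes in
about 6–8 minutes on one CPU, and the Monte Carlo protocol uses 100–200
runs in demonstrations (1000 remains the library default). Unit and
property tests run on 8³–24³ grids; the null false-positive control uses
100 seeds of 40 smoothed-noise maps on a 24³ grid; effect-size recovery
uses 26-subject cohorts on the 6 mm grid with 200 Monte Carlo runs per
effect size. These sizes are the package's own demonstration choices;
every stage accepts full-resolution inputs.

## Known limitations

- The cluster filter is pure component-size thresholding; the reference
  software's exact "spatial correlation algorithm" is unpublished.
- The FDR variant (BH) and the whole-brain-mask construction are
  reasonable readings of an underspecified protocol, both configurable.
- A2 summary-row semantics are an interpretation (see above); the
  published summary SDs are sometimes smaller than both components, which
  pooled re-evaluation does not reproduce.
- The Holm family for MMSE correlations is per syndrome (its feature
  set); per-modality or global families are configurable choices left to
  the caller.
- Single-compartment ASL quantification only; no multi-compartment or
  transit-time-resolved modelling, no tractography, no diffusivity
  metrics beyond FA.
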