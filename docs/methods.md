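# Methods

`asymtraj` implements a longitudinal biomarker-staging analysis built around
contralateral neuroanatomical asymmetry.  This note documents the models,
the numerical choices, and what the synthetic study conditions do and do not
establish.

## 1. Asymmetry features

Input is a 3D integer label map (NIfTI) in an 83-region anatomical scheme
with 40 left/right region pairs (the packaged default pair table follows the
Hammers-style numbering; any site-specific CSV can replace it).  For each
pair the package computes five measurements:

- mean contralateral volume `mV = (V_R + V_L)/2` (mm^3) and the normalized
  absolute difference `dV/mV`;
- mean contralateral surface area `mSA` (mm^2) and `dSA/mSA`;
- the Jaccard index `J = |A ∩ B| / |A ∪ B|` between the right-region mask
  and the reflected, rigidly registered left-region mask.

Normalizing the differences by the pair means removes the first-order size
bias, making `dV/mV` and `dSA/mSA` dimensionless (invariant under uniform
rescaling of voxel spacing; tested).

**Reflection.** The left-region image is flipped along the volume's
left-right axis (taken from the NIfTI orientation; files with unset
sform/qform codes are rejected unless an explicit axis override is given).
No anatomical mid-plane is estimated: the subsequent rigid registration
absorbs any reflection-plane offset, which is what makes a plain axis flip
sufficient.

**Registration.** A rigid 3D versor (unit-quaternion) transform is fitted by
minimizing mean squared error with regular-step gradient descent (SimpleITK;
initial step 1.0, minimum step 1e-4, relaxation 0.5, at most 500 iterations,
gradient-magnitude tolerance 1e-10 — binary masks produce small metric
gradients, so the tolerance sits well below ITK's default; all exposed in
`RegistrationOptions`).  Initialization aligns image centroids (moments),
which makes pure translations converge immediately and puts the tested
capture range (±5 voxels, ±15°) within reach.  When an intensity channel is
supplied, the masked intensity images drive the metric; otherwise the binary
masks do.  The metric is computed over the (cropped) image by default; an
option restricts it to the fixed mask.  The moving mask is always resampled
with nearest-neighbor interpolation, and the Jaccard index is always
computed on binary masks — overlap of fractional masks is not well defined.
A registration that exhausts its iterations keeps its Jaccard value but is
flagged, and downstream fitting can exclude flagged rows; an empty region
yields a row flagged missing rather than an exception, so a 40-pair batch
never aborts.

**Surface area** is exposed-face counting: each voxel face adjacent to
background contributes its physical face area (6-connectivity).  This is
exact on voxel data (single voxel at unit spacing → 6.0; 3×3×3 cube → 54.0)
and deterministic; it is a voxel-level measure and, like any voxelized
surface estimate, overestimates the area of smooth anatomical surfaces — a
consistent bias that cancels in the normalized difference.

Known limitation carried over from the method itself: region size affects
the magnitude of the post-registration metric, and no size correction is
applied to `J`.

## 2. Conversion-anchored time alignment

Visit tables keyed by subject (`rid`) and months-since-baseline are merged
(outer join onto the diagnosis table; duplicate keys are an error), and the
cohort filter removes subjects who are cognitively normal at every visit or
lack a required covariate at every visit.

Subjects with an MCI visit preceding an AD visit are *converters*; their
first AD visit becomes adjusted time 0 and all visits shift rigidly (a
converter first diagnosed at month 24 has baseline −24 and its 36-month
visit at +12).  Subjects holding one diagnosis throughout are *static*;
other sequences (e.g. reversion without re-conversion) are excluded and
logged.

Static subjects borrow an anchor by hot-deck nearest-neighbor imputation.
The comparison visit — the last visit for static-MCI, the baseline visit for
static-AD (the baseline reading of the source procedure; both the comparison
visit and an optional donor-stage restriction are configurable) — is
compared with every converter visit on MMSE, ADNI-MEM and age using a
Euclidean distance with each variable normalized by its range.  Ranges
default to the observed min–max over the donor pool, frozen once per run and
stored in the output metadata.  Ties break deterministically by distance,
then donor id, then donor visit.  The selected donor visit's adjusted time
is assigned to the comparison visit and the rest of the timeline shifts
rigidly, so within-subject visit spacing is always preserved exactly.

**Validation replicates.** The imputation is re-run `n_replicates` times
(default 1000) with the donor drawn uniformly from the k=5 closest matches,
replicate r using seed `seed + r`; donor distances are computed once per
static subject, so the replicate set costs little more than a single run.
Each replicate's adjusted-time sample is compared with the original by a
two-sample Kolmogorov–Smirnov test whose p-value comes from pooled bootstrap
resampling (n_boot=1000 by default): both samples are redrawn with
replacement from their pooled values and p is the fraction of bootstrap
statistics at or above the observed one.  The bootstrap is what keeps the
test honest under the heavy ties that integer months and rigid shifts
produce.  Identical samples give statistic 0 and p = 1 by construction.
The per-variable summary (min / mean / sd of p across replicates) is the
quantity reported.

## 3. Single-knot segmented regression

Each biomarker y on adjusted time t is modeled as a one-knot linear spline
with Gaussian errors:

    y = a + b1·t + (b2 − b1)·(t − ψ)_+ + ε,  ε ~ N(0, σ²).

One knot is the right capacity: within a window that covers the MCI→AD
transition only one bend of a sigmoid course is observable.  Before
fitting, values outside the Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
(closed interval, quartiles by linear interpolation) are excluded globally
per variable; the per-time-point variant is available as an option.
Fitting uses the individual observations; mean-value curves (per unique
month, suppressing points with fewer than 5 measurements) are for display.

**Estimation.** Given a working knot ψᵢ, regress y on
{1, t, (t − ψᵢ)_+, −1[t > ψᵢ]} and update ψᵢ₊₁ = ψᵢ + γ̂/δ̂, where δ̂ is the
slope-difference coefficient and γ̂ the indicator coefficient (zero at a
fixed point).  Convergence is |Δψ| < 0.01 months within 100 iterations;
updates that overshoot are halved.  Because the RSS profile in ψ has local
optima, the iteration always runs from a multi-start set: the median time, a
10-point grid over the admissible window, and the two best cells of a
1-month profile scan.  The profile is additionally kinked at the observed
times, and a minimum sitting in a kink repels the gradient-style update, so
when the scan's argmin strictly beats every iterative candidate it is
accepted as the estimate.  The minimum-RSS convergent candidate is reported;
with Gaussian errors the negative log-likelihood reported as the objective
is a monotone function of that RSS.  On exactly piecewise-linear data the
knot is recovered to machine precision, and the estimate is exactly
equivariant under time translation.  On simulated cohorts the reported
optimum is never worse than an exhaustive 0.5-month grid search (tested
against an independent brute-force oracle).

The knot is constrained to the [5th, 95th] percentile window of the
observed times with at least 10 points on each side; n < 20 observations,
no admissible interior knot, or δ̂ ≈ 0 (no slope change, e.g. purely linear
data) yield a non-converged fit classified inconclusive.  Standard errors
come from the linearized design at convergence: coefficient SEs from the
final 3-column OLS, and SE(ψ̂) = SE(γ̂)/|δ̂| (delta method; ±2·SE coverage of
the knot verified at 0.90–0.99 over 200 noisy piecewise simulations).  A
residual bootstrap is not used, matching the cited estimation approach.

**Trend classification.** A converged fit is *stabilizing* if the post-knot
slope is significantly smaller in magnitude than the pre-knot slope,
*destabilizing* if larger, and *inconclusive* if the slope change is not
significant, neither slope differs from zero at α = 0.05, or the knot lies
in the outer 10% of the observed time range — the operational version of
discarding fits driven by sparse extreme-time data.  Conclusive fits sorted
by knot give the biomarker ordering; for overlay displays, curves are
sign-flipped if decreasing and affinely mapped to [0, 1] (idempotent;
constant curves are rejected).

## 4. Synthetic study conditions

The generator produces the two kinds of input the analysis consumes, always
together with an answer key.

**Paired volumes.** The right region is an axis-aligned ellipsoid (default
semi-axes 12×9×7 voxels on a 64³ grid); the left region is its mirror image
scaled to a volume ratio 1/size_ratio, radially modulated by a random
degree-2 real spherical-harmonic field of chosen amplitude (left side only),
then rotated and translated by a recorded rigid transform.  Regions touching
the grid boundary or overlapping abort generation (boundary contact would
bias the exposed-face surface area).  With no asymmetry the left mask is the
exact voxelwise mirror of the right, which pins the downstream Jaccard at
1.0; increasing modulation amplitude strictly decreases it.  What this does
not emulate: anatomical shape, MRI intensity structure, bias fields, or
segmentation errors — so passing tests certify the geometry and registration
machinery, not robustness to real MRI artifacts.

**Cohorts.** Each subject carries a latent conversion offset on the visit
scale (0–48 months, ADNI-like grid): converters (fraction 0.28 by default,
matching a 392/1382 split) convert at an observed follow-up visit; static
MCI subjects would convert 6–48 months after their last visit; static AD
subjects converted 0–36 months before baseline; static NL subjects lie far
to the left and exist to exercise the cohort filter (default static mix
NL/MCI/AD = 0.25/0.45/0.30).  Biomarker values are deterministic functions
of adjusted time plus independent Gaussian noise.

Each trajectory realizes the observable subsection of a sigmoid: its slope
blends logistically from a pre-inflection to a post-inflection rate,

    value(t) = v0 + p1·(t − ψ) + (p2 − p1)·τ·[softplus((t − ψ)/τ) − ln 2],

so the two asymptotes intersect exactly at the planted knot ψ and the far
bend of the sigmoid stays outside the observation window.  (Realizing the
full logistic *value* curve instead places both its bends inside a ±84-month
window unless τ is so large that the corner becomes statistically
unidentifiable at a few hundred observations; a one-knot model is then the
wrong description of the data by construction.  The hinge form is the
sigmoid subsection the one-knot model is meant for.)

The default five-marker panel staggers the knots in the canonical cascade
order — CSF amyloid (−65), P-Tau (−50), total Tau (−35), memory composite
(−15), MMSE (+10 months) — on scales resembling the reference cohort
(MMSE integer-rounded and clipped to 0–30).  τ is 10 months throughout.
Noise standard deviations are set so each knot's standard error is well
below the 25-month stagger at ~500 observations (the regime in which
validating ordering recovery is meaningful), and so that each marker's
pre-knot value range stays inside the global Tukey fences — a steep early
tail that the outlier filter amputates is otherwise the dominant failure
mode for the earliest marker.  The cognitive covariates keep a moderate
pre-conversion decline: they double as the matching variables, and
informative matching is the premise of the hot-deck imputation.

These noise levels represent residual scatter around a population-average
trajectory.  Real cohorts add between-subject heterogeneity (random
effects), assay batch effects, and covariate-dependent progression speed;
none are simulated, so passing tests demonstrate correctness of the
estimator under its own model, not performance on ADNI-scale noise.

**Known limitation (quantified here, inherent to the method).**  When the
segmented fits run on *imputed* adjusted times rather than the answer key,
anchor noise of roughly ±10–15 months (the time resolution the matching
covariates afford) smooths the earliest marker's corner and biases its knot
toward the data center: in end-to-end runs the amyloid-like knot is
attenuated from −65 to roughly −25 while the later markers move little.
Distributional stability of the time variable (what the KS validation
checks) does not imply per-subject anchor accuracy.

## 5. Problem sizes and defaults

Defaults were chosen once as the package's study conditions: demo pipeline
60 subjects / 25 replicates / 200 bootstrap draws; property suites use 64³
to 72³ voxel grids, cohorts of 72–150 subjects (≈500–1000 visit rows), 200
simulation replicates for knot-recovery and coverage statements, 100
imputation replicates with 300 bootstrap draws for the KS behavior, and a
0.5-month exhaustive grid as the segmented-fit oracle.  Every stochastic
stage takes an explicit seed; replicate r derives seed + r, and identical
seeds reproduce every output byte for byte.
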