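# Methods

`volcurves` estimates and compares cross-sectional age–volume associations
("volume curves") for brain regions in cognitively normal adults, stratified
by preclinical Alzheimer's and vascular biomarker status.  This note records
the statistical model, the defaults and why they were chosen, what the
synthetic cohort does and does not emulate, and the places where the design
was genuinely open.

## Cohort filtering and stratification

Subjects enter the analysis when they have complete CSF biomarkers (Aβ42,
t-tau, p-tau, with Aβ42 > 0 so the p-tau/Aβ42 ratio is defined), a global
CDR of exactly 0, passing volumetric QC, no radiological exclusion finding,
and age ≥ 50.  Each rejected subject carries a single machine-readable
reason code (the first failing filter, checked in a fixed order).

Four binary axes are derived with strict inequalities — a value exactly at
its threshold is negative:

* A: Aβ42 < 1030 pg/mL or p-tau/Aβ42 > 0.023
* T: p-tau > 27 pg/mL
* N: t-tau > 300 pg/mL
* V: Fazekas > 1, microbleeds > 3, or stroke history

For integer-valued Fazekas scores and microbleed counts these strict
inequalities are identical to the ≥2 / ≥4 formulations sometimes used for
vascular burden.  The sixteen A/T/N/V combinations partition into six
labels: AD (A+V−), AV (A+V+), V (A−V+T−), OP (A−V−, T or N positive),
N (all negative) and EXCLUDED (A−V+T+, an ambiguous profile dropped from
analysis).  Exclusion of the ambiguous profile is applied exactly once,
after the inclusion filters; this makes the rule order-independent and
fully testable.  Subjects with missing vascular readings are rejected with
a reason code; the package requires complete marker data by design.

## Normalization

Each region volume is divided by the subject's total intracranial volume and
the resulting ratio is z-scored.  The z-transform's mean and sample SD
(n−1 denominator) are computed **once over the full included cohort** and
reused for all subsets, so curves of different groups live on a common
scale — without this the between-group area metric would not be
interpretable.  A region with zero ratio variance raises an error naming the
region.  Gender-stratified reruns are treated as independent experiments and
recompute the normalization within each gender subset.

Outlier removal is |z| > 4 in any analyzed region, single pass (z-scores are
not recomputed afterwards).  The value 4 is conservative (P(|z|>4) ≈ 6×10⁻⁵
per observation under normality) and configurable.

## Valid age ranges

Kernel estimates are unreliable where subjects are sparse, so each group
gets a valid age range: sliding windows [a, a+2) for integer a from
⌊min age⌋ to ⌈max age⌉−2 are marked dense when they hold ≥ 5 subjects, and
the range spans the longest contiguous dense run (ties resolve toward the
younger end, making the rule deterministic).  Two curves are compared only
over the intersection of their groups' ranges; an empty intersection flags
the comparison rather than silently dropping it.

## Curve estimation

The volume curve is the Nadaraya–Watson estimator with a Gaussian kernel
K(u) = exp(−u²/2),

    m̂(g) = Σᵢ K((g−xᵢ)/h) yᵢ / Σᵢ K((g−xᵢ)/h),

evaluated on an integer-year grid over the group's age range.  The Gaussian
kernel never assigns exactly zero mass inside the data range, avoiding the
empty-window failures of compact kernels; row-max subtraction in log space
guards the weight normalization against underflow.

The bandwidth h is selected per region×group from the candidate set
{5, 10, 15} years by 5-fold cross-validated mean squared prediction error
(folds from a seeded uniform shuffle into near-equal blocks; ties, including
floating-point-exact ties, break toward the smallest candidate).  Selection
happens once on the full group sample, **outside** the bootstrap; replicates
reuse the selected bandwidth.  Selecting inside each replicate would be
five-fold more expensive and would mix bandwidth variability into the curve
uncertainty that the comparison statistic then has to absorb; fixing it
stabilizes the between-group comparison.

Uncertainty comes from a case bootstrap: 100 resamples of (age, volume)
pairs with replacement to the original group size, each refitted over the
same grid.  The reported curve is the pointwise mean of the replicates and
its confidence measure is the pointwise sample SD; a resample with vanishing
kernel mass at some grid point is redrawn and counted.  CV folds and
bootstrap draws use independent seeded streams derived from the run seed,
the group label and the region code, so any single curve is reproducible in
isolation and changing the CV seed does not perturb the bootstrap stream.

## Curve comparison

The effect size between two groups in one region is the trapezoidal
integral of the absolute difference of their mean curves over the overlap
range at one-year resolution (z·years).  The absolute (unsigned) integrand
is used: a curve pair that crosses still differs, and the ranking should
reflect total divergence.

Significance uses the statistic

    X² = Σⱼ (m̂ₐ,ⱼ − m̂_b,ⱼ)² / (sdₐ,ⱼ² + sd_b,ⱼ²)

summed over the J grid points of the overlap.  Kernel smoothing makes
neighbouring grid points strongly correlated, so referring X² to χ²_J is
badly anti-conservative — under perfect correlation X² behaves like J·Z²
for a single standard normal Z, and the nominal test's family-wise error
explodes.  The null is therefore calibrated against the exact distribution
of the Gaussian quadratic form: the covariance of the curve difference
across grid points is estimated from the bootstrap replicates of both
curves, standardized to a correlation matrix R, and X² is referred to
Σᵢ λᵢ χ²₁ with λᵢ the eigenvalues of R, evaluated with Kuonen's saddlepoint
approximation (Satterthwaite's two-moment match is the fallback near the
distribution center and defines the *effective df* reported alongside the
nominal df).  Under independence this reduces to the nominal χ²_J test;
under perfect correlation it collapses to a single-df test, which is exact.
Estimating R from 100 replicates is itself noisy; the estimation error
inflates the leading eigenvalues slightly, which errs on the conservative
side.  The calibration is certified by simulation (see the validation
suite), not assumed: across 200 null cohorts the family-wise rate of any
Bonferroni-adjusted p < 0.01 over a 10-region family measured 0 –
comfortably within its binomial bound.

P-values are Bonferroni-adjusted (p·m, capped at 1) over the regions of one
group-pair comparison; significance is declared at adjusted p < 0.01.  The
comparison of the reference group against the full cohort keeps the overlap
(the reference subjects are inside the full cohort, mirroring the original
design); the test for that pair is flagged `descriptive` in the output
because the two sides are not independent samples.  Pairwise tests among
the pathology groups themselves are deliberately not performed.

Residual sources of miscalibration are documented rather than corrected:
when the two groups select different bandwidths, their smoothing biases
differ systematically under a sloped null, which the bootstrap SDs do not
capture.  At the default settings this effect is small (it is inside the
simulated null above), but it grows with bandwidth contrast and slope.

## Synthetic cohort

The generator emulates the structure of the (access-restricted) source
cohort: five biomarker groups of sizes 782/178/212/118/90 (1,380 total),
the published gender mixes, and per-group/gender ages drawn from normals
truncated to [50, 95] with the published means and SDs (truncation yields
the mild right skew of a 50+ cohort).  CSF and vascular markers are sampled
from intervals that realize each group's A/T/N/V definition with a 5%
margin away from every threshold, so boundary-rule choices can never flip a
synthetic label — stratification of a generated cohort reproduces the
configured group sizes exactly, which the test suite uses as a round-trip
oracle.

Volumes follow a latent piecewise-linear z-trajectory per region,
z(age) = baseline + slope·(age−50), default baseline 0.7 and slope
−0.02 z/yr (a gradual normative decline), plus optional group-specific
accelerations `extra_slope·max(0, age−onset)` and Gaussian noise with SD
0.5 z.  The default effect set paints the qualitative pattern reported for
this kind of cohort — medial-temporal acceleration in the amyloid-positive
groups, slightly stronger with added vascular burden, and a
fronto-parietal/basal-forebrain pattern sparing the amygdalae in the pure
vascular group — with onsets of 58–62 years and extra slopes of −0.02 to
−0.034 z/yr.  The latent z maps to a volume/TIV ratio affinely
(ratio = base + 0.05·base·z, with base spread across regions), volumes are
ratio×TIV with TIV ~ N(1450, 130) truncated positive, and every generated
subject passes QC with CDR 0.  Effects can be restricted to one gender; a
*constant* gender offset would be absorbed by per-subset z-scoring, so
gender-specific pathology is expressed as an age-dependent acceleration.

What the generator does **not** emulate: covariance between regions within
a subject (regions are independent given age), CSF assay noise and
missingness, QC failures, non-linear trajectories beyond the piecewise
kink, and longitudinal structure.  Passing tests therefore certify the
statistical machinery — stratification, normalization, estimation,
calibration, detection — under a known data-generating process, not the
anatomical realism of any particular dataset.

The piecewise-linear choice is deliberate: it is the simplest model for
which the estimator, the bandwidth selection, the area metric and the
ground-truth recovery checks all have analytically known targets
(`true_mean_curve` marginalizes the noiseless trajectory over the group's
gender mix; `cohort_curve_to_latent` inverts the ratio/normalization chain
so estimated and true curves can be compared on the latent scale where the
noise SD is defined).

## Numerical choices and degenerate inputs

* Sample SDs use the n−1 denominator throughout.
* Bandwidth tie-break: smallest candidate, with ties detected up to a
  1e-12 relative tolerance (exact-arithmetic ties otherwise dissolve in
  floating-point round-off).
* Zero kernel mass at a grid point raises; in the pipeline the grid is
  restricted to the group's age range, where the Gaussian kernel cannot
  underflow.
* Zero pooled bootstrap variance at a grid point (degenerate bootstrap)
  raises an error naming the grid point.
* Empty cohorts, all-rejected cohorts, zero-variance regions and invalid
  overlaps raise typed errors with the offending entity; pipeline stage
  failures write a FAILED manifest and keep partial outputs.
* Synthetic generation iterates groups and regions in sorted order so
  results are invariant to dict insertion order (configs round-trip through
  sorted YAML).

## Reproducibility

A run is fully determined by its `RunConfig` (including the seed): two runs
with the same config produce byte-identical CSVs, and `manifest.yaml`
alone suffices to replay a run (`rerun_from_manifest`).  Per-curve seeds
are derived from the run seed with the group label and region code as
stream keys (CRC-32 of the names into a `SeedSequence`), so no curve's
randomness depends on evaluation order.

## Problem sizes used in validation

The validation suite runs the null calibration at 200 cohorts of 2×300
subjects with a 10-region family, effect detection at 50 cohorts with the
published 782/178 group sizes, and curve recovery at 400 subjects per
group; the acceptance script uses 100 null cohorts, 25 detection cohorts
and 3 recovery cohorts.  These sizes put Monte-Carlo error well below the
asserted margins while keeping a full validation run in the low minutes on
one CPU.

## Known limitations

* The curve test's null calibration is certified for the default settings
  by simulation; extreme bandwidth contrasts or very steep trajectories
  could reintroduce anti-conservative smoothing-bias effects.
* The Nadaraya–Watson estimator has design-dependent boundary bias; no
  local-linear correction is applied, so estimates near the age-range
  edges are shrunk toward the data-dense side.  The central-80% windows in
  the recovery checks reflect this.
* Cross-sectional only: the curves describe age-volume associations across
  subjects, not within-person change.
* No covariate adjustment (education, lifestyle, scanner) — out of scope.
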