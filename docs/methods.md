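# Methods

## Image model and quantification

A brightfield field image is an 8-bit gray grid; chromogen deposition
makes pixels darker, so 0 is the most intense stain and 255 the
reference white. The stained area is selected by a single gray-level
threshold at the midpoint of the field's minimum and maximum pixel
values, and the two measurements are the mean gray value over stained
pixels and the stained percentage of the analysis region.

The midpoint rule is circular as commonly stated — the stained pixels
define the threshold that defines the stained pixels. We resolve it by
computing min/max over the whole analysis region (the full field by
default, a caller-supplied ROI mask otherwise) and thresholding once;
pixels strictly below the threshold are stained, so ties at the
threshold count as unstained (conservative toward less staining).
Whether the original ImageJ workflow used a strict or non-strict
inequality, and whether min/max came from a hand-drawn tumor ROI, is
not determinable; both region options are supported, and the inequality
choice shifts results only on exact-tie pixels.

RGB input is collapsed to intensity by Rec. 601 luminance weights
(0.299 R + 0.587 G + 0.114 B); color deconvolution into DAB/hematoxylin
channels is deliberately out of scope. 16-bit input is rescaled to the
8-bit range with a warning. A constant field is degenerate: the
threshold equals the constant, the mask is empty, area is 0% and the
mean stain intensity is undefined (NaN).

Per-slide aggregation is the unweighted mean of the per-field
intensities (over fields with non-empty masks) and areas, and one
HScore is computed per slide from the aggregated measurements — not as
the mean of per-field HScores. The published analysis reports a single
mean intensity and a single percent area per group, which implies
aggregation happens before scoring; the two conventions differ only by
a Jensen-gap term.

## The optical-density HScore

Per case,

    OD     = log10(255 / mean_intensity)
    HScore = OD × (pct_area + 1),

with `pct_area` in percent units (0–100). The published formula writes
the optical density with an unspecified "log" and a summation symbol;
we read it as a single per-case scalar in base 10 with percent-unit
area, because that is the unique common reading that reproduces the
published group mean scores (3.06 positive, 2.62 negative) from the
published group moments: natural log gives ≈7.0, fraction-unit area
gives ≈0.42, both off by far more than 50%. This disambiguation is
itself a unit test.

Mean intensity is clamped to ≥1 gray level before the log transform so
a (physically implausible) all-black mask cannot send OD to infinity;
the clamp is logged when triggered.

## Synthetic data

No patient images or tables are distributable, so the generators
emulate the study conditions.

**Field images.** A boolean stain pattern — annuli around ellipse
"cells" by default, mimicking membrane staining; filled blobs as a
robustness alternative — is painted at a uniform stain gray level on a
near-white background, then Gaussian pixel noise (default SD 3 gray
levels, clipped to [0, 255]) models acquisition noise. The painted
pattern is trimmed or back-filled to hit the requested area fraction to
the pixel, and the realized stained fraction and realized mean stained
gray value are recorded as ground truth beside the image; analysis code
never reads them. With zero noise the quantification pipeline recovers
the ground truth exactly; at the default noise it recovers area within
1 percentage point and intensity within 3 gray levels (both tested).

**Cohorts.** Per case, mean intensity and percent area are drawn
independently from normal distributions truncated to the published
per-group ranges (defaults: FISH-negative 113.3 ± 13.9 on
[66.4, 142.8] and 6.3 ± 1.9 on [2.6, 13.8], n = 169; FISH-positive
103.82 ± 20.8 on [59.1, 126.4] and 6.8 ± 2.1 on [3.6, 11.9], n = 13).
Independence follows the reported absence of correlation between
intensity and area; only group-level moments are published, so any
finer dependence structure is unknowable. Truncation keeps draws
physically possible but, because the published ranges are asymmetric
about the means, it shifts the distributions' true means slightly
(negative intensity ≈112.7, positive ≈99.4); convergence tests
therefore target the truncated distribution's exact mean, and the
simulated group separation is modestly wider than the nominal moments
imply — the simulated mean AUC (≈0.71) sits above the published point
estimate (0.668) but inside its 95% CI. IHC 0/1+/3+ control groups are
generated directly at the HScore level (10 cases each at the published
score moments) because only their score summaries are published.

What the generator does **not** emulate: color (DAB vs hematoxylin),
cell morphology and nucleus structure, spatial heterogeneity of
staining within a slide, inter-observer thresholding variability, and
any intensity–area dependence. Passing tests therefore demonstrate
correctness of the measurement and inference machinery under the
stated distributional model, not performance on real slides.

**Enrollment.** A raw-enrollment generator produces n records with
exactly k flagged as missing clinical data and/or an unavailable
slide (flag pattern pseudo-random by seed); the exclusion stage keeps
rows with both flags clear and reports counts by reason, reproducing
the study's 331 → 182 accounting.

## Decision analysis

**ROC/AUC.** Candidate cutoffs are the observed score values; a case
is called positive when score ≥ cutoff (higher HScore → ERBB2
positive, matching the direction of the published group means). The
AUC is the Mann–Whitney probability with ties counted one half, its
standard error comes from DeLong's placement-value method, and the
95% CI is the normal approximation clipped to [0, 1]. The
implementation is validated against exhaustive pair counting on all
small inputs, against scikit-learn's `roc_auc_score` under heavy ties,
and against a frozen reference computed with R's pROC
(`ci.auc(method = "delong")`).

**Youden cutoff.** The cutoff maximizing J = sensitivity +
specificity − 1; ties break toward the smallest cutoff, which keeps
sensitivity maximal at equal J. Matched against exhaustive search.

**Logistic association.** `statsmodels` maximum-likelihood logistic
regression of FISH status on the HScore, optionally with covariates
(the covariate set is caller-supplied, not hard-coded). Odds ratios
with Wald 95% CIs; zero-variance predictors are dropped with a
warning; perfect separation falls back to a lightly ridge-regularized
fit and clears the `converged` flag.

**Cutpoint scan.** Each candidate c (default grid: midpoints between
consecutive observed scores) splits cases into {score < c} and
{score ≥ c}; the 0/1 outcome is compared between the groups and the
raw p-value is Bonferroni-multiplied by the number of candidates
actually tested (candidates whose split leaves an empty group are
skipped and recorded). The default comparison is the **pooled**
two-sample t-test, which on a binary outcome is a monotone function of
the pooled two-proportion z statistic. The unpooled Welch variant is
available (`test="welch"`) but not the default: at extreme splits a
small outcome-constant group has zero unpooled variance, its p-value
collapses toward zero, and the scan's family-wise error rate under the
null rises to ≈0.7 despite the Bonferroni correction, violating the
error control the correction exists to provide. The pooled default
holds the simulated null FWER at ≈0.03 (500-replicate test).
Chi-square and Fisher alternatives are also provided.

**Pairwise category AUCs.** For every pair of IHC categories present
with ≥2 scored cases, the higher category is the positive class and a
full ROC summary is computed, yielding the six-row comparison table
for categories 0/1+/2+/3+.

## Numerical and interface choices

- Determinism: every generator takes an integer seed; identical
  spec + seed reproduces bit-identical images, cohorts and reports.
  Report files embed the seed and a SHA-256 hash of the configuration.
- CSV is the interchange format for all tabular stages; images are
  lossless 8-bit PNG on write (JPEG/TIFF accepted on read).
- Degenerate inputs fail fast with named columns (schema errors, CLI
  exit code 2) or are flagged and excluded with a warning
  (unquantifiable slides, unscoreable cases, single-class cohorts —
  CLI exit code 3).

## Problem sizes

The default verification suite uses cohorts of the study's size
(n = 182), 200-replicate simulations for calibration and AUC
bracketing, 500-replicate nulls for family-wise error control, and
n = 5000 for logistic parameter recovery; the full suite runs in well
under a minute on one CPU. These sizes give Monte-Carlo standard
errors comfortably below the tolerances being asserted.

## Known limitations

- The exact published data-dependent values (AUC 0.668, cutoff 2.6007,
  sensitivity 0.77 / specificity 0.58) are not reproducible without
  the patient-level data; they are bracketed by simulation instead.
- The threshold rule analyzes whole fields by default; the original
  workflow may have used hand-drawn tumor ROIs.
- The classical categorical HScore (0–300 from binned intensity) is a
  different statistic and is intentionally not implemented.
- Whole-slide (pyramidal) formats, stain normalization and membrane
  segmentation are out of scope.
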