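# Methods

## Measurement model

Areas enter the pipeline as calibrated measurements, never as raw images:
either a polygonal contour in pixel coordinates (shoelace formula, absolute
value so winding direction is irrelevant, scaled by the squared pixel size)
or a binary mask (set-pixel count × pixel area). The pixel model is
all-or-nothing — a pixel is inside a mask iff its center is inside the
shape — matching manual ROI tools; there is no partial-pixel anti-aliasing.
Pixel centers sit at integer coordinates, origin top-left, y downward, and
the phantom rasterizer uses the same convention, so measured and analytic
areas converge as resolution grows (relative error is O(perimeter/area);
below 1% for discs of radius ≥ 30 px). Self-intersecting contours are not
detected beyond the ≥3-distinct-vertex precondition: anatomical ROIs are
near-convex and exhaustive detection buys nothing here.

Each site is read twice by each of two observers and the plain mean of all
readings feeds the ratios. The reference dural-sac area is the mean of the
sacs one level above and below the compressed level, standing in for the
(unmeasurable) normal sac at that level.

## Scores

All ratios are carried as percents — one representation end to end, with a
fraction accessor — to avoid ×100 bookkeeping bugs. CCAR = 100 − OCAR −
SCAR holds exactly by construction; values outside [0, 100], which noisy or
inconsistent measurements can produce, are **flagged and retained** (they
stay in ROC analyses and are counted in the report's QC field) rather than
clipped, since clipping would silently distort threshold statistics.

mJOA scores are validated as integers in [0, 11]; the recovery rate is
undefined when the preoperative score is already 11 (no achievable
improvement), and such patients are excluded from RR summaries and the
outcome ROC rather than imputed. Grading uses the unrounded RR with
boundaries [75, 100] excellent, [50, 75) good, [25, 50) fair, and
everything below — including negative RR, i.e. deterioration — poor: the
scale's worst category is the only defensible sink for values below its
printed floor.

Zone boundaries follow the published inequalities (≤14.3, ≥44.5 / ≥45.2),
so the gray zone is open at both ends. The binary DO rule is strict
(positive iff CCAR < cut-off): the boundary value classifies as non-DO.
Boundary handling at the cut-off is a convention, not an empirical claim.

## Evaluation statistics

* **Group tests.** Welch (unequal-variance) t by default — robust when
  group spreads differ, nearly identical to Student's t when they do not.
  Categorical tables use Pearson chi-square without continuity correction,
  switching to Fisher's exact test for 2×2 tables with any expected count
  below 5 (a `method` override forces either test); the report always
  records which test ran.
* **ROC.** Positivity direction is an explicit parameter,
  `lower_is_positive` by default (less CSF reserve ⇒ disease). The AUC is
  the Mann–Whitney probability with ties counting one half, computed from
  midrank placements; the same placements give DeLong's variance and a
  normal-approximation 95% CI (Hanley–McNeil available as an option). The
  reported optimal cut-off is the observed score value maximizing Youden's
  J, ties broken toward higher sensitivity and then the lower threshold, so
  the operating point is always realizable on the data.
* **Exact intervals.** Sensitivity, specificity and accuracy (the
  "diagnostic coincidence rate") carry Clopper–Pearson 95% CIs computed
  from the actual confusion-matrix counts via beta quantiles, with the
  closed-form edges (α/2)^(1/n) at the boundaries.
* **Reliability.** ICC(2,1) — two-way random effects, absolute agreement,
  single rater — on each observer's end-to-end CCAR (mean of that
  observer's two repeats per site). Absolute agreement is the right form
  because a systematic between-observer offset is a real disagreement for
  a threshold-based score; the CI uses the McGraw–Wong F-distribution
  interval. The ICC form is recorded in the result so outputs are
  self-describing. Degenerate inputs (no between-subject variance) warn
  and report NaN; perfect agreement returns a point interval.
* p-values display to 3 decimals with a `<0.001` floor.

## Synthetic cohort generator

The generator's defaults are the published study conditions: 27 DO / 25
non-DO patients; group CCAR means 22.2% / 50.0% with SDs back-computed
from the published CI half-widths (sd = h·√n / t_{n−1,0.975} ≈ 12.13 /
11.75); preoperative mJOA 5.1±3.0 / 5.7±2.2; recovery rate 42.3±32.5 /
72.5±23.0 truncated at 100 (negative RR — deterioration — is permitted, as
a few postoperative deteriorations occur); sign frequencies (tram-track
8/27 vs 0/25, comma 9/27 vs 0/25, bridge 6/27 vs 1/25) and Sato-type and
segment distributions taken as maximum-likelihood estimates of the
published counts, zero cells staying exactly zero; age, sex and follow-up
duration matched to the published moments for schema realism only.

Distributional choices the source data do not pin down, recorded here as
this package's assumptions: CCAR is normal truncated to [0, 100] (only
means and CIs are published; truncation shifts the DO-group mean up by
about +0.7 at these parameters, visible in the generator grand means);
SCAR is uniform on [15, 45]% — a plausible cord-occupancy range, exposed
as a parameter; the bony canal area is normal 230±25 mm²; the
adjacent-level sac reference equals the canal area up to a 3% log-normal
jitter (the measurement model's own assumption). Given CCAR, SCAR is
resampled alone on an infeasible split (implied OCAR < 0), which preserves
the calibrated CCAR marginal; CCAR is redrawn only if no in-range SCAR
fits. The latent OCAR + SCAR + CCAR = 100 identity is exact per patient.
Follow-up mJOA is back-computed from the drawn RR as pre + RR·(11−pre)/100,
rounded to the nearest integer in [pre−1, 11], so integer mJOA, RR ≤ 100
and at most one point of deterioration are guaranteed jointly.

Observer noise is a unit-mean multiplicative log-normal per reading
(default CV 3%) plus an optional systematic multiplicative bias per
observer. cv = 0 reproduces truth exactly.

What the generator does **not** emulate: non-normal or skewed CCAR
distributions, correlation between CCAR and the imaging signs beyond
group-conditional independence, longitudinal structure, and real
segmentation ambiguity. Consequently the synthetic DO AUC (~0.97) exceeds
the published 0.835: passing tests demonstrate that the pipeline's
arithmetic and inference are correct under known conditions, not that real
cohorts separate this cleanly.

Phantom slices use shapes with closed-form areas: a circular canal, a
crescent mass (canal minus an offset circular "bite", area via the
circle–circle lens formula), and elliptical sac and cord. Containment
(mass ⊂ canal, cord ⊂ sac) is enforced at construction.

## Problem sizes and numerics

Default analyses run on the 52-patient cohort; the generator-calibration
checks use 200 seeded cohorts and reliability simulations 200 subjects —
sizes at which Monte-Carlo error is well inside the asserted bands while
the whole suite stays fast. Oracle equivalences (AUC vs O(n²) pair
counting, Youden vs exhaustive search) are property-checked on 500 random
instances with n ≤ 50 and heavy ties. All randomness flows through one
seeded `numpy` Generator; reports echo their full configuration and are
byte-identical on regeneration.

## Known limitations

Real DICOM ingestion, segmentation, CT–MRI registration, and assignment of
morphologic types or imaging signs from images are out of scope — areas
and signs enter as measurements and labels. Published
sensitivity/specificity CIs in the source tables imply denominators
inconsistent with the stated group sizes; this package always computes CIs
from the actual counts of the cohort analysed rather than reproducing
printed intervals. Cut-offs are treated as external parameters: with 52
patients the Youden-optimal cut-off has high sampling variance, and no
attempt is made to present re-derived cut-offs as universal constants.
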