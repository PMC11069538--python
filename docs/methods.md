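# Methods

## The heterogeneity score and map

The score of an ROI is its percent coefficient of variation,
`SD / mean × 100`, computed over the raw stored pixel intensities.  Two
conventions are fixed deliberately:

* **Sample SD (divisor n−1).**  For clinical ROIs of thousands of pixels
  the difference from the population SD is far below 0.1% relative; sample
  SD is the standard CV convention, and every oracle in the test suite uses
  the same divisor so the choice is pinned, not incidental.
* **No intensity preprocessing.**  Rescale slope/intercept, windowing and
  other linear display transforms are not applied: the CV is invariant
  under any positive linear rescale, so they cannot change a score.  (A
  *shift* does change the CV — adding a constant to a non-constant ROI
  strictly lowers it, a property the suite tests — which is exactly why the
  stored values, not display values, are used.)

The map divides the ROI's percent score by each pixel value and multiplies
by 100, so map values may exceed 100 and darker pixels light up.  Pixels
with zero intensity are included in the score (they are real data, and the
score stays defined as long as the ROI mean is positive) but are *undefined*
in the map rather than divided by; they are tracked explicitly, rendered in
a reserved sentinel color, and excluded from map summaries.  An ROI that is
entirely black has no defined score (zero denominator) and raises an error.

Patient-level scores are the unweighted arithmetic mean over that patient's
frames (clinically 2–3; other counts are accepted with a warning).  ROI
size does not weight the mean.

## ROI geometry and rasterization

ROIs are closed polygons in 0-based (row, col) coordinates with the origin
at the *center* of the top-left pixel; vertices may be fractional.  A pixel
belongs to the ROI iff its center lies inside the polygon or exactly on its
boundary.  The predicate is evaluated by an exact geometric
point-in-polygon test (shapely/GEOS `intersects`), restricted to the
polygon's bounding box, so boundary pixels are included deterministically —
there is no coverage-fraction threshold to tune.  Collinear (zero-area)
polygons and polygons rasterizing to fewer than two pixels are rejected as
degenerate; self-intersecting rings are rejected as invalid.  The test
suite cross-checks the rasterizer against an independent even-odd
point-in-polygon oracle on random star-shaped polygons and against
hand-counted axis-aligned fixtures that exercise the boundary rule.

## Image input

Single-frame DICOM (MONOCHROME1/2 or RGB), 8/16-bit PNG and TIFF are
accepted; multi-frame/cine content is rejected.  MONOCHROME1 (inverted
video) is flipped to MONOCHROME2 convention on read.  RGB payloads are
collapsed with the BT.601 luma weights (0.299, 0.587, 0.114) and rounded
back to the source bit depth; the conversion is an exact identity on gray
(equal-channel) pixels.  Overlay rendering scales map values linearly
between the ROI's own min and max onto the "jet" ramp (a constant map
renders as the ramp minimum) and never touches pixels outside the ROI.
Per-ROI min/max scaling maximizes within-ROI contrast; it trades away
cross-image comparability of colors, which the score itself provides.

## Cohort statistics

* **ANOVA / Tukey / effect size.**  Classical one-way fixed-effects ANOVA
  over the four nodule groups (the normal-parenchyma reference is summarized
  but excluded from the ANOVA by default).  Partial eta squared is
  `SS_between / (SS_between + SS_within)`, banded negligible/small/medium/
  large at 0.01 / 0.06 / 0.14.  Tukey HSD adjusted p-values use the
  studentized range distribution with the Tukey–Kramer standard error
  `sqrt(MSW/2 · (1/ni + 1/nj))` for unequal group sizes.  The test suite
  checks them against an independently written nested-quadrature CDF of the
  studentized range (1e-6 agreement) and, loosely, against statsmodels.
* **Grade correlation.**  Pearson correlation (a degree-1 polynomial fit)
  between patient scores and the ordinal grade coding normal=0, II-B=1,
  III-B=2, III-M=3, V/VI-M=4; two-sided p from the t transform.  The coding
  map is configurable; the correlation includes the normal group by default.
* **ROC.**  The empirical AUROC (equal to the Mann–Whitney pair-counting
  probability, ties counted half).  The operating cutoff maximizes
  Youden's J = sensitivity + specificity − 1 over the observed scores with
  the rule "positive if score ≥ cutoff"; ties are broken toward the
  smallest attaining threshold so the choice is deterministic.  The
  criterion is declared rather than inherited: the selection rule behind
  published CV cutoffs is typically left unstated, and Youden is the field
  standard.  AUROC confidence intervals and the p-value against chance use
  DeLong's variance (midrank formulation); the implementation is verified
  against pROC's DeLong output on a frozen fixture.  All confusion metrics
  (sensitivity, specificity, PPV, NPV, diagnostic accuracy
  `(TP+TN)/total`) are stored as raw integer fractions; percentages are
  rounded only at display time, so rounding never propagates.  PPV/NPV with
  empty denominators are flagged undefined instead of failing the report.
* **Report.**  Six default pooled comparisons (III-B vs III-M up to
  normal/II-B/III-B vs III-M/V&VI-M).  A comparison naming a group absent
  from the cohort is skipped with a warning (or raises in strict mode).  No
  multiplicity correction is applied across the six comparisons.

## Synthetic data

The generators define the study conditions for all end-to-end tests; no
clinical images ship with the package.

* **Speckle ROIs** draw i.i.d. intensities with prescribed population mean
  and CV.  Gamma is the default — non-negative and right-skewed like
  B-mode amplitude speckle, with CV fixed entirely by the shape,
  `k = (100/CV%)²` — and lognormal is offered as an alternative.  Default
  scale: 8-bit, mean 100, where clipping is negligible for CV ≤ 45%; the
  clipped fraction is logged and warned about above 0.1%.  The model
  emulates only the first two intensity moments that the score measures: no
  point-spread function, attenuation, log compression or spatial
  correlation.  Passing tests therefore show the *estimator* recovers a
  known dispersion, not that clinical images behave like gamma noise.
* **Nodule embedding** fills an elliptical interior from one speckle spec
  and the exterior from another, returning the nodule polygon and a
  congruent "normal" polygon translated by a whole number of pixels (the
  clinical practice of drawing an equal-sized reference region).  Ellipse
  vertices are snapped to multiples of 1/256 — dyadic coordinates are exact
  doubles, so the integer translation is bitwise-exact and both polygons
  rasterize to identical pixel counts by construction.
* **Score cohorts** draw per-patient scores from a normal distribution
  truncated at zero with each group's mean/SD (truncation prevents
  impossible negative CVs; it raises the most dispersed group means by
  ~0.2–0.3 points, which the tests account for).  Defaults are the
  published group levels — normal 11.74 ± 2.84 (n=32), II-B 25.02 ± 5.82
  (n=24), III-B 32.04 ± 10.34 (n=52), III-M 39.93 ± 14.79 (n=54), V/VI-M
  41.30 ± 16.12 (n=58); 220 patients in all.  Under this Gaussian
  score model the benign-vs-malignant AUROC (normal/II-B/III-B vs
  III-M/V&VI-M) concentrates near 0.80 with an across-seed SD of about
  0.028, bracketing — not reproducing — the clinical value near 0.82;
  real score distributions are not Gaussian and patient images are not
  available, so exact reproduction is out of reach by design.

All generators are bit-reproducible for a fixed seed (NumPy PCG64);
problem sizes in the test suite (e.g. 200 ROIs of 10⁴ pixels for CV
recovery, 100 cohort seeds for the AUROC band) were chosen as the smallest
sizes at which the checked quantities stabilize.

## Known limitations

* No automatic segmentation: ROIs are always supplied, as in the manual
  clinical workflow; burned-in vendor annotations are assumed to lie
  outside the drawn ROIs.
* Single texture feature: the CV captures relative dispersion only — no
  GLCM, histogram-shape or spatial statistics.
* Reader reconciliation is out of scope: scores from multiple blinded
  readers are treated as separate columns, not merged.
* The AUROC band property above is intrinsically tight: with per-seed
  in-band probability ≈ 0.955, a 100-seed count fluctuates between about
  93 and 98, so that check sits at the edge of its own sampling noise.
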