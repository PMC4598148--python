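# Methods

This note documents the models, conventions and design choices behind
`plaqrisk`: what the synthetic cohort generator simulates, how each
quantitative measure is defined, and where the genuinely open decisions were
made.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design being emulated

A cohort consists of probe arms: rabbits injected with an MMP-cleavable
ACPP, a thrombin-cleavable ACPP, or the non-cleavable PEG control.  Each
rabbit's abdominal aorta, from the left renal bifurcation toward the iliac
bifurcation, is divided into contiguous 4 mm axial segments; a segment is
*disrupted* if a mural thrombus is attached on direct inspection of the
opened vessel.  The study-replica configuration
(`configs/study_replica.yaml`) reproduces the published design: 9 MMP +
8 thrombin rabbits, 286 segments total, exactly 47 disrupted.

Two published counts fix the replica geometry only partially:

- segments per rabbit is not reported.  Default 17 per rabbit
  (286 / 17 rabbits ≈ 16.8), with the last rabbit trimmed to 14 so the
  cohort totals exactly 286.
- the per-arm split of the 47 disrupted segments is not reported; they are
  drawn uniformly at random from all targeted-arm segments pooled (the PEG
  control arm is excluded from the draw).

## Synthetic cohort generator

### Signal model

All per-segment quantities are drawn from normal distributions truncated to
be positive — only the first two moments of the real distributions are
published, and truncation keeps ratios physical.  Study-replica calibration:

| quantity | disrupted | non-disrupted | source of defaults |
|---|---|---|---|
| closed-view FER, MMP arm | 4.5 ± 1.0 | 2.2 ± 1.0 | published group means |
| closed-view FER, thrombin arm | 5.0 ± 1.1 | 2.5 ± 1.1 | published group means |
| open-view plaque FER | 4.0 ± 1.1 (MMP), 6.8 ± 2.0 (thrombin) | — | published group means |
| remodeling ratio RR | 1.08 ± 0.12 | 1.00 ± 0.08 | chosen (see below) |
| Gd enhancement ratio GdR | 1.3 ± 0.25 | 1.3 ± 0.25 | chosen (see below) |

RR class distributions are not published; the values above give a binormal
AUC of Φ(0.08/√(0.12²+0.08²)) ≈ 0.71 — "moderately informative", in line
with the published single-predictor ROC summary for RR.  GdR distributions
are likewise unpublished; the published GdR ROC is essentially at chance, so
both classes share one distribution (1.3 ± 0.25, a typical contrast-enhanced
wall-to-baseline ratio), making GdR uninformative by construction.

The open-view thrombus signal is a fixed fraction (default 0.5, configurable
per arm) of the underlying plaque's signal, encoding the qualitative finding
that the enhancement originates mainly from the plaque, not the thrombus; no
quantitative thrombus/plaque ratio is published.

### Image rendering

Closed-view images are flat-field phantoms, not optical simulations: a
background at 100 counts, a femoral-artery reference patch at 1000 counts,
and an aortic strip in which each 4 mm segment block is painted at
`FER_target × 1000` counts.  Additive Gaussian noise with SD = 1 % of the
reference intensity (clipped at zero) is applied; with ≥ 1000 pixels per ROI
the quantified FER round-trips to well under the 2 % relative-error budget
the tests enforce.  Pixel pitch is 0.1 mm (40 columns per segment), exposure
1 s; images are written as 16-bit grayscale TIFF plus a JSON sidecar with
polygon ROIs in 0-based pixel coordinates (pixel centres at integers).
Open-view images contain one plaque/thrombus patch pair per disrupted
segment plus the femoral reference.

What the phantom deliberately omits: optical blur and depth attenuation,
heterogeneous plaque texture, ROI tracing error, inter-image illumination
drift.  Passing the round-trip tests therefore demonstrates that the
*quantification chain* (ROI rasterization → exposure normalization →
femoral normalization → axial segmentation) is correct and unbiased, not
that the pipeline is robust to real-image nuisances.

### MRI tables

The MRI stage consumes per-slice scalars (the surrogate for manually traced
contours), not images.  Baseline vessel area tapers linearly,
`VA(x) = 10 mm² − 0.03 mm²/mm · x`, and each slice's VA is the baseline
times its segment's remodeling multiplier.  Per rabbit, 20 % of the
non-disrupted slices (at least 2) are designated *lesion-free* and carry a
multiplier of exactly 1; these anchor the taper fit.  CE and NC wall
intensities are drawn so that their ratio equals the segment's GdR target.
Slices sit at segment centres (4 mm pitch = 3 mm slice + 1 mm gap), so
slice↔segment registration is a bijection on replica geometry.

### Randomness

One root seed governs everything.  The replica disrupted-set draw uses the
root generator over a canonically sorted segment list; every other draw uses
a per-rabbit substream keyed by `(root_seed, sha256(rabbit_id))`, so adding
or reordering rabbits does not perturb the others, and a fixed (config,
seed) pair reproduces all artifacts byte for byte.

## Quantification conventions

- **FER**: arithmetic mean of pixel intensities under the ROI, divided by
  exposure (counts/s), then by the femoral reference of the *same* image.
  Mean (not integrated) signal is used; exposure normalization makes FER
  exposure-proof and reduces to the equal-exposure convention when exposures
  match.
- **Axial segmentation**: half-open intervals `[4i, 4(i+1))` mm anchored at
  the renal bifurcation; `floor(extent/4)` full segments, a partial trailing
  slot is dropped (keeps all segments equal-support).  A pixel column belongs
  to the interval containing its centre.
- **ROI rasterization**: a pixel belongs to a polygon iff its centre lies
  inside under the even-odd rule.
- **Taper correction**: OLS line of VA vs axial position fitted on
  lesion-free slices only; corrected VA = raw VA × fitted(anchor)/fitted(x),
  anchor = the series midpoint.  The linear model is the simplest one
  consistent with gradual vessel tapering; the anchor choice only sets a
  common scale and cancels in RR.
- **Reference slice**: minimum corrected VA (plaque area is not modeled
  separately, and least plaque implies least outward remodeling in this data
  model); ties go to the smallest axial position.  RR of the reference slice
  is exactly 1.
- **GdR**: CE/NC wall intensity of the matched slice, whole-wall scalar.

## Statistical engine

- **ROC**: thresholds are the unique observed scores plus a +∞ sentinel;
  classify disrupted when score ≥ threshold (the same direction for FER, RR,
  GdR and combinations).  AUC by the trapezoidal rule, which under this
  convention equals the pairwise rank-sum statistic with ties counted half —
  the tests verify the equivalence on a thousand random tied instances.
  AUC < 0.50 is flagged as a test failure.
- **AUC standard error**: Hanley–McNeil closed form (reported, never used
  for selection).
- **Operating point**: Youden J = sensitivity + specificity − 1, maximized
  over finite thresholds; ties resolve to the lowest threshold (favoring
  sensitivity).  The criterion is a choice — the study reports one
  (cutoff, sensitivity, specificity) triple per predictor without naming the
  rule, and Youden J is the standard one consistent with that.
- **Normalization**: min-max to [0, 10], pooled over both classes within an
  arm.  Any class-aware scaling would leak labels into the predictor.
- **Weight grid**: all vectors of 5 % multiples summing to 100 % (231
  vectors for three predictors), built from integer fractions so the weights
  are exact.  Weights are constrained to sum to 100 %, reading "percentage of
  contribution" literally.  Ties on AUC resolve to the vector with the
  largest weight on the first-listed predictor, then lexicographically —
  fixed purely for determinism.
- **Group comparison**: pooled-variance unpaired Student t-test, two-sided;
  SD with n−1 denominator.  No multiple-testing correction is applied
  (matching the analysis being reimplemented).
- Arms are analyzed separately by default (the pipeline's `build_report`
  accepts any merged table, so pooled analyses remain possible).

## Numerical and degenerate-input choices

- Degenerate femoral reference (≤ 1e-9 counts/s) and constant min-max input
  raise errors rather than returning infinities.
- A single-value group reports SD = 0 with a `degenerate` flag.
- Two constant equal groups give t = 0, p = 1 instead of 0/0.
- Taper fitting requires ≥ 2 lesion-free slices; the generator refuses
  configurations that cannot provide them (disruption probability ≈ 1).
- Report rebuilding from CSV uses round-trip float parsing so the rebuilt
  report equals the original bit for bit.

## Problem sizes and estimator choices

The shipped replica cohort (286 segments, 17 rabbits, ~0.5 s per full
pipeline run) is the package's reference problem size; the test suite runs
one shared replica study plus smaller cohorts for unit-level checks.
`scripts/acceptance.py` pools four replicate cohorts for the stochastic
group means: each replicate is the exact 286/47 design, and pooling merely
halves the standard error of the reported mean.  The uninformative-GdR check
averages the empirical AUC over 25 draws at the replica class sizes because
a single draw's sampling SE (≈ 0.046) is comparable to the effect being
excluded.

## Known limitations

- The generator matches printed means and SDs with truncated normals; the
  real FER distributions are evidently heavier-tailed (the printed group
  moments imply a binormal AUC ≈ 0.95 versus a reported FER AUC of 0.79), so
  the synthetic single-predictor AUCs are *higher* than the real ones.  The
  pipeline makes no claim of recovering the published AUC values, and no
  calibration toward them is attempted.
- The combined-predictor weights are optimized in-sample, exactly as in the
  procedure being reimplemented; reported combined AUCs are optimistically
  biased and no cross-validation is offered.
- No image-domain MRI processing, no automatic plaque/thrombus detection,
  no histology: ROIs and wall intensities are inputs by design.
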