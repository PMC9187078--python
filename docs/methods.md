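# Methods

## Problem and model

A CCE-2 capsule records the colorectum with a forward and a backward camera
as 576 × 576 stills. Ulcerative colitis severity is diffuse and mixed: one
frame routinely contains mucosa of several Mayo endoscopic subscores (MES
0–3), especially during healing. The pipeline therefore scores severity at
the scale of 128 × 128 windows and reports, per still, the *composition* of
severities rather than a single grade.

The per-still statistic is purely geometric. Windows are tiled at a
32-pixel stride (half-open [r, r+128) × [c, c+128) windows, 0-based
row/column coordinates), each eligible window receives one of six labels
(MES0–3, inadequate quality, ileal mucosa), and for each MES grade *k* the
class area is the **pixel union** of all windows with that grade:
`areaK = |⋃ S_i|`. The total is the arithmetic sum
`area0 + area1 + area2 + area3`. Because per-class unions are computed
first and then summed, a pixel covered by windows of two different grades
counts once in each grade — the total is a sum of unions, not a union of
unions. This literal reading is implemented exactly (boolean-canvas
rasterization) and tested against an independent pixel-set oracle; an
"exclusive assignment" variant is deliberately not offered. Windows graded
inadequate or ileal contribute to no area; a still whose total area is zero
is excluded and kept as a blank column, so the map's x-axis remains a
faithful positional axis along the colon (x encodes still index, not
transit time).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| patch size | 128 px | classification window side |
| stride | 32 px | tiling step; 225 windows on a native frame |
| blackout rule | > 1 % of pixels < 70 | window rejected (strict inequalities) |
| overexposure rule | > 5 % of pixels > 230 | window rejected; blackout checked first |
| intensity channel | Rec.601 luma | configurable to a single R/G/B channel |
| stills per segment | 50 | uniform sampling with endpoints, `round(i·(L−1)/(n−1))` |
| mask corner threshold | 30 | near-black level for field-of-view estimation |
| min window-inside fraction | 1.0 | window must lie entirely inside the mask |

On a 128 × 128 window the exclusion tipping counts are 164 dark and 820
bright pixels (163 and 819 keep the window); both boundaries are
unit-tested. The intensity rules are deliberately strict readings of
"< 70", "> 230" and "exceeds X %".

The field-of-view mask is estimated by flood-filling near-black connected
components that touch the image corners and inverting; degenerate inputs
(no dark corners, or an entirely dark frame) fall back to an all-true mask
and the intensity rules handle the content downstream. An explicit
single-channel PNG mask overrides estimation.

## Classification

The classifier is a pluggable scikit-learn estimator; two implementations
honour the same contract (6-way score vector summing to 1, label = argmax,
ties to the lowest class index, order-preserving batch prediction):

* **MLPPatchClassifier** — patches are bilinearly resized to 224 px
  (`input_side`), mean-pooled to 32 px, scaled to [0, 1], flattened, and
  standardized per feature on the training set; a multilayer perceptron is
  trained with Adam on cross-entropy loss. Defaults: learning rate 2.5e-4,
  50 epochs, batch 256, explicit seed. The per-feature standardization is
  part of the model (recorded in its normalization metadata): the pooled
  pixel features are dominated by a near-constant direction, and without
  standardization the optimizer sits at the chance-level plateau for any
  learning rate within a short epoch budget, while the standardized problem
  is solved easily. Training is deterministic for a fixed seed and data
  order; single-class or empty training sets are rejected. Optional
  inverse-frequency class balancing (by repetition) is available behind
  `class_weight="balanced"` and off by default.
* **OracleClassifier** — decodes the synthetic texture signature of each
  aligned 32 × 32 block (FFT peak + mean-level check) and takes a majority
  vote over blocks, ties to the lowest class. Patches without a decodable
  signature are graded inadequate with a warning. The oracle exists so the
  geometric stages can be verified end-to-end with exact ground truth,
  independent of any training run.

## Synthetic data: what it emulates, and what it does not

The generator paints each class as a gray vertical grating with a
class-specific spatial frequency (4–24 cycles per 128 px, multiples of 4 so
every aligned 32-px block holds an integer cycle count and the FFT bin is
offset-invariant) on a class-specific base level (105–205 in steps of 20),
amplitude 18, plus seeded uniform pixel noise in [−5, 5]. All texture
values stay inside (70, 230), so class textures never trip the intensity
rules by themselves; blackout and overexposure defects are painted at 10
and 250 and always trip them. Optional circular field-of-view vignettes are
exactly 0 outside the disc. All generators are bit-deterministic under a
fixed seed.

This emulates the *structure* of the problem — distinguishable local
texture classes, a circular optical field, dark corners, saturated
highlights, uninterpretable regions — not the appearance of mucosa. Real
capsule frames have correlated color, motion blur, fluid, bubbles and
continuous severity gradients. Passing the synthetic suite therefore
demonstrates that the geometry, exclusion logic, area accounting, mapping
and the training loop are correct; it says nothing about classification
accuracy on clinical images, and the packaged clinical accuracy tables are
not reproducible from synthetic data by construction.

Whole studies are generated from a severity script: per still either target
MES0–3 fractions (summing to 1) or "excluded". Fractions are realized as
vertical class bands; scripted values on the 1/18 grid put band boundaries
on 32-px block edges. Recovery tolerance: a band boundary falls inside a
window of up to 4 overlapping patches; majority voting moves the union edge
by at most one stride beyond the true boundary, so each recovered fraction
deviates by at most ≈ 32/576 ≈ 0.056 of frame width before union
normalization — in practice ≤ 0.042 for the default script — and ±0.05 is
the documented acceptance band. The default script covers healthy mucosa,
mixed severities, a blank (all-inadequate) still per camera in the
transverse segment, and a half-healed rectum, five stills per segment and
camera.

## Scaled-down training benchmark

The training sanity benchmark runs the MLP classifier on the synthetic
6-class set with a 3,000 / 600 stratified split, 10 epochs, learning rate
2.5e-4 and batch size 64, expecting ≥ 0.90 validation accuracy. Problem
sizes are desk-scale choices: 600 patches per class keeps generation and
training near ten seconds, and the batch size is scaled down with the
dataset so an epoch still contains a sensible number of optimizer updates
(batch 256 is the full-scale recipe for a ~480k-image corpus; on 3,000
images it would leave only 12 updates per epoch). With these conditions the
benchmark is stable across seeds.

## Evaluation fixtures

The packaged CSVs hold the raw validation confusion matrix (6 × 6 counts)
and the per-class training/validation composition of the clinical patch
classifier. Everything else is derived at run time: per-class accuracy
`diag/rowsum` and overall accuracy `trace/total` (half-up, 3 decimals,
computed on exact integer ratios), composition shares (half-up, 1-decimal
percent), and the cross-table consistency check that the confusion-matrix
row sums equal the validation composition. Two published values exist for
the clinical classifier's overall validation accuracy (0.973 and 0.983);
the packaged confusion matrix is arithmetically consistent with 0.983 and
that value is treated as authoritative — the discrepancy is noted here, not
resolved. The corresponding training confusion matrix was released only as
supplementary material and is not bundled; the known 940 MES3→inadequate
training miscount is mentioned for context only and not tested.

## Numerical and design choices

* Union areas are exact (boolean canvas); no approximation anywhere in the
  severity statistic.
* Percent exports round half-up to 1 decimal; rows may sum to 99.9/100.1
  and the raw fractions are emitted alongside.
* Rounded accuracies use exact rational arithmetic before half-up rounding,
  so printed 3-decimal values never suffer float representation error.
* Empty confusion-matrix rows yield NaN (flagged), never 0.
* The segment partition is a declarative manifest (the human reviewer's
  call), not inferred from telemetry; still sampling within a segment is
  uniform with endpoints included — a seed-free, least-assumption choice.
* The two classifiers are scikit-learn estimators because classification is
  genuinely fit/predict-shaped; the tiling, union and mapping stages are
  plain functions over typed containers — forcing them into transformer
  shape would obscure their contracts.
* Video ingestion accepts any indexable frame source (arrays, image file
  sequences, an open reader); container decoding is delegated to imageio
  and is only available where a suitable plugin is installed.

## Known limitations

* The MLP backend is a compact classifier appropriate for the synthetic
  benchmark's texture discrimination; grading clinical mucosa would require
  a modern convolutional architecture and the original training corpus,
  neither of which ships here.
* The oracle decodes only the package's own texture signatures.
* Partial-window mask overlap is all-or-nothing by default (`min_inside`
  is configurable but 1.0 by default).
* Band layouts in the study generator are axis-aligned; scripted fractions
  far from the 1/18 grid or below ≈ 0.2 per class recover less accurately
  than the ±0.05 band, because a class band narrower than a window cannot
  win a majority vote.
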