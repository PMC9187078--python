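# ccemap

Topographic severity mapping of ulcerative colitis (UC) from colon capsule
endoscopy (CCE-2) stills.

Colonoscopy grades UC mucosa with the Mayo endoscopic subscore (MES, 0–3),
but a single score per image hides the fact that severity often varies
*within* one frame and *along* the colorectum. `ccemap` implements the
alternative: grade many small windows of every capsule still, express each
still as the **mix** of severities it contains, and lay those mixes out as a
topographic map along the colon. It is written for GI imaging researchers and
tool builders who want the full pipeline — tiling, quality exclusion,
classification, area accounting, mapping and evaluation — as a tested,
scriptable library plus CLI.

## The method

For each 576 × 576 still (the native CCE-2 frame):

1. **Tiling.** 128 × 128 windows are trimmed at every 32-pixel stride over
   the effective (field-of-view) region — 15 × 15 = 225 windows on a full
   frame, enumerated left-to-right, top-to-bottom.
2. **Exclusion.** A window is dropped as *blackout* if > 1 % of its 16,384
   pixels have grayscale intensity < 70, or as *overexposed* if > 5 % have
   intensity > 230 (strict inequalities; Rec.601 luma).
3. **Classification.** Each surviving window is graded into six classes:
   MES0, MES1, MES2, MES3, inadequate quality, or ileal mucosa.
4. **Severity profile.** With the MES0 windows S₁ … Sₙ,
   `area0 = |S₁ ∪ S₂ ∪ … ∪ Sₙ|` (pixel-union area), likewise `area1..area3`;
   `total = area0 + area1 + area2 + area3`, and the still's severity is the
   stacked fractions `areaK / total`. If `total = 0` (every window
   inadequate/ileal) the still is excluded and drawn as a blank column.
5. **Topographic map.** Profiles are ordered per camera (forward/backward)
   along cecum + ascending → transverse → descending + sigmoid → rectum and
   rendered as serial stacked bars (light gray / yellow / magenta / red for
   MES0–3).

Classification is pluggable: a trainable multilayer-perceptron classifier
(Adam, cross-entropy, seeded) and a deterministic *oracle* classifier that
decodes the synthetic texture signatures, so the geometric stages can be
verified end-to-end with exact ground truth. The `metrics` module recomputes
accuracy tables from the packaged validation confusion matrix of the
clinical patch classifier (483,644 training / 255,377 validation patches),
which is the package's exact, data-free evaluation surface.

## Worked example

Generate a synthetic dual-camera study with scripted severities, run the
pipeline with the oracle classifier, and inspect the outputs:

```sh
ccemap synth --out study --seed 1 --n-per-segment 5
ccemap run --input study --out results_demo --classifier oracle
ccemap eval
```

`results_demo/` then contains `patch_inventory.csv` (every grid window with
its exclusion decision), `severity_table.csv` (one row per still with raw
union areas, fractions and 1-decimal percentages), `topographic_map.png`
(the stacked-bar map, blank columns where stills were excluded) and
`topographic_map.json`. `ccemap eval` prints the recomputed reference
tables:

```
validation per-class accuracy:
  MES0       0.994  (n=109721)
  MES1       0.948  (n=14753)
  MES2       0.913  (n=3507)
  MES3       0.952  (n=20736)
  INADEQUATE 0.986  (n=106577)
  ILEAL      0.892  (n=83)
overall accuracy 0.983 (251126/255377)
```

i.e. the clinical classifier graded 251,126 of 255,377 held-out patches
correctly, and (from the composition table that follows) 52.4 % of all
739,021 patches were of inadequate quality — the price of uncontrolled
in-vivo imaging, absorbed by the union-area formulation because a single
interpretable window suffices to score a still.

The same flow is available as a library:

```python
from ccemap import generate_study, make_oracle_classifier, process_stills

bundle = generate_study(seed=1)
tmap = process_stills(bundle.stills, make_oracle_classifier(),
                      study_id=bundle.study_id)
profile = tmap.track(list(tmap.tracks)[0])[0]
print(profile.fractions)   # e.g. (1.0, 0.0, 0.0, 0.0) for a healthy still
```

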