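# Methods

## The measurement model

Gastric ulceration presents as erythema: increased mucosal blood flow reads
as elevated red-channel values in an RGB photograph. The pipeline treats
severity as an area measurement — the fraction of analysable tissue whose
red value reaches a threshold — and expresses it as an ulcer index

    UI = 100 × erythema_fraction / mean(control erythema_fractions),

so the untreated control group's mean is 100% by construction. The method
assumes erythema is separable from normal tissue on the red channel alone;
no hue ratio, texture, or learned segmentation is used, and depth is not
modelled (the score is strictly two-dimensional).

All arithmetic is on raw 8-bit sRGB values without gamma linearisation:
the acquisition protocol the method models controls lighting physically
(dark room, strobe, color card) rather than in color-managed software.
One figure caption in the source clinical material gives the RGB range as
0–225 where every other statement says 0–255; this package treats 0–255 as
canonical and regards the 225 as a typo.

## Pipeline stages and their parameters

**Color-card correction** (`correct_with_card`). For each channel, an
affine map `ref = gain × measured + offset` is fitted by least squares over
the card's patch means and applied to all pixels, then clipped to [0, 255].
The affine-per-channel form is the minimal model that makes identity cards
a no-op and pure exposure errors exactly correctable; the commercial
card-calibration software the protocol used does not publish its transform,
so this is a design choice of this package. Cards need ≥ 2 patches; a card
whose measured patches are identical in some channel cannot be fitted.

**Channel shielding** (`shield_channel`). A cellophane film of one color in
front of the lens makes the other color markers disappear; computationally
the designated channel is kept and the other two set to 0. Hard zeroing
(not spectral filtering) is deliberate: it reproduces the complete
disappearance of the blinded colors and is idempotent.

**Low-red suppression** (`suppress_low_red`). Normal tissue carries a
nonzero red value that would inflate the erythema count; pixels with red
below the threshold are set to (0,0,0) and excluded from the foreground
mask. Pixels at the threshold are kept (`>=` convention throughout).

**Brightness levels** (`adjust_brightness`). Levels follow the clinical
high/medium/low convention — 50 bright (×2), 100 as shot (identity), 200
dark (×0.5) — implemented as a per-channel scale of 100/level, rounded
half-up (deterministic across platforms; numpy's default banker's rounding
is not used), clipped to [0, 255]. Level 50 followed by 200 is the identity
wherever no clipping occurred.

**Tissue mask** (`tissue_mask`). Near-white pixels (min channel ≥
`white_cutoff`, default 240) are specular glare or gastric juice; near-black
pixels (max channel ≤ `black_cutoff`, default 20) are unlit background.
Both are excluded before any counting. The defaults exclude the synthetic
specular patch (252,252,252) and black borders without touching tissue
pinks around (205,145,150).

**Segmentation** (`segment_erythema`). Erythematous = tissue AND red ≥
threshold. The clinical protocol bisected the damage zone "per the medical
doctors' suggestions" without stating a number, so the default threshold is
Otsu's method on the tissue-masked red histogram — automatic and
reproducible — with an explicit override everywhere. scikit-image's Otsu
splits classes as (≤ t | > t) while segmentation here uses ≥, so the
returned default is the Otsu value + 0.5, placing the cutoff strictly
between the two classes of an 8-bit histogram. Raising the threshold never
increases the erythema count. A dark-spot detector (`detect_dark_spots`,
max channel < cutoff, default 100) covers the stress-ulcer (WIRE)
phenotype, whose lesions are dark rather than red; the exact clinical
criterion for that phenotype was never published, so the cutoff is exposed.

**Relief maps** (`relief_map`). Channel value / 255, giving [0, 1] heights
monotone in color density; normalised rather than raw so the array exports
scale-free to any 3D viewer.

**Calibration** (`fit_standard`, `predict_concentration`, `bin_severity`).
The erythema standard is whole blood serially diluted two-fold (50%, 25%,
12.5%, 6.25%, 3.125%, plus a 0% blank) and photographed in a 6-well plate.
The response is regressed on concentration by closed-form OLS
(covariance/variance form), with R² = 1 − SS_res/SS_tot. Degenerate cases
are pinned: identical concentrations are an error; identical responses fit
slope 0 with R² defined as 0. The reference line for this standard is
y = 0.4432x − 0.0282. Inverse predictions are clamped to [0, 0.8] — the
line gets applied to whole photographs where out-of-range responses occur,
and the clinical severity range is 0–80% blood-concentration equivalent.
Severity bins are 10% wide over [0, 0.8]; only the range and the ~60%
severe balance point are clinically fixed, and 10% bins make 60% a bin
edge. The severe flag is concentration ≥ 0.60. Which image statistic plays
the response "y" is not fixed by the protocol; any response column is
accepted, and the synthetic plate defines its own (mean red of the well
ROI, divided by 255).

**Rubric scoring** (`cco_score`). Small round corrosion 1 pt; linear
lesions by length band: < 1 mm → 2, [1, 2] mm → 3, (2, 3] mm → 4, > 3 mm →
5. The published bands leave (3, 4] mm unassigned ("4 points for 2–3 mm,
5 points for > 4 mm"); the default extends the 5-point band down to > 3 mm
so the rubric is monotone and gap-free, and `gap_policy="four_to_4"` keeps
the literal bands by extending 4 points up to 4 mm instead. "Scores were
added and doubled when the width was > 1 mm" admits two readings: the
default doubles each wide lesion's own points (order-independent and
granular); `doubling="total"` doubles the grand total when any lesion is
wide. Band boundaries are closed on the side stated first ("1–2 mm" =
[1, 2]).

**RGB-mean classification** (`mean_rgb`, `classify_rgb`). The image's mean
channel value (all three channels by default; `red_only=True` available,
since the clinical description does not pin this down) is assigned to the
nearest of three fixed class centroids — normal 247.964, mild 233.184,
severe 206.857 — equivalent to midpoint thresholds 240.574 and 220.0205.
Ties within 1e-9 break toward the more severe label. The centroids came
from a 140-image clinical reader study that is not deposited; they are
constants here, overridable per call and via the CLI.

**Agreement** (`rater_sd`, `bland_altman`). Per-subject sample SD (n−1
denominator — panels are small, typically 8 raters) across raters, and
Bland–Altman bias ± 1.96 · SD of paired differences. 1.96 is the standard
multiplier; the source protocol cites the method without the constant. No
significance test of LoA differences is implemented: how "significantly
lower reproducibility" was assessed was never stated.

## Synthetic fixtures

Generators are pure functions of spec + seed, using
`numpy.random.default_rng` (PCG64) so fixtures are bit-stable.

* **Gastric images** (default 512×512, background pink (205,145,150),
  pixel noise SD 2): the ethanol phenotype paints elongated ellipses
  (aspect 6:1) with red 220; the stress phenotype paints dark spots
  (60,45,50). The union of painted ellipses is grown to the requested area
  fraction (within 10% for targets in [0.01, 0.3]); the requested lesion
  count is a minimum, as small filler lesions top up rasterisation
  shortfall. Lesion color is applied before noise, so image and mask are
  consistent by construction.
* **Well plates**: one disk per dilution whose red value is
  255 × (slope·x + intercept + noise), noise on the response scale,
  clipped to [0, 255]. Clipping means curves with a negative intercept
  (like the reference line) flatten at the blank; round-trip recovery
  tests therefore use a non-negative-intercept curve, where refitting
  measured well means recovers slope/intercept within the ±0.5/255
  quantisation propagated through the design (~0.01 on the slope).
* **Rater panels**: cell = true UI + N(0, method SD), floored at 0;
  default SDs 15 (manual rubric) vs 3 (image analysis) encode the expected
  reproducibility ordering, and panels default to 8 raters.

What the fixtures do **not** emulate: real tissue texture, vignetting and
lighting gradients across the organ, JPEG artefacts, specular shape
variety, or correlated rater bias. Passing tests therefore demonstrate the
pipeline's arithmetic and its behaviour under idealised contrast and noise,
not segmentation performance on clinical endoscopy.

## Numerical choices

* Rounding after any scaling is half-up (`floor(x + 0.5)`), then clipping.
* Severity-bin indexing adds 1e-9 before flooring so exact bin edges
  (0.6/0.1 in binary floating point) land in the correct bin.
* R² is clipped into [0, 1] against floating rounding on perfect fits.
* Empty tissue masks, empty control groups, zero control means, zero-slope
  inversions, single-rater panels, and degenerate card/standard fits all
  raise rather than returning NaN.

## Problem sizes

The test suite uses 512×512 synthetic images, 32×32 random images for the
brute-force segmentation oracle, 1,000 replicates for the calibration
Monte Carlo, 10,000 pairs for the Bland–Altman sampling check, and 500
seeds for the reproducibility-ordering simulation; the whole suite runs in
a few seconds on one CPU.

## Known limitations

* Otsu's default threshold assumes a bimodal red histogram; on lesion-free
  images it bisects background noise and over-segments. Group comparisons
  should carry one threshold across images (as the CLI `index` command does
  when `--red-threshold` is given), or rely on a clinician-chosen value.
* The classifier centroids are fixed constants from a clinical reader
  study; they are not re-derivable here and will not transfer to other
  cameras or lighting without recalibration.
* Red-channel thresholding confounds erythema with any red, well-lit
  structure; the brightness-level ops exist precisely because the measured
  area is sensitive to exposure.
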