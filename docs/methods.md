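# Methods

## The FNF compositing model

The acquisition model assumes two frames of the same static scene taken
nearly simultaneously: a no-flash frame `N = clip(q(A))` and a flash frame
`F = clip(q(A + L))`, where `A` is the ambient contribution, `L` the
artificial-light contribution and `q` the sensor's 8-bit quantization.
For pixels where neither frame clips, the composite `C = max(F − N, 0)`
equals `L` up to one intensity unit of quantization error — the scene as
lit by the artificial source alone, independent of ambient intensity,
color cast or shadow structure. Two deviations from this ideal are handled
explicitly:

* **Sensor saturation.** A flash pixel with any channel at
  `saturation_level` (default 255) has lost the incident-light
  information; subtracting ambient from it produces color artifacts. Such
  pixels are excluded from subtraction and the flash value passes through
  unchanged. Pass-through keeps the fruit visible (rather than punching
  black holes into it) at the cost of retaining the ambient color cast in
  exactly those pixels; this residual is the main source of color spread
  left in composites under very strong ambient light. A pixel counts as
  saturated if *any* channel clips, which is conservative: a single
  clipped channel already distorts hue.
* **Negative differences.** Noise can push `F − N` below zero; negatives
  are clamped to 0 to keep a valid 8-bit image.

**Pair identification.** Real rigs alternate the light between frames,
but dropped frames and variable frame rate break strict alternation, so
pairs are recovered from the stream by brightness: a frame followed by a
frame whose mean intensity is lower by more than
`brightness_delta_threshold` (default 10 on [0, 255]; rig-specific in
practice) is taken as a flash/no-flash pair, and the scan advances past
both frames. Requiring the flash frame to *precede* its no-flash partner
reflects the trigger sequence (light fires, then the ambient-only
follow-up frame) and makes the pairing unambiguous when a dropped frame
leaves a dark frame stranded between two pairs: in a stream
`[bright, dark, dark, bright, dark]` the pairs are (0, 1) and (3, 4), and
the stranded frame 2 is skipped. Ties at the threshold are rejected
(strict inequality). The threshold is deliberately far above the
brightness jitter of consecutive ambient frames and far below the mean
gain a near-range flash produces (≥ ~11 intensity units under the
simulator's default conditions).

## The color-blob detector

The pipeline is deliberately naive: RGB → HSV; keep pixels with hue in
[`hue_min`, `hue_max`] = [20°, 50°] *and* saturation in
[`sat_min`, `sat_max`] = [90, 255] (bounds inclusive; the value channel is
unconstrained); morphological cleanup; 8-connected components; drop
components smaller than `min_area_ref` = 400 px, scaled linearly with
pixel count relative to the 320×240 reference resolution (so 1600 px at
640×480); report each surviving blob with its tight half-open bounding
window.

Morphological cleanup is opening (3×3 square), closing (5×5 square), then
filling of enclosed holes, all configurable. The opening removes isolated
noise pixels — without it, sensor noise in dark composite regions yields
sparse in-band pixels that the closing would weld into fruit-sized false
blobs. The closing bridges small gaps and is what merges touching fruit
into a single blob; that cluster-merge behavior is deliberate and is
scored explicitly by the evaluation protocol rather than suppressed.

**Calibration.** Field systems re-tune thresholds per greenhouse and
cultivar from a handful of images. `calibrate_thresholds` replaces an
interactive session with a reproducible percentile rule over the
fruit-labeled pixels of at most a few images: hue band = 1st–99th
percentile widened strictly outward to whole degrees (a degenerate
single-hue sample still yields a ±1° band), `sat_min` = 1st percentile of
saturation, `sat_max` = 255. The 1 %/99 % trim discards the mixed-color
boundary pixels of the label masks.

## Evaluation protocol

Detections and labeled fruit are matched by bounding-box IoU at a 50 %
threshold, greedily in descending IoU with ties broken by (truth index,
detection index); each detection and each truth is used at most once.
Matched pairs are classified by the truth's maturity: mature → TP;
partially mature → TP under the *flexible* scheme, FP2 under *strict*;
immature → FP1; distant (out of working range) → DC, which is ignored
entirely — it enters neither precision nor recall. Unmatched detections
are FP; unmatched countable truths (mature, plus partially mature under
flexible) are FN. Precision = NTP/(NTP+NFP) and recall = NTP/(NTP+NFN)
with FP1 and FP2 folded into NFP; a zero denominator yields an explicit
undefined marker (`None`), never 0 or 1.

**Cluster credit.** Merged cluster detections mislocalize but rarely cost
a harvest, because visual servoing re-detects during the approach. The
cluster-credit mode therefore counts every countable fruit with at least
`containment_threshold` (default 50 %) of its mask pixels inside a single
detection blob as a TP; a detection covering at least one countable fruit
is credited once; a detection covering nothing is a plain FP. By
construction cluster-credit TP ≥ per-object TP and FN ≤ per-object FN on
identical inputs.

**Color-stability statistics.** For a chosen maturity class, hue and
saturation are pooled over all labeled pixels of all scenes, normalized to
[0, 1] (hue /360, saturation /255), and summarized as population standard
deviations plus 100-bin histograms. Hue is treated as linear, not
circular: pepper hues (≈ 20–110°) sit far from the 0°/360° wrap point, so
the linear approximation is exact in practice. Comparing the statistics
between composites and flash-only frames quantifies the color constancy
the compositing buys.

## The scene simulator

Each synthetic scene is a depth-ordered painter's rendering at 320×240:
every surface has an illumination-independent RGB reflectance in [0, 1],
and the two frames are

```
noflash = clip(round(R · A_ambient + ε))
flash   = clip(round(R · (A_ambient + 255 · I_f / d²) + ε'))
```

with independent Gaussian sensor noise `ε, ε' ~ N(0, σ)` (σ = 2 by
default) and per-pixel depth `d`. The flash falloff is exactly
inverse-square; `I_f = 0.023` puts ≈ 160 intensity units on a perfect
reflector at the 0.19 m working distance and under 16 units beyond the
0.6 m distant-fruit cutoff, so out-of-range fruit stays dark in the
composite. The ambient term is the product of a global intensity
(`ambient_base` = 100 units at `ambient_intensity` 1, drawn per scene from
U[0.2, 2.0]), a directional linear gradient (low sun), and a smooth random
*dapple* field standing in for foliage-cast patchy hard light: sunlit
patches are brighter and carry one per-scene illuminant tint, shaded
patches are dimmer and carry a second (skylight) tint, each channel tint
drawn from U[0.3, 1.7]. Ambient chromaticity thus varies both across
scenes and across a single fruit, which is what defeats fixed color
thresholds on flash-only frames; the composite cancels all of it except
in sensor-saturated pixels, which the clipping model produces genuinely
under strong warm casts.

Scene content: one to three target peppers (ellipses, semi-axes 16–26 px,
depth 0.16–0.22 m) with a 35 % chance of an adjacent overlapping cluster
partner; maturity drawn as 60 % mature / 25 % partially mature / 15 %
immature. Mature hue is N(35°, 2.5°) — a single ripe cultivar is
chromatically uniform — immature hue N(105°, 8°); reflectance saturation
N(205, 6) and value N(160, 8) on the 8-bit scale, the value chosen so the
flash frame clips only in the extreme ambient tail (strong ambient *and*
strong warm tint) rather than routinely, matching a rig whose exposure is
set for the flash frame. Partial maturity is a sigmoidal hue ramp along
the fruit's major axis: a `maturity_level` fraction of the surface carries
the mature hue, so the chance of detecting a partially mature fruit grows
with its maturity. Occluding leaves (0–2, at 0.12–0.16 m) create genuine
false negatives; a mid-depth foliage canopy (22–30 large leaves at
0.23–0.33 m) fills most of the frame within flash range — it carries the
flash/no-flash brightness difference that pair identification relies on —
and distant mature fruit (depth 0.8–1.6 m, 40 % of scenes) shows through
its gaps, exercising the ignored DC class. The deep background (2–3 m) is
dark foliage with negligible flash contribution.

Ground truth is derived from the painter's ownership map: each pepper's
mask is its *visible* pixels (a fully occluded fruit is not labeled),
bounding boxes are tight, and peppers beyond the distant cutoff are
labeled `distant` regardless of color. Everything is deterministic given
the scene seed; dataset generation derives per-scene seeds from one master
seed via `numpy` seed sequences, and repeated runs are byte-identical.

### What the simulator does and does not show

The generator reproduces the *mechanisms* the method depends on — ambient
cancellation up to quantization, inverse-square falloff, sensor
saturation, cluster merging, occlusion, maturity-dependent color — under
controlled conditions where ground truth is exact. Under the default
conditions (50 scenes) the detector on composites reaches ≈ 0.95–1.00
precision and recall in the flexible cluster-credit scheme while the same
detector on flash frames loses 8–15 recall points, and mature-fruit hue
spread on composites is ≈ 0.4× that on flash frames. It does **not**
render real fruit texture, specular highlights, leaf venation, motion
between the two frames, or the spectral response of a real sensor, so
passing tests demonstrate correctness of the pipeline and the direction
and rough magnitude of the FNF advantage — not field-level absolute
performance, which depends on the crop and rig.

## Numerical choices and degenerate inputs

* All image arithmetic is integer (int16 differences, uint8 storage); the
  compositing rule is exact, with no float round-trip.
* HSV conversion keeps hue in degrees [0, 360) and S, V in [0, 255] as
  floats; quantization happens only at image boundaries. RGB→HSV→RGB
  round-trips within ±1 intensity unit per channel.
* Thresholds written as unit fractions in config files (`20/360` style)
  are converted at the config boundary; internally hue is always degrees.
* Zero-area boxes are rejected by `iou`; empty datasets, empty label
  masks, and unknown label codes raise immediately with the offending
  scene or code named.
* Greedy matching ties (equal IoU) break deterministically by truth index
  then detection index; connected components are reported in raster-scan
  order of first pixel.
* Problem sizes: the test suite and the acceptance script use 50 scenes at
  320×240 for dataset-level checks and 8–20 scenes for sweeps and
  consistency checks — large enough for stable aggregate rates at the
  reference resolution.

## Known limitations

* The cluster-credit precision denominator credits a covering detection
  once however many fruit it covers, which can make cluster-credit
  precision exceed per-object precision on cluster-heavy data; this is
  inherent to the measure, not a bug.
* The brightness-based pair scan assumes scene radiance changes slowly
  relative to the frame rate; a sudden global illumination change between
  two frames can masquerade as a flash event.
* Threshold calibration assumes the labeled fruit pixels are
  representative; it does not model class imbalance across maturity
  levels.
* Hue statistics are linear; for crops with hues near the red wrap point
  the circular standard deviation would be required.
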