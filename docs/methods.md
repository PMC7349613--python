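# Methods

## The identification problem

A feeding-station camera sees up to five stalls; each cow that inserts
her head wears a yellow ear tag printed with a barcode band, four large
work-number digits, and a trailing mini digit. The package recovers,
per 30-frame window, which stalls are occupied and by which work
number. The stages and their constants are described below together
with the choices made where the procedure left room.

## Tag detection and quality gates

Candidate tags are connected components of an HSV threshold mask
(closed intervals, H ∈ [0.082, 0.263], S ∈ [0.072, 0.559], V free). A
3×3 morphological closing bridges mask holes before labelling;
components under 100 px are speckle and dropped; component boxes are
padded by 4 px so the tag outline stays interior to the crop (the
Hough stage needs its edges).

Quality gating uses a tighter preset (H ∈ [0.128, 0.345],
S ∈ [0.067, 0.582], V ≤ 0.667). *Pixel density* is the mask's
foreground count: the initial gate accepts 400–2700 at native size
(both bounds inclusive — the source leaves this open), which brackets
plausible tag sizes; the standard gate, after bilinear resize to
200 × 200, requires density strictly above 15,500 and RMS contrast in
[0.17, 0.65]. "Contrast" is not defined by the source; root-mean-square
contrast (standard deviation of unit-scaled grayscale) was chosen
because it is parameter-free, and legible renders land inside the
printed band while heavy blur falls below it. Density is evaluated at
native crop size for the initial gate (also an open point; the chosen
reading makes the bounds a size gate, which matches their magnitudes).

## Skew normalization

The tight-preset mask is edge-detected with the Prewitt operator and
fed to a probabilistic Hough transform (fixed internal seed, so
detection is deterministic). Among lines inclined at most 45°, the
longest wins; ties break toward smaller |θ|. θ = atan((y₂−y₁)/(x₂−x₁))
with image y growing downward, so a baseline sloping down-to-the-right
has positive θ. Deskewing rotates by −θ about the centre with bilinear
interpolation, expands the canvas, and fills uncovered pixels with the
median border colour. Recovery accuracy on renders skewed uniformly in
[−15°, 15°] is within 2° in ≥ 90% of cases (tested).

## Digit segmentation

The crop is binarized (grayscale → invert → histogram equalization →
threshold). The threshold is selected by Otsu's method on the
*pre-equalization* intensities: equalization is a monotone map, so this
is identical to thresholding the equalized image at the mapped value,
while running Otsu directly on the rank-uniformized histogram is
degenerate (it splits the dominant class by sensor noise).

*Border removal* trims rows edge-inward while their projection is below
half the width, re-cuts and re-preprocesses the RGB, then trims columns
while below two-thirds of the height. Trimming stops at the first
violating row/column (interior rows are never tested).

*Barcode exclusion*: valley points of the row projection — indices
strictly lower than both neighbours, with a flat run flanked by higher
values counting once at its centre — are candidates when their value is
below half the width (a value comparison; indices are compared to the
height elsewhere). The band ends at the first candidate deeper than a
quarter of the height and starts at the prior candidate (row 0 if
none). The band end starts the digit area when the remaining height
exceeds 1.7× the band height and the band holds an object wider than
half the width; otherwise a fallback takes the row of minimum
projection among the estimate 0.45 × height, the nearest valley, and
its two neighbours. The 0.45 fraction is applied to the *height* (the
source text says "width" for what is a row coordinate; treated as an
erratum, with `start_fraction_axis` in the config to restore the
literal reading). On renders with the band wiped out, this minimum
genuinely lies in the empty gap above the digits rather than at the
digit top — harmless downstream, and asserted as such.

*Column cuts*: column-projection valleys deeper than half the height
are discarded; the surviving valleys plus the image edges are cut
candidates; a candidate survives only if it bounds at least one gap
wider than one-sixth of the width, and spans narrower than that minimum
are dropped. Ideally four spans result; three to five are tolerated and
flow through (real readings are often partial — the confirmation stage
exists for exactly that reason).

*Object determination*: within each span the RGB is thresholded at
gray < 150; an object is a digit when it is narrower than tall and
taller than two-thirds of the span. One object → its bounding box is
cropped; several → split lines midway between adjacent objects; none →
the span is rejected (this is what eliminates the mini digit and border
fragments). Digit crops are normalized to 64 × 32 binary images
(grayscale → complement → equalize → binarize → resize), with the
binarization threshold estimated on the central 70% of the crop so
margin pixels leaking in from outside the digit cannot dominate the
histogram.

## Digit classifier

Architecture: conv 16@5×5 (valid) + batch normalization + ReLU,
conv 32@3×3 + ReLU, conv 32@3×3 + ReLU, average pooling 2×2 stride 2,
fully connected 100 (ReLU), fully connected 10, softmax. Input 64 × 32
binary, zero-centred. Training: SGD with momentum 0.9 (chosen; the
solver is specified but not its momentum), learning rate 10⁻⁴, batch
size 64 (chosen), up to 10 epochs with early stopping once a one-tenth
validation split reaches 99.8% — on the synthetic set this triggers
after the first epoch. The implementation is plain numpy: im2col with
one BLAS matrix product per convolution, float32 throughout; a full
1000-per-class training runs in roughly three minutes on one CPU. A
deterministic normalized-cross-correlation template matcher (per-class
mean glyphs) provides a training-free classifier so pipeline tests do
not depend on SGD runs.

The trainer's random stream uses a compound seed so that passing the
same integer to the dataset generator and the trainer cannot make the
validation split coincide with a generation-order artifact.

## Confirmation

Check lists derived from the roster: the 4-digit list (the roster), the
3-digit list of delete-one-digit subsequences (four per tag — chosen
over contiguous substrings as the reading consistent with "three
correct digits"; a config switch restores the other), and four
per-position 1-digit indices. Hamming≤1 candidates for a length-4 cut
are the union over position-triples of the intersected 1-digit indices
— provably equal to brute-force Hamming matching, which the tests
assert at scale.

The decision tree: length < 3 → D1. Length 3: unique 3-digit hit → S1;
several with a history hit → S2; several without → D3; none → D2.
Length ≥ 4: the first left-to-right length-4 window found verbatim in
the roster → S3 (history is *not* consulted — the worked example saves
an exact roster member at a position whose history holds a different
cow); otherwise Hamming≤1 candidates pooled over all windows: one → S4;
several with a history hit → S5; several without → D5; none → D4.
Non-digit sentinel characters are stripped before the length test;
an absent reading behaves as the empty string. History per (camera,
position) is the most recently saved tag, falling back to the rolling
final-list entry. The final list updates every 30 frames with the modal
confirmed tag, ties breaking toward the most recent.

## Temporal decision

Tumbling (non-overlapping) 30-frame windows; trailing partial windows
are discarded. A stall is occupied when heads were detected there in
strictly more than 50% of the window's frames. Percentages are
truncated toward zero (5/30 reports as 16%), which the worked example
fixes. The same mechanism smooths the tag stream; presence is decided
from head boxes alone, with the tag attached when one was confirmed
(whether presence should require a confirmed tag is ambiguous in the
source; head-box presence was chosen, and the tag table runs in
parallel).

## The synthetic renderer, and what it does not show

The renderer emulates the tag format — printed frame, barcode band,
four digit cells, trailing mini digit — with exact ground truth
(boxes, band rows, skew) by construction, plus five-stall scenes with
dark elliptical head proxies, digit training sets, and noisy
recognition streams (per-digit drop/substitute, per-gap insert,
per-frame miss probabilities).

Design choices that make the renderer a *fair* substrate for the
pipeline's fixed thresholds:

* Digits are printed in reverse video: a light glyph punched out of a
  solid dark cell. Any real sans face drawn dark-on-light has glyph
  columns with little ink ('1' beside its stem, '7' under its bar),
  which the half-height valley-discard rule cannot tell from true
  inter-digit gaps; solid cells give the column profile the structure
  the method implicitly assumes of its (unknown, evidently very heavy)
  tag typeface. The punched glyph's gray (~72) groups with the cell
  under both the adaptive tag binarization and the fixed gray < 150
  threshold, while the per-digit binarization separates them.
* Print is dark orange (hue 0.10): inside the wide detection ranges
  (the whole tag is one mask component and coverage stays ≈ 100%) but
  below the tight range's hue floor, so pixel density counts the
  yellow field only — as it does on real tags, whose print is not
  yellow — which is what makes the printed 400–2700 native-density
  band correspond to realistic tag sizes (~27–68 px).
* Backgrounds and head proxies are achromatic, so sensor noise cannot
  push them across the saturation thresholds.
* Glyphs come from two open faces bundled with matplotlib
  (DejaVu Sans Bold, DejaVu Sans Mono Bold), stretched to the cell.
* All randomness flows through one seeded generator per call; renders
  are byte-identical across runs.

What passing tests therefore show: the *rules* — thresholds, profiles,
valley logic, check lists, windowing — behave exactly as specified, and
the chain is robust to the modelled noise (blur, occlusion blobs,
rotation, per-pixel noise, OCR-style string corruption). What they do
not show: performance on real farm imagery, where fur, lighting,
perspective, motion blur and the actual tag typeface differ from the
renderer in ways no synthetic margin can certify. Reported accuracies
on real herds are out of scope here, and the head detector the package
bundles is a stub/blob detector, not a trained object detector (the
interface accepts one).

## Known limitations

* Rotation-only normalization; perspective (keystone) distortion is
  not corrected.
* Rosters must consist of 4-digit work numbers; fuzzy matching beyond
  Hamming distance 1 is out of scope.
* The blob head detector is tuned to the renderer's scenes; real
  deployments should plug in a trained detector.
* The segmentation fallback start point (barcode occluded) can sit
  well above the digit band; subsequent stages tolerate this, but the
  start row itself is not a digit-top estimator.
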