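# Methods

`slidequant` studies how lossy JPEG2000 compression and image
downscaling change the output of two automated histology image-analysis
methods: an area-based immunohistochemistry (IHC) scorer and a
texture-based epithelium/stroma classifier.  The real inputs such
studies use — whole-slide scans of stained tissue-microarray (TMA)
cores — are not publicly packaged, so all experiments here run on
synthetic histology-like scenes with known ground truth.  This note
documents the models, the defaults and why they were chosen, and what
results on the synthetic scenes do and do not show about real slides.

## IHC scoring by colour deconvolution

Brightfield absorption follows the Beer–Lambert law: a pixel's optical
density `OD_c = -log10(I_c / 255)` (per RGB channel `c`, with `I`
clamped to at least 1) is a non-negative combination of unit-length
stain vectors.  With the Ruifrok–Johnston H-DAB matrix — haematoxylin
(0.650, 0.704, 0.286), DAB (0.268, 0.570, 0.776), residual = their
normalized cross product — stain concentrations are the projection of
OD onto the inverse matrix.  Each concentration is mapped back to 8-bit
transmittance `255·10^(-conc)`, the ImageJ-plugin convention in which
darker means more stain, so a pixel is stain-positive when its channel
value falls *below* a global threshold.

The two summary statistics are

* **extent** = |DAB⁺| / |H⁺ ∪ DAB⁺| — the share of stained tissue that
  is DAB-positive (0 for a blank image);
* **intensity** = mean DAB-channel value over DAB⁺, rescaled linearly
  so the DAB threshold maps to 0% and maximal stain (value 0) to 100%.
  Anchoring at the threshold keeps intensities comparable across
  threshold choices; an empty DAB mask reports 0%.

Thresholds are global constants calibrated once on five synthetic cores
(`examples/calibrate_thresholds.py`) and frozen at `h=149`, `dab=151`:
the deconvolved channel value of a pixel exactly half covered by its
stain.  This anchoring matters for the scaling experiment: pixel
blending under box downscaling happens in transmittance while
deconvolution works in log space, so the half-coverage value is *not*
the midpoint of the stained and background channel levels (the
convexity is strongest for DAB, whose positive nuclei also absorb
along the haematoxylin direction).  Half-coverage thresholds count a
pixel as positive exactly when stain covers at least half of it, so
measured areas — and their ratio, the extent — stay unbiased as
resolution drops; channel-midpoint thresholds leave a systematic
downward extent bias of about 0.02 by scale 1:8, and thresholds placed
asymmetrically destroy the statistic several octaves earlier.

## Texture classification by LBP + VAR and a linear SVM

Images are halved (box filter), converted to grayscale with weights
`0.2989 R + 0.5870 G + 0.1140 B`, and background glass (gray > 240) is
removed; the tissue mask is smoothed by morphological closing then
erosion with a disk of radius 5 (the brightness threshold and disk size
are configuration values — sensible defaults, not calibrated claims).

The local binary pattern operator samples P neighbours on a circle of
radius R around each pixel (bilinear interpolation off-grid; first
sample at offset (0, +R), counter-clockwise; neighbour ≥ centre → bit
1).  Uniform patterns — at most two 0/1 transitions around the circle —
map to their bit count, all others to one extra code, giving the
rotation-invariant uniform (riu2) alphabet of P+2 codes.  LBP is
invariant to any monotone gray-level change and discards contrast, so
it is paired with the rotation-invariant local variance VAR of the same
P samples (population variance, 1/P).  VAR is quantized into Q = 8 bins
whose cut points are the equal-occupancy quantiles of VAR pooled over
the *training* images' tissue pixels, learned once and frozen (no
test-time information reaches the quantizer).  Interpolated samples are
snapped to the nearest integer when within 1e-8 so that the tie
convention is stable against floating-point residue.

Features are joint (LBP code, VAR bin) occurrence histograms over
80×80-pixel elements placed on a 40-pixel grid (50% overlap, anchored
top-left, no partial windows); an element is processed if at least half
of it is tissue.  The two scales (P=8, R=1) and (P=16, R=2) give
(8+2)·8 + (16+2)·8 = 224 bins, normalized to unit Euclidean norm.

A linear soft-margin SVM (hinge loss, C = 300, tolerance 1e-6, fixed
solver seed; scikit-learn's liblinear-style implementation) scores each
element; the image's mean decision value assigns the class — epithelium
if strictly positive, stroma otherwise (an exact zero is stroma) — and
|mean| ≤ 1 marks a weak call.

## Degradation operators

JPEG2000 encoding uses OpenJPEG through Pillow: reversible 5/3 wavelet
for lossless (bit-exact round trip, asserted in tests) and irreversible
9/7 with rate control for lossy compression at target ratios 12, 25
and 50 against the raw RGB payload (`width·height·3` bytes).  Rate
control is approximate (±20% on realistic-entropy images) and bottoms
out at the ~0.3 KB codestream header for tiny images.  Downscaling is a
deterministic box filter: `ceil(n/f)` output pixels per axis,
edge-padded trailing blocks, round-half-away-from-zero to 8 bits.  The
degradation order is compress → decode → downscale, with file-size
accounting re-encoding the scaled image under the same compression spec
(the file an archive would store for that condition); the alternative
scale-then-compress order is available as a flag.

## The degradation experiments

The IHC arm degrades every core over the full ratio × scale grid,
scores it, dichotomizes extents at the seventh decile (linear
interpolation quantile; ties at the cutoff are low) of the *reference*
condition — lossless, unscaled — and reports percent agreement and
unweighted Cohen's kappa of each condition against the reference
labels.  Computing the cutoff once on the reference is what makes the
comparison measure degradation rather than cutoff drift, and makes the
reference cell exactly 100% / κ = 1.  The segmentation arm classifies a
held-out test split at each compression ratio and compares predictions
to the lossless predictions; no scaling series is applied because the
LBP operator is scale-variant.  The SVM is trained once, on lossless
images only.

## Synthetic scenes

**IHC cores** (default 640×640 px): 225 elliptical nuclei of radius
11–16 px — about 25–35 px diameter, i.e. 7–9 µm at the 0.26 µm/px
scanner resolution these scenes emulate — on a white background.  All
nuclei carry haematoxylin (peak OD 0.65), a Bernoulli-`positive_fraction`
subset additionally carries DAB (peak OD 0.9), with ±15% per-nucleus OD
jitter and Gaussian pixel noise σ = 2.  Colours come from the same
Beer–Lambert forward model the scorer inverts, so deconvolution is
exact up to quantization and noise; overlaps take the maximum OD per
stain, which biases the planted pixel share slightly above the nominal
fraction (a pixel shared by a positive and a negative nucleus carries
DAB).  Ground truth is the planted positive-pixel share of nuclear
pixels.  Dataset sweeps space `positive_fraction` evenly over
(0.05, 0.95).

**Texture scenes** (168–1191 px per side; dataset default 240–420):
epithelium is densely packed rounded dark blobs (radius ~6–15 px),
stroma thin elongated fibres with a coherent orientation, both over a
pale tissue matrix with smooth mid-frequency mottling (Gaussian-filtered
noise, σ = 2.5 px kernel, amplitude 10 gray levels) plus pixel noise
σ = 1.5 and a thin bright glass border.  The mottling is load-bearing:
with a flat matrix, the equal-occupancy VAR quantizer places its lowest
cut points at the pixel-noise scale, and sub-gray-level codec artifacts
then move most of the histogram mass across bins — in a direction that
depends on the balance between the codec's ringing and smoothing —
making classifier scores erratic under mild compression.  Mottling
keeps matrix variance robustly mid-bin, so only genuine texture
destruction (mainly at ratio 1:50) moves features.

Two stratified per-image difficulty axes emulate real annotation
variability: texture fineness (`size_factor`, 0.9–1.1) and tissue
composition (`other_mix` — the fraction of 80-px blocks carrying the
opposite class's texture; evenly spaced 0–0.38 for epithelium and a
third of that for stroma, which is the easier tissue to delineate
purely).  Training splits use composition-pure scenes, mirroring
training on representative tissue regions.  Mixed composition is what
produces the graded response to compression: each ratio flips the
images whose lossless score falls within that ratio's drift of zero,
so agreement declines in the order 1:12 ≥ 1:25 > 1:50 instead of the
whole class crossing the decision boundary at once.

## What the synthetic results do and do not show

The synthetic experiments reproduce the *structure* of the degradation
study: IHC agreement ≥ 95% through ratio 1:50 combined with scaling
1:8, collapse by 1:32 and beyond; segmentation agreement high at 1:12,
slightly lower at 1:25, sharply lower at 1:50.  The numerical agreement
values depend on the synthetic difficulty distribution and are not
estimates of any real cohort's values.  The scenes omit, among other
things: chromatin texture inside nuclei, stain batch and illumination
variation, scanner optics and focus blur, tissue folds, and genuinely
continuous (non-ellipse) morphology; real compression tolerance of any
specific algorithm and cohort must be validated on its own data.

## Numerical and size choices

Default problem sizes keep a full run light: 100 cores for the IHC arm
(4 ratios × 8 scales), 30+30 training and 30+30 test annotations for
the segmentation arm; `scripts/acceptance.py` completes in a few
minutes on one CPU.  Degenerate inputs are defined, not guessed: blank
images score extent 0, empty DAB masks report 0% intensity, an
annotation with no tissue elements raises an explicit unclassifiable
error, kappa raises on degenerate marginals, and the VAR quantizer
refuses an all-constant training pool.  All randomness flows from
explicit integer seeds through `numpy` generators; every generator
output, the SVM fit, and both codec paths are deterministic given the
seed.
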