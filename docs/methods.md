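# Methods

`orgadetect` quantifies the vitality of cultured organoids from brightfield
microscopy. It couples a single-stage object detector (YOLOv3 with
convolutional block attention, CBAM) to a small amount of downstream
arithmetic: detected bounding boxes become counts, calibrated diameters and
an aging fraction, and those parameters are correlated against classical
senescence read-outs (SA-β-Gal positivity, passage number). This note
records the model, the choices that were genuinely open, and what the
synthetic test bed does and does not establish.

## Detection model

The detector is the standard three-scale YOLOv3 layout: a Darknet-53-style
residual backbone (stage widths 64·2^k channels, residual block counts
1/2/8/8/4), a feature-pyramid head that merges strides 32, 16 and 8 via
nearest-neighbour upsampling and concatenation, and three anchors per cell
at each scale. For a cell with origin (c_x, c_y), anchor prior (p_w, p_h)
and raw outputs (t_x, t_y, t_w, t_h, t_o, t_c…):

    b_x = (σ(t_x) + c_x)·stride     b_w = p_w·e^{t_w}
    b_y = (σ(t_y) + c_y)·stride     b_h = p_h·e^{t_h}
    confidence = σ(t_o)·σ(t_c)

CBAM is inserted once after each of the five backbone stages, channel
attention before spatial attention, reduction ratio 16, 7×7 spatial kernel.
Placement and ratio are not dictated by anything upstream of this package;
we follow the CBAM authors' sequential arrangement and treat both as
configuration. Setting a block's `bypass` flag turns it into the identity,
which reproduces the attention-free network exactly — this identity is
exercised in the test suite, and it is also how the parameter-count audit
separates attention parameters from backbone parameters.

The network is implemented directly in numpy: im2col + GEMM convolutions,
batch normalisation, leaky ReLU (slope 0.1), with hand-derived backward
passes for every layer and a small static-graph executor. The analytic
gradients are audited against central finite differences in float64 in the
test suite (the whole model supports a float64 mode for exactly this
purpose). All production arithmetic is float32.

`width_multiplier` scales every channel count (floor of 4). The published
architecture corresponds to multiplier 1.0; the desk-scale configuration
used throughout the tests is 0.125 (~1M parameters), which keeps CPU
training of the full-depth network practical.

## Input geometry and calibration

Images are 8-bit grayscale, letterboxed (aspect-preserving resize, mid-gray
padding) to 416×416 and replicated to three channels, intensities scaled to
[0, 1]. The letterbox transform is recorded and inverted exactly when
detections are mapped back to image pixels; boxes are clipped to the image.
Internally all boxes are 0-based half-open; Pascal-VOC XML files use the
1-based inclusive convention and are converted only at the I/O boundary.

Physical calibration is 0.833 µm per pixel edge (100× magnification) and is
carried as metadata on every detection set, so all micron-valued outputs
are linear in it.

## Training

Loss (averaged over the batch):

* **box** — squared error on (σ(t_x), σ(t_y), t_w, t_h) against the encoded
  target at positive anchors, weighted by `box_weight` (default 7.5) times
  (2 − area/416²);
* **objectness** — binary cross-entropy, weight `obj_weight` (default 10) at
  positives and `noobj_weight` (default 0.5) at negatives;
* **class** — binary cross-entropy per class at positives.

A ground-truth box is assigned to the anchor (of nine) with best co-centered
shape IoU, at the grid cell containing its center on that anchor's scale.
Two mechanisms remove ambiguous locations from the negative-objectness term,
limiting the positive/negative imbalance: statically, non-best anchors at
the target's cell whose shape IoU exceeds `ignore_iou_threshold`; and
dynamically, any prediction whose *decoded* box overlaps a truth above the
same threshold. The dynamic mask is treated as a constant with respect to
the parameters, as in the reference implementations of this detector family.
The threshold defaults to 0.7: at the conventional 0.5, wrong-size
predictions that transiently overlap a truth escape the negative term early
in training and persist as confident duplicates; 0.7 restricts the
exemption to genuine near-hits, which measurably improves precision on the
synthetic bed.

Anchors are re-estimated before each fit by k-means over training box
shapes under the 1 − IoU distance, with deterministic farthest-point
initialisation; they are sorted by area and assigned three per scale,
coarsest grid taking the largest.

Optimisation is Adam with the two-phase schedule: learning rate 0.001 at
batch size 8, then 0.0001 at batch size 2. Both phases train all layers —
with no pretrained backbone a frozen warm-up has nothing to preserve, so
the two phases differ only in learning rate and batch size. Epoch counts
are configuration; the desk-scale preset is 30 + 60 (the batch-2 phase
carries most of the refinement). The checkpoint with the best held-out
total loss is restored at the end of a fit. The final 1×1 convolutions
start with objectness bias −2, a rare-object prior that stabilises the
first epochs. Augmentation is limited to horizontal/vertical flips,
pre-encoded so epochs pay no augmentation cost; it is off by default and
enabled for the 40-scene desk-scale fixture, which would otherwise
underdetermine a from-scratch detector. Batch-norm running statistics use
momentum 0.9 so that inference-mode statistics are usable after a few
hundred steps.

Determinism: with a fixed seed and single-threaded BLAS, sampling, anchor
estimation, initialisation and the epoch shuffle are all reproducible; the
first-epoch loss is asserted bit-identical across runs in the suite.

## Vitality parameters and quality control

Per image: `organoid_number` is the post-NMS detection count; each
organoid's diameter is the mean of its box width and height × 0.833 µm
(for near-circular bodies the least-assumption estimate from an
axis-aligned box); `average_diameter_um` their mean; `No.×Dia.` the product
of count and average diameter (µm). With the two-class (active/aging)
model the aging fraction is reported, and a sample whose aging fraction
strictly exceeds 0.80 is flagged poor quality — the threshold is
configurable, the default strict inequality deliberately so, as 80% itself
is acceptable. Correlations are Pearson (exact t-transform p-value) or
Spearman (mid-ranks, t-approximation) via scipy; series with zero variance
raise rather than report a coefficient.

Detection evaluation is Pascal-VOC style: confidence-ordered greedy
matching at IoU ≥ 0.5, each truth claimable once; AP by all-point
interpolation (VOC2010+) by default with the 11-point variant behind a
flag, and the convention used is recorded in every report; mAP is the
unweighted class mean; precision/recall/F1 are point metrics at a stated
confidence threshold. Frames-per-second is never asserted — it measures
hardware, not the model.

## Synthetic scenes

The generator emulates the two morphologies used as detection classes:
*active* organoids as a dark annular rim (thickness 0.18·d, ≥3 px) around a
brighter lumen, *aging* organoids as filled darker regions with speckle and
an irregular outline (3 random low-order harmonics; amplitudes normalised
so the relative radial perturbation never exceeds `boundary_roughness`,
and the outline rescaled so its mean axis extent equals the nominal
diameter — the ground-truth box then measures the organoid without upward
bias). Diameters are log-normal (median ≈55 px, σ=0.25, clipped to
24–120 px) — a right-skewed size distribution typical of organoid
cultures; placement is rejection sampling on nominal boxes against
`max_overlap_iou` (default 0: non-overlapping) with a 1,000-attempt cap.
Background is a constant mean (150) plus Gaussian pixel noise (σ=8) and a
low-frequency cosine shading field emulating uneven illumination. Scenes
default to 512×512 px, letterboxed to 416 downstream. Rendering is a pure
function of the scene description including its seeds: bit-identical
images, and tight boxes computed from the actual rendered masks.

Phenotype tables are generated per (sample, passage): SA-β-Gal positivity
0.10 + 0.12·passage and single-cell diameter 12 + 1.5·passage µm, plus
Gaussian noise (σ 0.04 / 0.4 µm), clipped to valid ranges — monotone
senescence trends of the kind reported for serially passaged cultures.

What passing on this bed shows: that the detector, losses, decoding,
matching and phenotype arithmetic are internally correct and can learn and
recover known structure end-to-end. What it does not show: performance on
real brightfield images — real debris, focus gradients, overlapping and
budding organoids, and staining variation are all absent, and no claim is
made that desk-scale synthetic mAP transfers to microscope data.

## Problem sizes and numerical choices

The test suite and the reproduction script train the desk-scale detector
(multiplier 0.125, full depth, 416×416 input) on 40 generated scenes with
10 held out — sizes chosen so a single-CPU fit stays in the minutes range.
Oracle-equivalence checks run hundreds of randomized trials at ≤50 boxes
against brute-force reimplementations (tolerance 1e-6 for box/metric
arithmetic, 1e-5 for attention and decoding, which traverse float32
network code). Ties in NMS and matching are broken by input order after a
stable confidence sort. Degenerate inputs are defined rather than left to
chance: empty detection sets summarise to zeros, zero-variance series and
zero-truth classes raise, empty target lists reduce the loss to its
background term.

## Known limitations

* Pure-numpy training is single-threaded GEMM-bound; the full-width
  (multiplier 1.0) model is defined and runs forward, but training it to
  published-scale accuracy is a GPU-framework task outside this package's
  scope.
* The aging/active distinction in the generator is geometric (rim + lumen
  versus filled rough outline); it does not model intermediate morphologies
  seen in real senescing cultures.
* Letterbox resizing uses bilinear interpolation via Pillow; other
  resamplers shift box-edge positions by sub-pixel amounts.
* `estimate_anchors` accepts a `seed` for interface stability, but the
  farthest-point initialisation has made it a no-op.
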