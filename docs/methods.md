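# Methods

## Problem and model

Fetal head circumference (HC) is measured on a transthalamic ultrasound
plane as the perimeter of the ellipse best fitting the skull. `fetalhc`
implements an end-to-end detector-regressor for this measurement: a
Mask-RCNN-style detector (ResNet/FPN backbone, region-proposal network,
ROI align) whose segmentation head is replaced by a head that regresses a
*distance field* — a per-pixel map `F(p) = exp(-d(p)^2 / (2 sigma^2))`
where `d(p)` is the Euclidean distance from `p` to the skull contour.
Regressing a smooth band rather than a 1-px contour (or a filled mask)
gives the head a well-conditioned target, and detection-first regression
confines the field to the head region so no outlier post-processing is
needed. At inference the predicted field is thresholded at 0.9 and an
ellipse is fitted to the surviving pixels; HC in millimetres is the
Ramanujan-II perimeter of that ellipse times the per-image pixel size.

Assumptions: one head per image; square pixels; grayscale input. The
contour annotation is an exact ellipse (the HC18 convention) rasterized
2 px wide.

## Ground-truth construction (`targets`)

1. Rasterize the annotated ellipse at the stated line width (a pixel is on
   iff its center is within `width/2` of the continuous contour, measured
   against a dense parametric sampling).
2. Thin to a one-pixel skeleton (morphological thinning; any residual 2x2
   solid block is broken).
3. Exact Euclidean distance transform of the skeleton, then the Gaussian
   profile with `sigma = r/2`. This is mathematically equivalent to the
   per-contour-pixel rectangle construction for a smooth contour and much
   simpler to verify against brute force.
4. The box target is the tightest axis-aligned box containing the field's
   support.

**Truncation.** The band thickness `r` (default 100 px at the 512-px
working resolution) defines `sigma`, but the construction needs an
explicit support rule. The default truncates at `d <= r/2` — a band of
total thickness `r`, with a step from `exp(-0.5) ~ 0.607` to 0 at the
edge. The alternative support `d <= r` is available as
`FieldConfig(support="wide")`. Training targets and all reported numbers
use the default.

Coordinates are 0-based `(row, col)`; boxes are half-open. Images resize
to the square working resolution with bilinear interpolation (nearest for
masks), preserving aspect ratio and zero-padding right/bottom; the
`ResizeTransform` record makes the mapping invertible.

## Ellipse fitting (`ellipse`)

Stage 1 is an unconstrained, non-iterative least-squares conic fit (the
smallest right singular vector of the design matrix in centered, scaled
coordinates) followed by a fixed number of gradient-normalized
reweightings, which approximate geometric rather than algebraic distance.
It is exact for noise-free samples of an ellipse; degenerate input (under
6 distinct points, collinear points, a non-elliptic best conic) raises a
fit failure.

Stage 2 corrects a bias specific to thresholded distance fields. The 0.9
superlevel set is a band of half-width `w = sigma*sqrt(2 ln(1/0.9))`
(~23 px at r=100) around the contour, and the *outer* ring of the band
contains more pixels than the inner ring (offset-curve length is
`P + 2 pi s` at signed offset `s`), so any fit of the raw pixel cloud
lands `~2 pi w^2 / (3P)` outside the true contour — several pixels for
small heads. The refinement therefore extracts the band's boundary
pixels, classifies them inner/outer against the stage-1 estimate, and
solves a least-squares problem for (ellipse, w) such that boundary pixels
sit at signed distance ±w: the recovered ellipse is the band midline.
The refinement is skipped when the input is thin (max boundary distance
< 1.5 px), which keeps stage 1's exactness on noise-free samples; it can
be disabled with `refine_band=False`.

Thresholded pixels enter the fit unweighted by default; field values can
be used as weights via the `weights` argument. The reported angle is in
radians, counter-clockwise from the +x axis, canonicalized to `[0, pi)`
with `a >= b` (circles report theta = 0).

Perimeter uses Ramanujan's second approximation,
`P = pi (a+b) (1 + 3h / (10 + sqrt(4 - 3h)))`, `h = ((a-b)/(a+b))^2`,
accurate to better than 1e-4 relative for aspect ratios up to 5 (tested
against adaptive quadrature of the arc-length integral).

## Architecture (`net`)

ResNet body (depths 18/34/50/101; default 101) with an FPN top-down
pathway (256 1x1 lateral filters by default) producing P2..P6 at strides
4..64; P6 is stride-2 subsampling of P5. The RPN (shared 3x3 conv + 1x1
objectness/delta convs) runs over all levels; anchors span one scale per
level (default [32, 64, 128, 256, 512]) and ratios [0.5, 1, 2] with
`w = s*sqrt(ratio)`, `h = s/sqrt(ratio)`. ROI align is quantization-free
bilinear pooling to `d x d` (default 14) with 2x2 samples per bin and the
standard FPN level heuristic `k = floor(4 + log2(sqrt(wh)/224))`.

Heads: classification (two 1024-wide dense layers, then 2-way softmax),
box regression (same trunk, 4 linear outputs), and the distance-field
head — four 3x3 convolutions as in the mask head, then an upsampling path
of `n_upsamplings` (default 3) blocks. Two variants: `transposed` (one
2x2/stride-2 transposed convolution per block, as in the original mask
head) and `upconv` (2x nearest upsample, a 2x2 convolution, then two 3x3
convolutions — the UNet decoder style; the default). Every convolution is
followed by batch norm and ReLU except the final 1x1, which is linear so
the regression reaches 0 and 1 symmetrically (targets live in [0, 1];
detections clip the patch to [0, 1] downstream). Output is
`(2^u d) x (2^u d) x 1` per ROI. With the class head disabled
(`include_class_head=False`) detections fall back to RPN objectness
scores and the classification loss term disappears.

Hyper-parameters inherited from standard Mask-RCNN without restatement:
RPN positive/negative IoU 0.7/0.3, proposal NMS 0.7, head-positive IoU
0.5, detection score threshold 0.7, detection NMS 0.3, pre/post-NMS
proposal counts 6000/1000 (train) and 1000/100 (test), 256 RPN training
anchors per image.

All tensor work runs on a compact reverse-mode autodiff engine
(`fetalhc.nn`) written on numpy: convolutions via im2col + BLAS matmul
(with a pointwise fast path), transposed and even-kernel "same"
convolutions, batch norm with running statistics, bilinear ROI align with
exact scatter gradients, SGD with classical momentum. Gradients are
verified against central differences in the test suite; subgraphs whose
parameters are frozen are pruned from the backward pass, which is what
makes the staged schedule cheap.

## Training (`train`)

Multi-task loss `L = alpha*L_cls + beta*L_box + gamma*L_df` with
`alpha = beta = gamma = 1`: cross-entropy over head/background,
smooth-L1 on box deltas of positive ROIs, and `L_df` the RMSE between
predicted and target field patches, computed per positive ROI and
averaged (field targets exist only where a head does, mirroring the mask
loss convention). The RPN's own two losses are optimized jointly, as in
standard Mask-RCNN, but are kept outside the logged `L`: `L` is the
quantity recorded per step and used for best-model selection, and the
identity `L = alpha*L_cls + beta*L_box + gamma*L_df` holds for every
logged step. Proposals are labeled positive at IoU >= 0.5 against the
ground-truth box, sampled to 150 per image (desk scale: 64) with at most
1:3 positive:negative; the ground-truth box is appended to the proposals
so positives exist from the first step. Field targets are the GT field
cropped to the ROI and bilinearly resized to head output resolution.

Optimizer: SGD, learning rate 0.001, momentum 0.9, batch size one image,
no schedule (only the initial rate is specified; we keep it constant per
stage). Three stages of freezing: (1) everything except the residual body
(FPN, RPN, heads — the usual Mask-RCNN "heads" convention), (2) the
distance-field head alone, motivated by the detection losses dropping
faster than the field loss, (3) the whole network. Default 50+50+50
epochs; desk-scale experiments use 5+5+5. One checkpoint per epoch stores
the full state dict with its training and validation `L`; the selected
model is the validation-`L` argmin, ties to the earliest epoch.

On-the-fly augmentation applies one affine transform per sample — scale
U[0.9, 1.1], translation ±5% of the image side, rotation ±15°, shear ±8°
— consistently to image and field, recomputing the box from the warped
field; a draw that pushes the head out of the canvas is retried up to 10
times, then the sample passes through unaugmented. Validation is computed
without augmentation, in evaluation mode (batch-norm running statistics),
with a fixed ROI-sampling stream so epochs are comparable. All randomness
— initialization, ROI sampling, augmentation, data order — derives from
`TrainConfig.seed`; two runs with the same seed produce identical loss
traces on one CPU.

The COCO-pretrained backbone of the original recipe is supported only as
an optional externally supplied checkpoint (grayscale input is replicated
to 3 channels when `in_channels=3`); the default is random (He)
initialization so the package builds and trains with no downloads.

## Inference and metrics (`infer`)

The top-scoring detection's field patch is bilinearly resized to its box,
pasted into a zero canvas at working resolution, clipped to [0, 1], and
mapped back to source coordinates through the inverse resize; thresholding
and fitting then happen in original-image pixels. Fit or detection
failures surface as no-measurement records rather than aborting a batch.

Metrics: DF = predicted HC − reference HC in mm (negative mean =
under-estimation), ADF = |DF|; HD is the classic symmetric Hausdorff
distance between contours sampled at >= 3600 points, in mm (note that
challenge servers sometimes report modified/averaged variants, which read
lower); DSC is Dice between filled ellipse masks. Aggregation reports
mean ± SD per metric with no-measurement records counted separately.

## Synthetic phantoms (`synth`)

The generator emulates the *structure* of fetal-ultrasound biometry data:
one bright elliptical skull band per image (Gaussian cross-profile of
drawn thickness and contrast) over a low-frequency soft-tissue background,
optional angular shadow sectors attenuating the band, and multiplicative
unit-mean gamma speckle (shape 4 by default), lightly smoothed to emulate
speckle's spatial correlation. Head semi-major axis, axis ratio
(U[0.6, 0.95]) and orientation (U[0, pi)) are uniform; pixel size is
uniform on [0.052, 0.326] mm and negatively rank-correlated with head
size in pixels through a Gaussian copula (rho = 0.7), emulating
sonographers zooming out for older fetuses — so uniform marginals survive
exactly (they are Kolmogorov-Smirnov-tested) while HC in mm spans a
realistic range. Heads are placed uniformly subject to full containment
with a margin of skull thickness + r/2. Trimester labels are HC terciles
of the generated set, standing in for gestational age. Generation is
byte-reproducible for a fixed seed.

What the phantoms do *not* emulate: wave propagation (no point-spread
function in polar coordinates, no fan geometry, no reverberation
artifacts), anatomy beyond the skull band, and real HC18 intensity
statistics — contrast and noise levels are free parameters, not fitted to
HC18. Passing desk-scale tests therefore shows the pipeline is correct
and trainable on data with this structure; it does not certify clinical
accuracy on real ultrasound.

## Desk-scale configuration

Full-scale training (512-px images, ResNet-101, 256 channels, 150 epochs)
is a GPU-sized workload. The package's experiments and tests therefore run
a reduced configuration chosen once: 128-px phantoms with field thickness
r=24 (so sigma scales with the image as r=100 does at 512), ResNet-18
body at 3/16 width, a 20-channel FPN, a 12-channel field head, 80-wide
dense layers,
ROI align d=7 with u=3 upsamplings (56x56 field patches), anchor scales
[16, 32, 64, 128, 256], 64 training ROIs per image, proposal counts
1000/100 (train) and 500/50 (test), 200 training / 50 held-out phantoms,
5+5+5 staged epochs. Optimizer settings are unchanged from the full
recipe. The ablation comparison trains the default upconv u=3 head and
the single-transposed-convolution head (the original mask-head upsampler)
under the identical seed and budget.

## Known limitations

- The band-midline fit refinement assumes the thresholded region is a
  roughly constant-width band; for wildly malformed network output it
  falls back to the stage-1 fit or raises a fit failure.
- Batch norm with batch size one makes training statistics noisy; running
  statistics stabilize validation but small desk-scale runs still show
  epoch-to-epoch variance in validation L.
- The classic Hausdorff distance is reported; published challenge numbers
  may use a modified definition and are not directly comparable.
- CPU training at desk scale is minutes, not seconds; the full-scale
  recipe is supported but not exercised by the tests.
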