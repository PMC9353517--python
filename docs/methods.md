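# Methods

`vineseg` implements an improved Mask R-CNN for instance segmentation of
grape clusters in field images, together with the annotation tooling and the
evaluation protocol such a model is trained and scored with. This note
documents the model, the choices that were genuinely open, the synthetic
data the tests run on, and what the shipped checks do and do not establish.

## The model

The detector is two-stage. A backbone turns an RGB image into a five-level
feature pyramid P2–P6 (strides 4–64, one shared channel width); a region
proposal network (RPN) scores anchor boxes at every pyramid location; RoIAlign
pools each proposal into fixed grids (7×7 for the classification/box branch,
14×14 for the mask branch); fully connected layers predict a class and
class-specific box deltas, and a small fully convolutional head predicts an
m×m per-class mask grid (m = 28). Training minimizes the unweighted sum

    L = L_cls + L_box + L_mask

with cross-entropy classification, smooth-L1 box regression on parameterized
deltas, and mean per-pixel sigmoid binary cross-entropy on the target class's
mask slice (all-zero logits therefore give exactly ln 2 ≈ 0.6931).

Two modifications to the standard ResNet50-FPN backbone define the
ResNet50-FPN-ED variant:

* **Efficient Channel Attention (ECA)** on each stage output C2–C5, applied
  before the 1×1 lateral reductions. The gate is: global average pool to a
  length-C vector, a bias-free 1-D convolution of odd width k across the
  channel axis (zero padding (k−1)/2), a sigmoid, and channel-wise rescaling.
  The width adapts to the channel count as

      k = ψ(C) = |log2(C)/γ + b/γ|_odd,   γ = 2, b = 1,

  so C = 256, 512, 1024, 2048 give k = 5, 5, 5, 7. "Nearest odd" is resolved
  as truncate-to-int, plus one if even — the convention of the original ECA
  reference code; the written rule is ambiguous for even or half-integer
  values, so the kernel size can also be overridden explicitly. Each gate
  adds exactly k parameters.

* **Dense Upsampling Convolution (DUC)** replaces nearest-neighbour
  interpolation in the top-down pyramid fusion: a 3×3 convolution maps the
  C-channel map to C·r² channels, which are rearranged deterministically into
  an r× larger grid (intermediate channel c·r² + dy·r + dx becomes output
  pixel (y·r+dy, x·r+dx) of channel c). Adjacent pyramid levels differ by a
  factor of two, so r = 2 throughout. The upsampler is thereby learnable.

Fusion order follows the architecture table of the original design: stage →
ECA → 1×1 lateral (256 channels) → top-down DUC upsample + elementwise add →
3×3 anti-aliasing convolution → P2–P5; P6 is a stride-2 max-pool of the
post-3×3 P5. Inputs are right/bottom zero-padded to a multiple of 64 before
the stem so every level has exact integer geometry.

### Anchors

Five scales {8, 16, 32, 64, 128} × three aspect ratios {0.5, 1, 2} give 15
benchmark windows. Scales are base side lengths in input pixels assigned one
per level P2–P6 (smallest scale on the finest level); at fixed scale the
anchor area is preserved across ratios (w = s·√a, h = s/√a, rounded). The
source design does not state how scales map to levels; the flat one-per-level
assignment is the reading that keeps exactly 15 global templates. The
aspect-ratio orientation (width/height vs height/width) is also
convention-dependent; since the ratio set {0.5, 1, 2} is symmetric, the
template *set* is identical either way — this package defines
aspect_ratio = width/height.

## Numerical core

No GPU deep-learning stack is assumed: the model runs on `vineseg.nn`, a
compact reverse-mode autodiff core written for this package on numpy —
im2col convolutions, pooling with recorded argmax, a bilinear RoIAlign with
the half-pixel-aligned convention (continuous coordinate c samples at
c·scale − 0.5; sampling_ratio² sub-samples per output cell), pixel shuffle,
fused numerically stable losses, and SGD with momentum, L2 weight decay and
global-norm gradient clipping. The 2×2 stride-2 transposed convolution of
the mask head is implemented exactly as a 1×1 convolution to 4·C channels
followed by pixel shuffle (the windows do not overlap). Every operation is
verified against finite differences or a closed form in the test suite.
Default dtype is float32; oracle-equivalence tests use float64 so that
tolerances measure the algorithm rather than the dtype.

Batch normalization supports a `frozen` mode (normalize with stored running
statistics, so the layer is a per-channel affine map). Frozen BN is the
default for the test-scale preset: at batch size 2 batch statistics are
noisy, and the detection literature freezes BN at small batch sizes for the
same reason.

## Training recipe

Defaults in `TrainConfig` are the field-data recipe: 50 epochs, batch size
2, SGD with initial learning rate 0.01 decayed ×0.1 every 5,000 iterations
(the schedule is iteration-based and independent of epoch bookkeeping),
weight decay 1e-4, online augmentation (horizontal/vertical mirror,
rotation, crop, brightness/contrast/saturation), and multiscale resizing
with short edge drawn from {640, …, 800 step 32} and the long edge capped at
1,443 px — the cap is exactly a 3008×1668 sensor frame at short edge 800.
Momentum (0.9), rotation range (±15°), and crop fraction (0.8–1.0) are not
specified by the recipe; the defaults are the standard values for this kind
of detector and are logged per run. Geometric augmentations transform the
polygons and the image with the same map and all boxes are recomputed from
the transformed polygons, so geometry cannot drift from the pixels;
photometric jitter leaves geometry bit-identical.

"Loading partial weights" for a modified backbone is implemented as
name-intersection checkpoint import that reports skipped tensors; training
from scratch is the tested path.

## Annotation semantics

A cluster occluded by a trunk or wire appears as several disjoint blobs;
each blob is traced as its own polygon and the parts share a *group id*.
Merging is keyed on (label, group id) and is file-local; parts with equal
group id but different labels are an error. The outer box is the tightest
axis-aligned rectangle over every vertex of every part. Rasterization fills
a pixel when its center (col+0.5, row+0.5) lies inside the polygon under the
even-odd rule; a multi-part instance is the union (OR) of its parts' fills,
and areas are pixel counts of that union. COCO export stores one annotation
per merged instance with one polygon list per part (never run-length, so the
multi-part structure stays visible), `iscrowd` always 0, and a single
category ("grape").

The 8:2 train/test split shuffles deterministically per source dataset and
takes round-half-up of 20 % as the test count: 218 images → 174/44. (The
published Grape-B partition, 370/94 of 464, is not an exact 8:2 — 92.8
expected; the splitter follows the arithmetic, not that table row.)

## Evaluation protocol

`vineseg.cocoeval` implements the COCO metric suite: greedy score-ordered
one-to-one matching per image, ten IoU thresholds 0.50:0.05:0.95, a
right-to-left precision envelope with 101-point interpolation for AP, and
recall at 1/10/100 detections per image for AR. A detection matches at
IoU ≥ threshold (the reference tooling's convention; prose descriptions
often say "greater than"). With one category the category average is a
no-op; when no ground truth exists the sentinel −1 is reported. Box IoU is
computed on (x, y, w, h) boxes, mask IoU on dense boolean masks decoded from
the polygon segmentation with the package's own fill rule. Reports carry
fractions in [0, 1] plus a percent-scale view, since published tables print
the 0–100 scale. The test suite checks the vectorized evaluator against a
second, deliberately naive loop-based implementation; the two agree to
better than 1e-6 on randomized fixtures for all six metrics on both tasks.

## Synthetic scenes

The generator emulates the *statistical structure* of annotated vineyard
images, not their appearance: 1–20 cluster-shaped objects built from
overlapping berry discs scattered in an elliptical envelope; bar-shaped
trunk/wire occluders drawn after the clusters, which can split one cluster
into disjoint parts; a near/far scale regime (near ≈ the 50–100 cm capture
distance: 1–5 larger clusters; far ≈ 100–150 cm: 6–14 smaller clusters);
and global brightness/contrast/saturation jitter standing in for
down-light/back-light variation. Those density/occlusion defaults are free
parameters — the field datasets are not quantified at that level — chosen
once to make occlusion splits common without making scenes unreadable.

Polygons are derived from the visible pixels by marching-squares contour
extraction (what an annotator traces), and each instance's stored
ground-truth mask is defined as the rasterization of its polygons, so
annotation fidelity (polygons ↔ masks, pixel for pixel) holds by
construction. Clusters are placed without mutual overlap so that, absent
occluders, every instance is a single polygon. Scenes are bit-reproducible
from (config, seed); datasets derive per-image seeds from one root seed.

What passing tests show: the architecture, losses, gradients, annotation
pipeline and evaluator are wired correctly, and the full train/predict loop
can drive the objective to ≈0 and recover every instance on data drawn from
the structure it was designed for. What they do not show: segmentation
accuracy on real vineyard imagery — synthetic discs have none of the
texture, lighting or boundary ambiguity of field photographs, and the
published accuracy tables require the original (unreleased) datasets and
GPU-scale training, which are explicitly out of scope here.

## Problem sizes

CPU-friendly sizes are used throughout: the `test_scale` preset keeps the
full ED topology with one bottleneck per stage, widths ÷4 and a 64-channel
pyramid; scenes are 128×128 ("tiny" preset, ≤3 clusters) or 256×256;
evaluator fixtures use 20 images; the learnability run is 300 iterations at
batch 2 on four scenes (a few CPU-minutes) and reaches total loss < 0.05
and AP@0.5 = 1.0 on its own training images. The full-geometry backbone
(256-channel pyramid, 16 bottlenecks) is exercised for its shape contract
on 128×128 inputs.

## Known limitations

* Single category; no crowd regions; no area-stratified AP.
* Mask pasting uses bilinear resize of the 28×28 probability grid into the
  box followed by a 0.5 threshold; very thin structures can alias.
* The numpy core is single-threaded and orders of magnitude slower than a
  GPU stack; the full-scale recipe is encoded and runnable but not practical
  to train to convergence on CPU.
* `load_state_dict` imports by exact name/shape match only; there is no
  cross-framework weight translation.
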