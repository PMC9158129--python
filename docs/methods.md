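# Methods

## Problem setting

Karyotype analysis starts from a microscope image of a metaphase cell
containing ~46 chromosomes. Chromosomes are flexible, elongated objects that
curve, touch and overlap; instance segmentation — one pixel mask per
chromosome — is the step on which all downstream classification depends.
Two failure modes dominate for detector-style segmenters on such scenes:

1. **Score/quality mismatch.** The classification confidence of a proposal
   says "this looks like a chromosome", not "this mask is accurate". In
   clusters, high-confidence proposals with poor localization outrank
   accurate ones.
2. **Box-level suppression of true instances.** Two correct masks of
   crossing chromosomes can share most of their bounding boxes (box IoU
   ~0.8) while the masks barely overlap (mask IoU ~0.2). NMS on box IoU at
   a conventional threshold deletes one of them.

This package implements the scoring, suppression, loss and evaluation
machinery that addresses these failure modes, and a synthetic scene
generator that reproduces the geometric regime, so every component is
testable end to end without clinical data.

## The partitioned log-IoU loss

The plain mask loss is `L_IoU = −ln IoU(pred, gt)`. For an elongated object
a gross error confined to one region is diluted by the well-segmented
remainder: the overall IoU stays high and the penalty small. The
partitioned loss divides the tight bounding box of the ground-truth mask
into a `rows × cols` grid of K cells and charges each cell its own
log-penalty:

    L_K-IoU = − Σ_i δ_i · ln IoU_i ,      δ_i = |gt ∩ cell_i| / |gt| ,

where `IoU_i` is the prediction/truth IoU restricted to cell i. The weights
δ_i sum to one over a non-empty ground truth, and a cell with no ground
truth carries weight zero. The unweighted variant (δ_i := 1 on every
non-trivial cell) is the harshest reading; since 0 ≤ δ_i ≤ 1 it bounds the
weighted loss from above. For an error confined to one cell, the unweighted
loss equals `−ln IoU_c` of that cell, which is at least the overall loss
(adding the agreeing pixels of the other cells to both intersection and
union can only raise the ratio) — the penalty-strengthening property, which
the test suite checks on a thousand random single-cell corruptions.

Design choices where the construction was genuinely open:

* **Partition frame.** We partition the tight bounding box of the
  ground-truth mask (not a RoI or the full image) and extend the boundary
  cells outward so the cells tile the whole image. Predicted false-positive
  pixels outside the bounding box are then charged to exactly one cell, and
  Σδ_i = 1 is preserved.
* **Grid reading.** The 4-part division is implemented as one vertical plus
  one horizontal center split (a 2 × 2 grid), generalized to `rows × cols`.
* **Uneven integer splits.** Cell extents differ by at most one pixel, with
  the larger cells placed first (top/left) — deterministic and documented.
* **Empty∩empty IoU := 0**, not 1. Such cells always carry δ_i = 0 in the
  loss so the choice never changes L_K-IoU; 0 avoids spurious perfect
  per-cell scores in reports.
* **Epsilon clamp.** Every logarithm uses `−ln(max(IoU, eps))` with
  `eps = 1e-7`. With fine grids some cells have zero IoU; without the clamp
  the loss is infinite and its gradient dead. All losses are finite for any
  input, including fully disjoint masks. K = 4 (2 × 2) is the package
  default; finer grids increase the fraction of zero-IoU cells and are the
  known failure direction.

## Regression confidence and score correction

The box head's Smooth-L1 loss (mean over the four offset coordinates,
transition point 1) is mapped to a localization confidence

    P_Box = 1 − tanh(L_Reg)  ∈ (0, 1],

a strictly decreasing bijection of the regression loss: 1 iff the
regression is perfect. It is computed in the numerically stable form
`2/(1 + e^{2x})` so it remains strictly positive long after `tanh`
saturates in float64. Together with the predicted mask IoU it corrects the
classification confidence multiplicatively:

    score = P_Cls · IoU_Mask^α · P_Box^β ,    default (α, β) = (2, 6).

Both exponents are configurable; the defaults square the mask-IoU factor
and take the sixth power of P_Box, the strongest-ranking setting. Because
all factors live in [0, 1], the corrected score is again a probability and
never exceeds P_Cls; raising either exponent can only lower it.

Head-supervision terms follow the composite per-proposal ledger

    L = L_Box + L_Seg,  L_Box = L_Cls + L_Reg + L_PBox,
                        L_Seg = L_Mask + L_K-IoU + L_IoUMask,

with binary cross-entropy for the classification and P_Box heads (the
P_Box head is trained against the transform of the realized regression
loss), mean per-pixel binary cross-entropy for the mask head, and squared
error against the true mask IoU for the mask-IoU head (the published
precedent for mask-IoU heads is a regression loss; the squared error is
our choice where the construction was unspecified). All mask losses also
accept probability-valued masks using the soft intersection Σ(p·g) and
union Σ(p+g−p·g), so they can serve as differentiable objectives; binary
masks are the tested default contract.

## Mask-based NMS

Both suppressors are greedy: traverse detections in descending score (ties
broken by lower instance id, making the kept set invariant to input
permutation), keep the best survivor, remove every remaining detection
whose IoU with it **strictly exceeds** the threshold. Box NMS uses box IoU;
mask NMS uses mask IoU, which keeps both members of the crossing-chromosome
pair above. The traversal orders by the corrected score by default;
`score_key="raw"` switches to P_Cls. An optional high-threshold box
pre-filter exists for throughput but is off by default, so that as many
proposals as possible reach the mask stage.

## Evaluation

AP^M follows the COCO conventions wholesale: greedy score-ordered matching
with each ground truth consumed at most once, match iff mask IoU ≥
threshold (inclusive), 101-point interpolated area under the
precision-recall curve, thresholds 0.50–0.95 in steps of 0.05, AP^M their
mean, AP50/AP75 the fixed-threshold entries. Single category; no
max-detections cap (scene instance counts are small). With no ground truth
and no detections AP is defined as 0. Multi-image datasets pool TP labels
and scores across images per threshold, as COCO pools across images.

## Synthetic scenes

The generator emulates the geometric regime the methods target, not the
appearance of real Giemsa photographs. Each instance is a smooth random
spline (five control points jittered perpendicular to a random main axis;
`curvature` scales the jitter relative to length) thickened by a tapering
width profile and shaded with a sinusoidal banding texture. Defaults:
256 × 256 scenes, 8 instances, lengths 60–120 px, widths 7–13 px,
curvature 0.25, overlap level 0.3 — chosen to preserve elongation
(principal-axis ratio ≥ 2) and reachable overlap while keeping desk-scale
experiments fast. `overlap_level = 0` forces pairwise-disjoint placement
(with a retry budget and a capacity error beyond it); larger values reject
non-overlapping placements with that probability, producing clusters.

The detector simulator degrades each ground-truth mask (erosion/dilation
bias, random flips in a boundary band), jitters its box, and assigns
confidences: `p_box` is the regression-confidence transform of the realized
box offsets and `iou_mask_pred` the realized mask IoU — i.e., the heads are
truthful — each plus optional Gaussian noise; the raw classification score
mixes true mask quality with uniform noise according to
`score_informativeness` (0 = uninformative). Spurious detections are short
curve fragments with low true IoU to any ground truth. Scene *i* of an
experiment derives its RNG stream from `(seed, i)`, so every output is a
pure function of configuration and seed.

What passing tests on these scenes do **not** show: performance on real
Giemsa images (texture, staining variability, touching-but-not-overlapping
clusters, class-specific banding are all absent), nor anything about
training dynamics — this package computes losses and scores but contains no
network or optimizer.

## Problem sizes used in the shipped experiments

The confidence-correction experiment runs 50 scenes of 8 instances plus 2
spurious detections at 192 × 192 (~500 detections), with uninformative
classification scores, truthful heads, erosion bias −1 px, boundary band
1.5 px and box jitter 3 px. These are the package's standard desk-scale
study conditions; they are configuration, not claims about any clinical
dataset.

## Known limitations

* No autograd integration: losses are reference implementations in NumPy.
* Binary (chromosome vs background) classification only; no multi-class
  NMS or per-class AP.
* Pixel-aligned geometry only: no polygonal sub-pixel masks, no rotated
  boxes.
* A single label map cannot represent overlapping instances; the PNG
  writer raises and directs to per-instance files.
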