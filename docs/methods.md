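# Methods

`anatodetect` implements an anchor-based 3D lesion-detection pipeline for
co-registered PET/CT volumes with an organ-label prior channel, a
self-supervised pretraining stage, and lesion-level FROC/AP evaluation. All
neural components run on a small numpy reverse-mode autodiff engine shipped
inside the package (`anatodetect.nn`); its gradients are verified against
central finite differences in the test suite, including the 3D convolutions,
transposed convolutions and the windowed-attention block.

## Detection model

The detector follows the Retina-U-Net layout: an encoder emits a four-level
feature pyramid at strides 2/4/8/16; a feature-pyramid network merges it
top-down with lateral 1×1 connections to a uniform width; anchor
classification and box-regression heads attach to the stride-4/8/16 levels,
and the stride-2 level drives an auxiliary voxel segmentation head whose
gradients regularise the shared trunk. Two encoders satisfy the same pyramid
contract and are interchangeable behind the FPN:

* **CNN U-Net encoder** — strided convolutions with instance normalisation;
  stage widths (32, 64, 128, 256) at full scale, (8, 16, 32, 64) at desk
  scale.
* **Hierarchical windowed-attention encoder** — four stages with block
  depths (2, 2, 6, 2), embedding width C = 96 (so stage widths C, 2C, 4C,
  8C), 4×4×4 attention windows and (3, 6, 12, 24) heads at full scale;
  blocks alternate plain and cyclically shifted windows with the standard
  additive attention mask, and token grids that are not window multiples are
  zero-padded (MONAI-style). Relative-position bias is omitted; at the
  spatial scales exercised here its absence was not limiting, and it keeps
  the attention arithmetic minimal. The desk-scale configuration is C = 24,
  depths (1, 1, 1, 1), window 2.

Anchors are axis-aligned boxes tiled at every feature location; the
full-scale default carries 27 per location (3 sizes × 9 per-axis aspect
combinations), the desk default 2 isotropic sizes per level, sized for the
phantom lesion radii. An anchor is positive when its best IoU with a
ground-truth box reaches 0.5 (argmax assignment), ignored in [0.4, 0.5), and
each ground-truth box force-matches its single best-overlapping anchor so no
target goes unsupervised. Regression targets are center offsets normalised
by the anchor extent and per-axis log shape ratios; the raw head outputs are
squashed through tanh (centers to ±2 extents, log ratios to ±3) before
decoding. The squash matters: with a hard clamp, a regression that
overshoots early in training stops receiving gradient and never recovers —
observed, not hypothetical.

### Multitask loss

    L_total = L_Dice_seg + L_CE_seg + L_GIoU_reg + L_CE_cls  (unweighted)

* Segmentation: soft Dice (ε = 1e-5) plus voxel-mean binary cross-entropy,
  both computed on logits in softplus form so saturated predictions keep a
  gradient.
* Regression: mean (1 − GIoU) over positive anchors, on boxes decoded
  differentiably from the squashed deltas; zero by convention when a patch
  has no positive anchor.
* Classification: focal cross-entropy with γ = 2, α = 0.25 over positive and
  negative anchors (ignored anchors excluded). The α convention multiplies
  the positive term only, so γ = 0, α = 1 is exactly plain cross-entropy.
  The public `focal_ce` averages over the anchors it is given; inside the
  training loop the focal sum is normalised by the positive-anchor count
  (RetinaNet convention) — with per-anchor averaging over ~4000 anchors, the
  per-positive gradient is too weak to train at desk scale.

### Optimisation

SGD with Nesterov momentum 0.9 and weight decay 3e-5; the learning rate
warms linearly from 1e-6 to 0.01 and then decays polynomially with exponent
0.9. Full-scale defaults are 50 epochs × 2500 iterations, batch 2, 96³
patches, 4000 warm-up iterations. Desk defaults (the configurations the
tests and acceptance script actually run) are 6–12 epochs × 25 iterations,
32³–48³ patches, 20–40 warm-up iterations. Three further stabilisers proved
necessary at this scale and are standard in the nnU-Net/RetinaNet lineage:
instance normalisation inside the FPN outputs and head trunks, zero
initialisation of the head projection layers (so training starts from
"anchor, background prior"), and global gradient-norm clipping at 12.

Patches are sampled 50% centered on a random lesion, 50% uniformly.
Augmentation applies mirror flips, optional small rotations / elastic
deformation / scaling (images linearly, labels nearest-neighbour, boxes
recomputed from the warped mask), Gaussian noise (p = 0.10), blur
(p = 0.20), brightness scaling in [0.75, 1.25] (p = 0.15), and optional
contrast and standard/inverted gamma transforms.

### Inference

Sliding windows with 50% overlap; per window the anchors above the score
threshold are decoded and clipped, mapped to volume coordinates, pooled, and
de-duplicated by greedy NMS (ties broken by index, idempotent). Minimum
object size and a detections-per-case cap are post-filters. The
segmentation head can optionally be aggregated across windows with Gaussian
weights. Volumes smaller than the patch are zero-padded symmetrically and
boxes mapped back.

## Self-supervised pretraining

A randomly cropped patch is duplicated; each copy is corrupted by coarse
dropout — rectangular regions replaced with per-voxel uniform values in
[0, 0.2], or with probability 0.5 the inverted variant that retains the
regions and fills the remainder — followed by pixel shuffling inside random
regions, independently per channel. Region geometry is shared across
channels; when the organ channel participates, it is corrupted like the
imaging channels. Inputs are min-max normalised to [0, 1] per channel per
patch so the fill range is meaningful.

The autoencoder couples the windowed-attention encoder's stride-16
bottleneck to two transposed-convolution layers (factor 4 each) recovering
the input resolution. Training minimises

    L_total = L_rec + L_con · L_rec

where L_rec is the mean absolute reconstruction error against the
uncorrupted patch and L_con is the NT-Xent contrastive loss (temperature
0.05) over the globally pooled bottleneck features of the 2B views in a
batch — positives are sibling views, negatives the other 2B − 2 views, no
projection head, batch-only negatives. Optimised with Adam at a fixed 1e-4;
full-scale defaults 500 epochs, 96³ patches, batch 2; desk defaults 5
epochs, 32³ patches with window 2. Validation patches and their corruption
seeds are frozen at the start so the validation L1 curve is comparable
across epochs.

## Synthetic phantoms

The generator produces co-registered CT, PET, an integer organ-label map and
a lesion mask on a (z, y, x) voxel grid (3 mm isotropic). A soft-tissue
body ellipsoid (40 HU, background −1000 HU) contains seven organ analogues:
brain, heart, two lungs, liver, bladder and a spine column, each an
ellipsoid with an organ-specific CT range and a PET uptake range classed
low or high. The high-uptake organs (brain, heart, liver, bladder) are the
physiological decoys; when decoys are enabled their PET uptake (brain 5–7,
heart 3.5–5.5, liver 2–3, bladder 6–9 relative to body background 1.0)
overlaps the lesion range. Lesions are spheres placed by constraint-aware
sampling: fully inside the body, pairwise separated, and clear of every hot
organ — far enough that the lesion sphere cannot touch the organ (keeping
decoy uptake pure) and the tight ground-truth box cannot reach the organ's
core (inner 60%). An infeasible request fails loudly after bounded retries;
nothing is silently truncated. Both modalities then receive Gaussian noise
and Gaussian point-spread smoothing.

Two named regimes define the study conditions:

* `easy` — 48³, one or two large lesions (radius 5–7 voxels), uptake 9–13,
  +15 HU CT offset, decoys disabled: the miniature learning check.
* `decoy` — 48³, one or two lesions (radius 4–6), uptake 5–9 overlapping
  the hot organs, **zero** CT offset (lymphoma is CT-subtle on low-dose
  attenuation-correction CT), decoys enabled: the anatomy-prior regime.
  With a CT offset the lesions acquire a CT signature no real organ shares,
  the image-only model exploits it, and the anatomical confound the decoys
  exist to create disappears.

What the phantoms do not emulate: scanner physics (attenuation,
reconstruction kernels), inter-patient anatomical variability beyond small
position jitter, non-spherical lesion shapes, partial-volume effects beyond
Gaussian smoothing, and longitudinal or multi-tracer structure. A detector
that works here has been shown to exploit multi-channel intensity and an
anatomical label prior under controlled confounds — not to work on clinical
data.

## Evaluation

Predictions are matched to lesions greedily in descending score with
one-to-one consumption at a configurable IoU. Sensitivity is TP/(TP+FN).
AP is the discrete sum Σ (R_n − R_{n−1}) P_n with one threshold per distinct
score. The FROC curve pools all cases; its scalar score is the mean
sensitivity at FPPI operating points {1/8, 1/4, 1/2, 1, 2, 4, 8} (reading
the curve at the largest achieved FPPI below each point; mean-over-points
chosen over area-under-curve, both are common and this one is exposed in
config). mAP averages AP over IoU thresholds 0.1–0.5 in steps of 0.1.
Cases without lesions contribute false positives to FPPI but are excluded
from sensitivity denominators. Group-stratified reports reuse the same code
path on filtered case sets and are verified equivalent to standalone
evaluation.

## Desk-scale experiment sizes

The shipped experiments (tests and `scripts/acceptance.py`) use: 20 easy
phantoms (5 held out) for the learning check with the tiny CNN encoder
(~150 SGD iterations); 16 decoy phantoms (6 held out) per ablation arm with
12 × 25 iterations on 32³ patches, three seeded replicates; 8 phantoms and
5 epochs for the SSL convergence check. These sizes were chosen as the
smallest at which the respective effects are stable, so the whole suite
runs on a single CPU in minutes.

## Known limitations

* The numpy engine is single-device and eager; full-scale (96³, C = 96)
  training is out of reach by design — forward passes at that scale are
  exercised for the architecture contract only.
* Absolute metric values on phantoms are not comparable to clinical
  results; only directions and invariants transfer.
* The greedy matching protocol and fixed-IoU anchor assignment are the
  dominant conventions but not the only defensible ones; both are isolated
  behind small functions with brute-force oracle tests, so swapping them is
  cheap.
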