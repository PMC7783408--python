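# Methods

This note records the scientific and numerical choices behind
`lesionseg`: what is modeled, which parameters matter, what the phantom
generator does and does not emulate, and where genuinely open design
points were settled.

## Segmentation model

The network is a 3D residual encoder–decoder operating on whole volumes.
Configuration (`NetworkConfig`):

| parameter          | default | meaning |
|--------------------|---------|---------|
| `levels`           | 3       | down/upsampling stages; 2 is the halved-receptive-field variant |
| `encoder_width`    | 32      | channels in encoder blocks; 28/36 are the width ablations |
| `decoder_width`    | 64      | fixed at 2×encoder width by the skip concatenation |
| `blocks_per_stage` | 1       | residual blocks per level |
| `block_type`       | resnet  | `densenet` swaps in concatenative blocks |

Blocks use the pre-activation order ReLU → BatchNorm → Conv. That
ordering is unconventional but is retained deliberately as part of the
architecture's definition; with the residual shortcut it makes a block
whose convolutions are zeroed an exact identity.

Convolutions use "same" padding so the output grid equals the input
grid. Volumes whose spatial extent is not divisible by `2^levels`
(e.g. 18 slices under three poolings) are zero-padded on entry and the
output cropped, so the shape contract holds for any input. Upsampling
is trilinear with cell-centered (align-corners-off) semantics, fixed
for reproducibility. Where a channel-count change is needed, 1×1×1
bottleneck units (ReLU → BatchNorm → Conv) are used; there are no
transposed convolutions.

The block multiplicity inside each stage is not uniquely determined by
the architecture's published description; one block per encoder level,
one bridge block and one per decoder level is the choice here, with
`blocks_per_stage` exposed so deeper variants can be probed. With this
choice the theoretical receptive field of the three-level network is
118 voxels per axis, reported by `receptive_field`, which propagates
index dependencies exactly through the layer graph (branch joins take
unions; the extent is maximized over output-voxel parity). The
calculator is validated against a brute-force perturbation oracle on a
linearized network — all-positive convolution weights, zero biases,
BatchNorm at identity running statistics — for which a dependency is
visible as an exactly nonzero output.

`match_parameters` equalizes trainable-parameter counts across ablation
variants by scanning the variant's free width knob (encoder width, or
growth rate for DenseNet-style blocks) and picking the closest count;
parameter counts include convolution kernels, biases and BatchNorm
affine terms.

## Numerical engine

All layers and their gradients are implemented in numpy (float32), with
convolution as an im2col matrix product; the input gradient of a
stride-1 convolution is computed as a convolution with flipped,
channel-transposed kernels. BatchNorm uses per-volume statistics in
training (batch size 1 — full-volume steps) with running estimates
(momentum 0.1, eps 1e-5) for inference. Backward passes are verified
against central finite differences in the test suite; agreement is
limited only by float32 forward-pass noise (relative error ~1e-3–1e-2
at step 1e-3). Everything is deterministic given the initialization
seed.

## Loss and optimization

`L_total = L_BCE + L_Dice` on the softmax lesion probability. Numerical
guards: probabilities entering logarithms are clipped at 1e-7 (finite
loss under saturation), and the Dice loss carries a smoothing constant
s = 1e-6 in numerator and denominator, which both stabilizes the
gradient when the denominator is small and makes the empty-vs-empty
case a perfect score. For a binary prediction and s → 0, the Dice loss
is exactly one minus the Dice overlap.

The two-class softmax reduces to a sigmoid of the logit margin; the
loss gradient is taken analytically through that sigmoid.

Defaults follow the reference protocol: Adam (0.9, 0.999, 1e-8),
constant learning rate 1e-5, 700 epochs, batch size 1 (full-volume
steps; the batch size is not pinned down by the protocol and 1 is the
standard choice for whole-volume 3D segmentation). No augmentation and
no learning-rate schedule. A validation set may be supplied; both the
final-epoch and the best-validation-Dice weights are retained, and
inference defaults to the latter — strictly more informative than
keeping only the fixed-epoch endpoint, which remains available.

Three runs differing only in seed (`base_seed + run_index`) are fused
by voxel-wise majority voting on binary labels. Even ensembles are
rejected rather than tie-broken; probability averaging exists as a
non-default option.

## Phantoms

`generate_phantom` emulates the acquisition geometry of the target
data: anisotropic voxels of 0.117 × 0.117 × 1.0 mm and 18 coronal
slices, desk-scaled in-plane to 64×64 by default (256×256 available via
`grid_shape`). The scene is piecewise-constant: background 0, an
ellipsoidal brain of intensity 10, and hyperintense lesion voxels at
brain + `lesion_contrast` (default 4.0, i.e. the T2-hyperintense
appearance), plus additive Gaussian noise (`noise_sigma`, default 1.0).
Lesions are unions of 1–4 random spheroids seeded in one hemisphere
(right by default, matching unilateral occlusion models), smoothed and
re-thresholded to roughen the boundary, and clipped to brain ∩
hemisphere. Gaussian rather than Rician noise is used deliberately: at
the SNRs simulated the difference is minor, and Gaussian noise keeps the
lesion-contrast contract (lesion minus healthy-tissue mean ≈ contrast)
exactly testable.

What the phantoms do **not** emulate: MR bias fields, partial-volume
effects, skull/CSF compartments, stage-dependent lesion texture, and
the lesion-volume distribution across time points (no public
quantitative description exists). Passing the desk-scale tests
therefore demonstrates that the pipeline's machinery — optimization,
ensembling, post-processing, metrics — works end to end, not that the
tiny networks would reach publication-grade accuracy on real scans.

`corrupt_mask` injects defects of *exact* requested voxel counts:
islands are grown in the background at ≥3 voxels' separation from all
foreground (so 26-connectivity labeling keeps them distinct), holes are
carved strictly inside the eroded main component (every cavity voxel
keeps a foreground shell, so it is a 6-connected background component
with no border path). Grown shapes that would enclose an unplanned
cavity (or carve out an unplanned island) are rejected and regrown; the
result is re-verified by independent component labeling and generation
fails loudly rather than deliver a wrong inventory.

## Post-processing

Islands are foreground components other than the largest
(26-connectivity; size ties broken toward the component with the
lexicographically smallest seed voxel); holes are background components
with no path to the volume border (6-connectivity). The complementary
26/6 pairing avoids the classic topological paradox of treating a
diagonal crack as both connected foreground and connected background;
both are configurable, and holes are defined in 3D, not per slice.
`remove_small` removes islands first, then recomputes and fills holes —
removing an island cannot create a hole under these definitions, and
the operation is idempotent (tested). `auto_threshold` returns the
smallest integer removing at least the requested fraction (default
90%) of an observed defect-size inventory, falling back to the
operating default of 20 voxels for an empty inventory.

## Metrics

* **Dice**: voxel-count overlap. Two empty masks score 1.0 (a correctly
  predicted sham animal); empty vs non-empty scores 0.
* **Surface area**: sum of exposed voxel faces weighted by physical
  face area; faces on the volume border count as exposed (a mask
  touching the image edge still has surface there).
* **Compactness** = area^1.5 / volume, dimensionless and invariant
  under isotropic spacing rescaling (verified to 1e-9 relative). Note
  that face-counted areas overestimate smooth surfaces by 3/2 in the
  fine-resolution limit, so a digitized ball converges to
  (6π)^1.5/(4π/3) ≈ 19.55 rather than the smooth-sphere minimum
  6√π ≈ 10.63; realistic solid masks therefore sit near ~20, and the
  often-quoted sphere minimum "6π" appears to drop a square root
  (6√π) even for ideal surfaces. The implementation follows the
  formula, not the quoted constant.
* **Hausdorff distance**: symmetric max–min distance between boundary
  voxel centers in mm (boundary = foreground voxels with an exposed
  6-face), computed with Euclidean distance transforms using the voxel
  spacing — exact for center-to-center distances and verified against
  the O(|∂A|·|∂B|) brute force.
* Compactness and Hausdorff are *undefined* (NaN, excluded from
  aggregates) when a mask is empty, so sham scans never distort
  surface statistics.
* **Paired permutation test**: sign-flip test on the mean paired
  difference, two-sided; exact enumeration when 2^n ≤ iterations,
  otherwise the add-one Monte-Carlo estimator (p never 0). Default
  10,000 iterations. Calibration at the 5% level is checked by
  simulation in the test suite.

## Desk-scale study

The end-to-end experiment (`lesionseg.experiments`) scales the protocol
to one CPU: 15 phantoms (8 train / 2 validation / 5 test) on 64×64×16
grids with high-contrast lesions (contrast 6, noise 1), a two-level
network of encoder width 4, 30 epochs at learning rate 1e-3 (Adam's
conventional small-problem rate; the full-size 1e-5/700-epoch schedule
is far too slow for a tiny model on easy phantoms), three runs fused by
majority vote and cleaned at the 20-voxel threshold. The study
reproduces the qualitative claims at this scale: the fused ensemble
reaches mean Dice ≥ 0.8 on held-out phantoms and is at least as good
as the worst individual run.

## Known limitations

* Full-size training (256×256×18, width 32, 700 epochs) is supported by
  the code but impractical without hardware acceleration; the numpy
  engine is written for correctness and desk-scale speed.
* BatchNorm running statistics after very short trainings are noisy;
  validation Dice early in training reflects that.
* The phantom generator's severity knobs are not calibrated to any real
  lesion-stage distribution.
* Only two-class (lesion / non-lesion) segmentation is implemented.
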