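# lesionseg

Automated segmentation of ischemic brain lesions in rodent MR volumes.

Pre-clinical stroke studies (middle cerebral artery occlusion in rats)
produce hundreds of 3D T2-weighted scans whose lesions are still mostly
delineated by hand — slow work with only moderate inter-rater agreement.
`lesionseg` implements the **RatLesNetV2** approach to automating it: a 3D
residual encoder–decoder convolutional network trained end to end on whole
volumes with no preprocessing beyond intensity standardization, plus the
full protocol around it — a composite loss, majority-vote ensembling of
independent runs, connected-component post-processing, and an
anisotropy-aware evaluation suite. Because pre-clinical MR datasets are
rarely shareable, the package also ships a phantom generator so the entire
pipeline is testable and demonstrable on synthetic rat-brain volumes.

## The method

**Architecture.** An autoencoder-like network with three downsampling /
upsampling stages connected by skip connections. Each encoder level applies
a residual block (two stacks of ReLU → BatchNorm → 3×3×3 convolution, input
added to output) followed by 2×2×2 max pooling; the decoder mirrors it with
trilinear upsampling, concatenation of the same-level encoder output (the
decoder therefore runs at twice the encoder width, 64 vs 32 channels), a
1×1×1 bottleneck, and another residual block. A final bottleneck maps to
two channels and a per-voxel softmax

$$q_i = \frac{e^{z_i}}{\sum_{j=1}^{2} e^{z_j}},$$

with the predicted label $\arg\max_i q_i$. No transposed convolutions are
used. Ablation variants (halved depth, width ±4, DenseNet-style blocks
with parameter matching) are plain configuration changes.

**Loss.** With ground truth $p_i \in \{0,1\}$ and lesion probability
$q_i$, training minimizes $L_{total} = L_{BCE} + L_{Dice}$ where

$$L_{BCE} = -\tfrac{1}{N}\textstyle\sum_i p_i \log q_i + (1-p_i)\log(1-q_i),
\qquad
L_{Dice} = 1 - \frac{2\sum_i p_i q_i}{\sum_i p_i^2 + \sum_i q_i^2},$$

optimized with Adam ($\beta_1{=}0.9$, $\beta_2{=}0.999$,
$\epsilon{=}10^{-8}$). Three independent runs are fused by voxel-wise
majority voting.

**Post-processing.** Predicted masks are cleaned by removing *islands*
(foreground components disconnected from the largest component) and
filling *holes* (enclosed background cavities) of at most 20 voxels — the
threshold at which ~90% of observed defects disappear, recomputable for
any defect inventory with `auto_threshold`.

**Evaluation.** Dice overlap $2|A\cap B|/(|A|+|B|)$; compactness
$\mathrm{area}^{1.5}/\mathrm{volume}$ (lower = smoother, more realistic
masks); Hausdorff distance (the largest boundary-to-boundary error, in mm).
Surface areas and distances use physical voxel geometry, so the strongly
anisotropic voxels (0.117 × 0.117 × 1.0 mm) are handled correctly.
Surface metrics are left undefined on empty (sham) masks; paired
permutation tests assess significance of metric differences.

The network engine (3D convolutions, batch norm, pooling, trilinear
upsampling, backpropagation, Adam) is implemented directly in numpy and
validated against finite differences; no GPU or deep-learning framework is
required.

## Worked example

```python
import numpy as np
from lesionseg import (PhantomConfig, generate_dataset, normalize,
                       NetworkConfig, TrainConfig, train, predict,
                       majority_vote, remove_small, evaluate_set)

# 12 synthetic rat-brain volumes with unilateral hyperintense lesions
cfg = PhantomConfig(grid_shape=(64, 64, 16), lesion_contrast=6.0, noise_sigma=1.0)
data = [(normalize(v), m) for v, m in generate_dataset(12, cfg, seed=100)]
train_set, val_set, test_set = data[:8], data[8:10], data[10:]

# three independent tiny trainings, majority-voted
members = []
for run in range(3):
    res = train(NetworkConfig(levels=2, encoder_width=4), train_set, val_set,
                TrainConfig(learning_rate=1e-3, epochs=30, seed=run))
    members.append([predict(res.use_best(), v)[1] for v, _ in test_set])

fused = [remove_small(majority_vote([m[i] for m in members]), 20)
         for i in range(len(test_set))]
report = evaluate_set(fused, [t for _, t in test_set])
print(report.per_scan)
```

Output (one CPU, a few minutes):

```
    scan_id      dice  compactness  hausdorff_mm
0  scan_000  0.917752    28.720180      0.421849
1  scan_001  0.901333    20.059207      0.234000
```

Per held-out scan: Dice above 0.9 means the predicted and true lesions
overlap almost completely; compactness of 20–29 is the range of solid,
fairly smooth masks (a digitized ball sits near 19.5 under face-counted
surface area); and a Hausdorff distance of 0.2–0.4 mm says the worst
boundary error is just a few in-plane voxels.

The same workflow is available from the shell:

```bash
lesionseg generate -n 12 --seed 100 --out data/
lesionseg train --dataset data/ --runs 3 --out ckpt/
lesionseg predict --checkpoint ckpt/run_0.npz --checkpoint ckpt/run_1.npz \
                  --checkpoint ckpt/run_2.npz --input data/phantom_010_img.nii.gz \
                  --out preds/
lesionseg evaluate --pred-dir preds/ --truth-dir truth/ --out report
```

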