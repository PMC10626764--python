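# hogseg

Multi-task semantic segmentation of surgical scenes in which the auxiliary
task — regressing a Histogram-of-Oriented-Gradients (HOG) descriptor of the
input image — is supervised by *pseudo-labels computed without any human
annotation*. The package is aimed at researchers in medical image analysis
who want to squeeze more out of a fixed annotation budget: the HOG map of a
surgical frame sharply demarcates instruments from anatomy, so forcing a
segmentation network to also predict it pushes the shared encoder towards
boundary-aware representations.

## Method

Given training triplets (x, y, y^pl) — image, ground-truth class mask, and
HOG pseudo-label — the network minimizes

```
L = (1/N) Σᵢ [ α · L_ce(xᵢ, yᵢ) + β · L_hog(xᵢ, yᵢ^pl) ]
```

where `L_ce` is the per-pixel categorical cross-entropy of the segmentation
output and `L_hog` is the mean-squared error of the auxiliary HOG
regression. Defaults are α = β = 1.

**Pseudo-labels.** Each image is resized to a 64×128 window, converted to
luminance, and filtered with central-difference kernels [−1, 0, 1] (and its
transpose). Gradient magnitudes vote into k = 6 unsigned-orientation bins
(30° each over 0–180°, nearest-bin voting) per non-overlapping cell;
2×2-cell blocks slid at 1-cell stride are L2-normalized and concatenated.
Cell sizes 16×16 / 12×12 / 8×8 give descriptors of dimension
**504 / 864 / 2520**.

**Backbones.** A configurable UNet (one auxiliary head on the bottleneck)
and a nested-U architecture, U2Net, built from residual U-blocks with
deep-supervision side outputs (one auxiliary head on the bottom stage and on
every decoder stage). Each head is a 1×1 adapter to 3 channels, two
(3×3 conv → ReLU → 2×2 max-pool) stages, flatten, and a linear map to the
descriptor dimension D. The networks run on a small numpy autograd engine
included in the package (`hogseg.nn`), so everything trains deterministically
on one CPU at desk scale.

**Evaluation** is per-class IoU = TP/(TP+FP+FN) and its mean (mIoU), with
pooled-confusion and per-image averaging modes.

## Worked example

```python
import dataclasses
from hogseg.config import desk_scale_config
from hogseg.synthetic import generate_samples
from hogseg.training import attach_pseudo_labels, train

cfg = desk_scale_config(seed=1)           # tiny UNet, 64x128 inputs
samples = generate_samples(cfg.scene, 4)  # synthetic surgical scenes
attach_pseudo_labels(samples, cfg.hog)    # 504-dim HOG targets
tc = dataclasses.replace(cfg.train, max_iters=1200, validate_every=200)
res = train(samples, cfg.model, tc)
print(res.metrics.to_string())
```

prints (about 100 s on one CPU):

```
   iteration      lr     total        ce       hog  val_miou
0        200  0.0002  0.892542  0.858822  0.033720  0.322098
1        400  0.0002  0.439675  0.423493  0.016182  0.506340
2        600  0.0002  0.290710  0.283742  0.006968  0.564633
3        800  0.0002  0.112752  0.110585  0.002168  0.914830
4       1000  0.0002  0.045117  0.044505  0.000611  0.954788
5       1200  0.0002  0.039357  0.039162  0.000195  0.960584
```

`total` is the joint loss α·ce + β·hog; `ce` (cross-entropy) and `hog`
(auxiliary MSE) both shrink as the model fits the four scenes, and the
mean IoU over the training pool climbs to 0.96 — the model has learned to
delineate the synthetic anatomy and instrument classes. The learning rate
stays at its initial 2e-4 because the halving schedule steps only every
50k iterations.

The same pipeline is available from the shell:

```bash
hogseg synth --out data --n-train 10 --n-val 2 --n-test 2
hogseg pseudolabel --data data --out store.h5
hogseg train --data data --store store.h5 --out run
hogseg eval --data data --checkpoint run/checkpoint.npz --out eval
```

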