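# osteoformer

Semantic segmentation of bone from CT-slice-like grayscale images, built
for the *small-dataset* regime that medical imaging usually lives in —
expert-labelled ground truths are expensive, so a few hundred annotated
slices is a realistic budget.

The toolkit implements a data-efficient variant of the SegFormer family:

* a **hierarchical mix-transformer encoder** whose Mix-FFN 3x3 depthwise
  convolution stack is deepened from 1 to M ∈ [1, 5] layers, and whose
  per-stage feature resolutions are configurable fractions of the input
  side — the data-efficient schedule keeps the first stage at **full input
  resolution** (1, 1/2, 1/4, 1/8) instead of the standard quarter-resolution
  start (1/4, 1/8, 1/16, 1/32);
* two decoder heads: the baseline **All-MLP** fusion and an **FPN decoder
  with per-level self-attention** (top-down upsampling plus 3x3-convolved
  lateral fusion, each combined level refined by spatially-reduced
  attention);
* the evaluation stack: per-image pixel confusion counts,
  IoU = TP/(TP+FP+FN) and DSC = 2TP/(2TP+FP+FN), with the per-image
  identity DSC = 2·IoU/(1+IoU);
* the model-comparison harness: K-fold cross-validation, the Friedman rank
  test (χ² with k−1 df) and the Nemenyi post-hoc test on mean-rank
  differences against the studentized range distribution;
* a **synthetic phantom generator** (concave vertebra cross-sections,
  multi-bone hand layouts with thin gaps, simple femur shafts, all with
  exact masks) plus Gaussian-noise augmentation and 8:1:1 splitting, so the
  whole pipeline runs and is tested without any patient data.

Everything runs on plain numpy/scipy — the neural network layers, autodiff
and Adam optimiser live in `osteoformer.nn` and are finite-difference
tested. No GPU or deep-learning framework is required.

## Worked example

Train the tiny proposed configuration on synthetic phantoms and compare it
against the SegFormer-like baseline:

```python
import numpy as np
from osteoformer import BoneSegmenter, evaluate_set
from osteoformer.phantoms import generate_dataset

train = generate_dataset(24, size=64, seed=0)     # mixed anatomies
test  = generate_dataset(30, size=64, seed=500)
X,  y  = np.stack([s.image for s in train]), np.stack([s.mask for s in train])
Xt, yt = np.stack([s.image for s in test]),  np.stack([s.mask for s in test])

for name in ("tiny_proposed", "tiny_baseline"):
    est = BoneSegmenter(config=name, epochs=20, seed=0).fit(X, y)
    ev = evaluate_set(list(est.predict(Xt)), list(yt))
    print(f"{name}: mean IoU {ev.mean_iou:.3f}  mean DSC {ev.mean_dsc:.3f}")
```

```
tiny_proposed: mean IoU 0.999  mean DSC 0.999
tiny_baseline: mean IoU 0.878  mean DSC 0.933
```

The full-resolution first stage is what separates the two here: at 64 px
the baseline's finest feature map is 16 px, too coarse for thin inter-bone
gaps, while the proposed encoder keeps every pixel in play and the FPN
decoder fuses the scales back together. Dice reads above IoU on the same
predictions because DSC = 2·IoU/(1+IoU) per image.

Comparing several methods' cross-validation scores:

```python
from osteoformer import ScoreMatrix, friedman_test, nemenyi_test

m = ScoreMatrix.from_csv("scores.csv")   # folds x methods mean IoUs
fr = friedman_test(m)                    # e.g. chi2(4) = 40.00 when one
print(fr.statistic, fr.p_value)          # method ordering holds in all folds
print(nemenyi_test(m).to_frame())        # pairwise p-values
```

The same flows are scriptable from the shell:

```bash
osteoformer generate --anatomy mixed --n 30 --size 64 --seed 0 --out data/
osteoformer train --preset tiny_proposed --data data/manifest.jsonl --out run/
osteoformer eval --ckpt run/checkpoint.npz --data data/manifest.jsonl --report report.json
osteoformer ablate --grid attention --data data/manifest.jsonl --out ablation.csv
osteoformer compare --scores scores.csv --alpha 0.05
```

See `docs/methods.md` for the model details, the training protocol
(batch 4, 20 epochs, Adam at 1e-3, pixel-wise cross-entropy over
foreground/background), the phantom design and its limitations, and every
numerical choice.

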