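# aanet — aggregation-and-attention network for brain-tumor MRI segmentation

`aanet` segments gliomas on multi-modal brain MRI (T1, T2, T1ce, FLAIR) into
the three nested clinical regions — whole tumor (WT), core tumor (CT) and
enhancing tumor (ET) — using a U-Net-shaped encoder–decoder augmented with:

* **EDS** encoder stages: residual double convolutions
  `maxpool(conv(conv(x)) + conv₁ₓ₁(x))` with a fused low/high-level side
  feature feeding a deep-supervision head;
* **MSC** skip connections: parallel 1×1 and dilated 3×3 convolutions
  (rates 6/12/18) fused in place of the plain skip;
* a **DAF** bottleneck with dual attention — positional attention
  `EA_j = α Σᵢ softmax_i(Aᵢ·Bⱼ) Cᵢ + x_j` over all pixel pairs, and a
  convolution-free channel attention `CA_j = β Σᵢ softmax_i(xⱼ·xᵢ) xᵢ + x_j`
  over channel pairs (three fusion variants DAF1/2/3);
* **US** decoder stages mirroring EDS with bilinear upsampling, each with a
  supervision head.

Training minimizes the deeply supervised composite loss

    L_total = λ₁ (L_down + L_up) + λ₂ L_dual + L_result,
    L = 0.5·L_BCE + L_Dice  per head,   λ₁ = 0.4,  λ₂ = 0.2,

with Adam (lr 3e-4), batch 16, early stopping (patience 20) on mean
validation Dice.  Evaluation reports Dice, precision, sensitivity and
Hausdorff distance per region.

The package includes BraTS-layout NIfTI preprocessing (z-score over the
brain support, 160×160 center crop, axial slicing, modality stacking), a
synthetic multi-modal phantom generator so the entire pipeline runs and is
tested without any external dataset, and the compact NumPy reverse-mode
autodiff engine (`aanet.nn`) the network runs on — no deep-learning
framework is required.  See `docs/methods.md` for the full model
description and design choices.

## Worked example

Train a reduced-width network on synthetic phantoms from the shell:

```bash
aanet phantom --out data/phantoms --n-slices 24 --image-size 64 --seed 3
aanet train --data data/phantoms --out runs/demo --config examples/demo.yaml
aanet evaluate --checkpoint runs/demo/checkpoint.npz \
               --data data/phantoms --out runs/demo/report.csv
```

or the equivalent in Python:

```python
import numpy as np
from aanet import (PhantomSpec, generate_dataset, NetConfig, TrainConfig,
                   fit, labels_to_regions, evaluate)
from aanet.train import predict_samples

samples = generate_dataset(PhantomSpec(image_size=64, seed=3), 24, seed=3)
config = TrainConfig(batch_size=8, max_epochs=60, early_stop_patience=20,
                     seed=0, net=NetConfig(base_channels=8, seed=0))
model, log = fit(samples[:16], samples[16:], config)
report = evaluate(predict_samples(model, samples[16:]),
                  [labels_to_regions(s.label) for s in samples[16:]])
print(report)
```

which prints (the run is deterministic for this seed; ~3 minutes on 1 CPU):

```
       dice  precision  sensitivity  hausdorff
wt   0.9400     0.9175       0.9689     4.6951
ct   0.8827     0.8037       0.9840    18.8592
et   0.8656     0.7950       0.9565     3.5431
mean 0.8961     0.8387       0.9698     9.0325
```

Row `mean` averages each index over the three regions.  Dice/precision/
sensitivity are in [0, 1] (1 = perfect); Hausdorff is the boundary distance
in pixels (0 = perfect).  Held-out Dice near 0.9 after 60 short epochs on
these simple elliptical phantoms; the inflated core-tumor Hausdorff comes
from a few scattered false-positive islands, which the boundary-distance
index punishes much harder than the overlap indexes do.

`aanet predict --checkpoint ... --case <folder>` segments a BraTS-layout
case folder (`<id>_t1/_t2/_t1ce/_flair[.nii|.nii.gz]`) and writes the
predicted label volume as NIfTI, re-embedded into the original 240×240
frame.

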