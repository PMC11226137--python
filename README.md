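# gleasonpatch

Multi-label, one-vs-all CNN ensemble for patch-level Gleason grading of
prostate histopathology, with auditing of the label noise that
majority-vote patch labelling introduces.

## The problem

Patch-level Gleason datasets annotate tissue per pixel (non-cancerous NC,
or Gleason patterns G3 < G4 < G5) but conventionally label each 512×512
patch with the single *majority* grade. A patch mixing grades therefore
silently mislabels every off-majority pixel — on real data the
off-majority area of a patch reaches ~30% — which both discards clinical
information (a minority high-grade focus) and injects label noise into
any classifier trained on the patch labels.

`gleasonpatch` implements the multi-label alternative:

- **Relabelling.** A grade g enters a patch's multi-label iff its pixel
  count reaches `max(min_count, ⌊τ·N⌋)` with τ = 0.01 by default (for a
  512×512 patch, exactly 2621 pixels). NC is asserted only when the patch
  contains *zero* grade pixels. Patches with sub-threshold cancer only
  are flagged `excluded`.
- **Auditing.** For every patch, the fraction of pixels belonging to each
  off-majority grade; aggregated per fold into mean/max statistics and
  1-percentage-point histograms.
- **Ensemble classifier.** Three binary one-vs-all CNNs (one per grade),
  each a truncated ResNet18 variant: stem 7×7/64 stride 2 + BN + ReLU +
  2×2 max-pool, the conv2 (3×3/64) and conv3 (3×3/128, stride-2 entry)
  basic blocks, and only the first half of conv4 (3×3/256, stride 1, with
  projection skip), ending in global average pooling and a 2-way softmax
  head. Activation sizes on a 224×224×3 input: 112×112×64 → 56×56×64 →
  28×28×128 → 1×1×256 → 2.
- **Training recipe.** Adam, base LR 1e-3 dropped ×0.1 every 15 epochs,
  head LR ×10, L2 = 1e-2 on conv/FC weights, class-weighted
  cross-entropy `L = Σᵢ w_{yᵢ} ℓᵢ / Σᵢ w_{yᵢ}` with inverse-frequency
  default weights `w_c = n/(2 n_c)`, resize/rotate/translate/flip
  augmentation, up to 50 epochs with early stopping after 8 consecutive
  epochs of rising validation loss (best weights restored).
- **Decision rule & metrics.** Grade g is predicted iff its score exceeds
  a per-grade threshold selected at the F1 optimum of the validation
  precision–recall curve; NC iff no grade is predicted. Evaluation
  reports per-class F1 over {NC, G3, G4, G5}, their macro average,
  macro-averaged binary accuracy and exact-match (subset) accuracy.
- **Explanations.** Grad-CAM on the final convolutional ReLU (the input
  to global average pooling), and slide-level activation maps stitched
  from overlapping patches.
- **Synthetic data.** A deterministic generator of H&E-like slides with
  planted, pixel-exact grade regions, patient-exclusive 5-fold splits
  (Val1–Val4 + Test), 50%-overlap patch tiling and an Otsu 20%-tissue
  filter, so the entire pipeline is testable without any external
  dataset. The CNN stack itself (layers, backprop, Adam, Grad-CAM) is
  implemented in NumPy inside the package.

## Worked example

```python
import numpy as np
from gleasonpatch import GRADES, LabelPolicy, TrainConfig
from gleasonpatch.synthetic import SyntheticConfig, generate_dataset
from gleasonpatch.train import train_sub_classifier
from gleasonpatch.ensemble import EnsembleModel, select_thresholds, evaluate

cfg = SyntheticConfig(n_patients=10, slides_per_patient=3,
                      slide_size=(384, 384), patch_size=128, seed=7)
manifest, _ = generate_dataset(cfg, "dataset")
policy = LabelPolicy(tau=0.01)
tc = TrainConfig(input_size=64, max_epochs=10, batch_size=16)

models = {g: train_sub_classifier(manifest, g, policy, tc, seed=1)[0]
          for g in GRADES}
ensemble = EnsembleModel(sub_models=models)
select_thresholds(ensemble, manifest, policy, folds=["Val4"])
report = evaluate(ensemble, manifest, policy, folds=["Test"])
print({k: round(v, 3) for k, v in report.per_class_f1.items()})
print("macro F1", round(report.macro_f1, 3), "accuracy", round(report.accuracy, 3))
```

On this 398-patch dataset the run prints

```
{'NC': 0.952, 'G3': 0.935, 'G4': 0.928, 'G5': 0.986}
macro F1 0.95 accuracy 0.961
```

i.e. with thresholds tuned only on the Val4 fold, the ensemble recovers
the planted per-patch multi-labels of the held-out Test fold almost
perfectly; the residual errors are patches whose off-majority grade just
clears the 1% pixel threshold.

The same pipeline is available from the shell:

```bash
gleasonpatch synth --out dataset --seed 7 --n-patients 10
gleasonpatch relabel --manifest dataset/manifest.csv --out relabelled
gleasonpatch stats   --manifest dataset/manifest.csv --out audit
gleasonpatch train   --manifest dataset/manifest.csv --grade G4 --out models
gleasonpatch evaluate --manifest dataset/manifest.csv --models models --out eval
gleasonpatch explain --image dataset/images/P000_S00_r0_c0.png \
    --models models --grade G4 --out heatmaps
```

## Layout

- `src/gleasonpatch/io_formats.py` — masks (paletted PNG), manifests
  (CSV), run configuration (YAML)
- `src/gleasonpatch/relabel.py` — majority vote, multi-labels,
  inconsistency audit, one-vs-all targets
- `src/gleasonpatch/synthetic.py` — slide/patch generator, Otsu tissue
  mask, tiling
- `src/gleasonpatch/nn/` — NumPy CNN: layers, truncated ResNet18
  variant, weighted CE, Adam
- `src/gleasonpatch/train.py` — LR schedule, early stopping,
  augmentation, the training loop
- `src/gleasonpatch/ensemble.py` — multi-label decision rule, PR curves,
  threshold selection, metrics
- `src/gleasonpatch/explain.py` — Grad-CAM and slide activation maps
- `src/gleasonpatch/cli.py` — the `gleasonpatch` command

See `docs/methods.md` for modelling choices and limitations.
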