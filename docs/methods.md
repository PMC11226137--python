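# Methods

## Relabelling model

Annotation masks code each pixel as BG (no tissue), NC (benign tissue)
or one of the Gleason patterns G3/G4/G5. The majority-vote label of a
patch is the grade with the largest pixel count; BG is ignored and NC is
returned only when no grade pixel exists. Ties between grades break
toward the higher grade — the clinically conservative choice, since an
underestimated high-grade focus is the costlier error.

The multi-label of a patch asserts grade g iff

    count_g >= max(min_count, floor(tau * N))

with defaults tau = 0.01, min_count = 1 and N the *full* patch area
(512² = 262144 pixels, so the default threshold is exactly 2621 pixels).
The all-pixels denominator is the default because it is the only choice
consistent with the 2621-pixel arithmetic of the tuned recipe; a
tissue-pixels denominator is available as a `LabelPolicy` option.
`min_count = 1` guarantees that tau = 0 never admits a grade with zero
pixels. NC is asserted iff the patch contains zero grade pixels of any
kind; consequently a patch whose cancer is entirely sub-threshold gets
neither a grade nor NC. Such patches are tagged `excluded`: they are
removed from one-vs-all training and from evaluation (but counted),
because under the labelling model they are genuinely ambiguous — keeping
them would re-inject exactly the label noise the multi-label scheme is
meant to remove.

The inconsistency audit reports, per fold and grade, the mean and
maximum off-majority pixel fraction. By default the statistics are taken
over patches where the grade occurs off-majority (fraction > 0), which
is the population that makes the maximum meaningful; an `include_zero`
switch averages over all patches instead. Distributions are emitted as
histograms with 1-percentage-point bins rather than density estimates:
the bin width matches the reporting precision and avoids a smoothing
bandwidth choice.

## Architecture

Each sub-classifier is a deliberately truncated ResNet18: stem
(7×7/64, stride 2, BN, ReLU, 2×2 max-pool), the 64-channel basic block
(two 3×3 convs, identity skip), the 128-channel basic block (stride-2
entry, 1×1 projection skip), and only the *first half* of the
256-channel group — a single 3×3/256 stride-1 conv with BN and a 1×1
projection skip, closed by a ReLU. Global average pooling over the
resulting 256 feature maps feeds a fully connected 2-way softmax head.
The conv5 group and the second conv4 block are removed; on small,
imbalanced patch datasets the full network overfits, and this truncation
keeps the residual wiring intact (the final ReLU output is exactly the
feature map Grad-CAM needs) while roughly halving the parameters.

The network is implemented directly in NumPy inside the package
(`gleasonpatch.nn`): im2col convolution, batch normalization with
running statistics, 2×2 max-pooling, explicit backward passes, and an
Adam optimizer with parameter groups. Float64 arithmetic is used
throughout, which keeps analytic gradients within 1e-4 of central finite
differences (verified in the tests) at the problem sizes this package
targets. Weight init is He-normal, seeded.

ImageNet-pretrained initialization is part of the published recipe, but
no weight archive ships with the package; `build_model(init="pretrained")`
raises with instructions, and every test and script uses `init="random"`.
On the synthetic data this costs little because the classes are designed
to be separable from scratch (below); on real histopathology data random
init would need substantially more data/epochs than the defaults assume.

## Training recipe

Defaults (all overridable in `TrainConfig`):

| parameter | default | note |
|---|---|---|
| optimizer | Adam | β₁ = 0.9, β₂ = 0.999 |
| base LR | 1e-3 | dropped ×0.1 every 15 epochs |
| head LR | ×10 base | fresh head adapts faster than the backbone |
| L2 | 1e-2 | conv/FC weights only, not biases or BN |
| epochs | ≤ 50 | early stop after 8 consecutive val-loss rises |
| batch | 16 | |
| input | 224×224 | bilinear resize from the 512×512 patch |
| augmentation | flips p=0.5, rotation ±15°, translation ±10% | training folds only |

The loss is class-weighted cross-entropy, normalized by the sum of the
per-sample weights so that uniform weights reduce exactly to plain
cross-entropy. Default weights are inverse-frequency, w_c = n/(2·n_c),
computed on the training targets of each one-vs-all problem.

"Validation loss rising" is a strict comparison against the immediately
preceding epoch; any equal-or-lower epoch resets the counter, so the
stop cannot fire before epoch patience+1. On stopping (or on reaching
the epoch cap) the weights of the best-validation-loss epoch are
restored — standard practice, and cheap insurance given that the final
epochs of a stopped run are by construction the worst ones.

Augmentation parameters (rotation ±15°, translation ±10%, flip p=0.5)
and batch size are package choices; bilinear interpolation is pinned for
both the 512→224 resize and the augmentation warps so runs are
reproducible bit-for-bit given a seed. BN layers keep training during
fine-tuning.

## Ensemble decision rule and metrics

Each sub-classifier emits the softmax probability of its positive class;
the three scores are independent and need not sum to 1. Grade g is
predicted iff score_g > threshold_g (strict — a score exactly at the
threshold is negative), NC iff no grade is predicted, so the predicted
multi-label satisfies the same NC invariant as the reference labels by
construction.

Thresholds are selected per grade on validation data as the F1-optimal
point of the precision–recall curve. The sweep uses every unique score
plus a sentinel below the minimum, so the curve spans recall 1 → 0;
precision at an empty prediction set is defined as 1 (no false alarms),
F1 as 0 when P+R = 0; ties in best F1 resolve to the lowest threshold
(favouring recall). A selected threshold is clamped to [0, 1]: softmax
scores are strictly inside the unit interval, so when the optimum is the
below-minimum sentinel (predict everything positive), threshold 0
induces the same decisions.

The evaluation treats {NC, G3, G4, G5} as four binary presence/absence
problems: per-class F1, macro F1 (their arithmetic mean), and accuracy
as the macro average of the four per-problem binary accuracies. Because
"accuracy" is not uniquely defined for multi-label output against
multi-class baselines, the exact-match (subset) accuracy is reported
alongside. Reference labels at evaluation time use the same `LabelPolicy`
as training by default; a different test-time tau can be passed.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes —
not histology. Each slide is a white background with one contiguous
tissue region; grade regions are carved from smoothed-Gaussian-noise
level sets, so they are compact blobs with pixel-exact planted areas
(the top-k pixels of the field are taken, making area fractions exact up
to rounding, which the recovery tests exploit). Textures are procedural
and colour-separated: pale pink NC, pink with dark ringlets (G3), violet
with dense dots (G4), near-solid dark purple (G5), plus Gaussian pixel
noise on tissue. Patients are assigned round-robin to the five folds
(Val1–Val4, Test), slides are tiled into 50%-overlap patches, and
windows under 20% Otsu tissue are dropped. Grayscale for Otsu is Rec.601
luminance, quantized to uint8 so the threshold search is exactly
reproducible against a brute-force oracle.

What passing tests on this data do show: the relabelling arithmetic, the
fold bookkeeping, the training loop, threshold selection and the metric
stack are correct, and the ensemble recovers planted multi-labels from
images alone. What they do not show: robustness to stain variation,
scanner artefacts, morphological (rather than colour) class differences,
or annotation noise — real-data performance claims need real data.

Default study conditions for the end-to-end run: 10 patients × 3 slides
of 384², patch 128 with 50% overlap (≈ 400 patches), network input
64×64, 10 epochs, batch 16. These sizes keep a full from-scratch run
(three trainings + evaluation) around ten minutes on one CPU while
leaving each fold with all four classes represented; the generator's
`SyntheticConfig` defaults (2048² slides, 512 patches) describe the
full-scale layout the package targets.

## Numerical and degenerate-input choices

- Mask I/O is single-channel paletted PNG with codes 0–4; arbitrary
  dataset encodings map through a configurable palette, and an unmapped
  pixel value is a hard error naming the value and file.
- Majority vote on an all-BG mask is an error (no tissue, no label).
- Otsu on a constant image returns an all-background mask.
- MaxPool routes gradients to the argmax element (first on exact ties).
- PR curves require both classes; degenerate validation folds raise.
- All randomness flows through `numpy.random.Generator` objects seeded
  from explicit integers; identical seeds give bit-identical datasets,
  training histories and predictions.

## Known limitations

- No pretrained backbone ships with the package (see above).
- No slide-level Gleason score aggregation (primary+secondary pattern);
  slide activation maps are provided for inspection only.
- The NumPy implementation is CPU-bound and sized for small studies;
  it is not a platform for full-scale histopathology training runs.
- The original spreadsheet dialect of public Gleason datasets is not
  parsed; datasets are expected as the documented CSV manifest plus
  image/mask directories (a converter is a few lines of pandas).
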