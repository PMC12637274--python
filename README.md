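# spatioseg

Distance-biased hierarchical vision-transformer semantic segmentation, with
overlap/boundary evaluation and Bland-Altman agreement analysis, exercised
end to end on a built-in synthetic multi-class image generator.

## What this is for

Segmenting anatomical regions in medical photographs (the motivating setting
is cervical screening imagery with background, cervical, columnar and lesion
classes) demands both global context and precise boundaries. Plain
vision-transformer attention is permutation-agnostic over tokens: it has no
built-in notion that two patches are spatial neighbours. `spatioseg`
implements a SegFormer-style encoder-decoder that injects that notion
explicitly, and ships everything needed to study it quantitatively — a
training harness, overlap (mIoU/DSC/F1) and boundary (HD95) metrics,
Bland-Altman method-agreement statistics, and a synthetic data generator so
no clinical data is required.

## The model in brief

For a stage grid of H×W patches (N = H·W tokens), attention scores are
offset by two spatial priors before the softmax:

* a **static centroid-distance bias**
  `B_dist[i,j] = −‖p_i − p_j‖₂ / (max(D) + ε)`,
  where `p_k` are patch-lattice centroids and D the pairwise distance
  matrix — near pairs get larger (less negative) offsets;
* a **learnable 2D relative positional bias**
  `B_rpe[h,i,j] = B_height[y_i−y_j+S, h] + B_width[x_i−x_j+S, h]`,
  per-head lookup tables indexed by vertical/horizontal token offset.

The fully biased score is `S″ = S + B_dist + B_rpe`, followed by softmax
over keys. Tokenization uses an **adaptive patch embedding** (strided conv →
learnable per-patch scalar weight → layer norm), and the feed-forward block
is a **MixFFN** whose expanded features pass through a depthwise 3×3
convolution on the 2D grid. Multi-scale stage features are fused by an
all-MLP decoder into per-pixel class logits. Training uses a composite
soft-Dice + categorical cross-entropy loss, Adam (1e−4) with gradient-norm
clipping, batch size 1, and reduce-on-plateau / early-stopping /
best-checkpoint callbacks.

Everything runs on CPU via a small built-in numpy autodiff engine — there is
no deep-learning-framework dependency. See `docs/methods.md` for the full
account of conventions, defaults and limitations.

## Worked example

`examples/03_train_segmenter.py` trains a 9,662-parameter two-stage model on
60 synthetic 64×64 images for 10 epochs (about a minute on one CPU core):

```text
model: 9662 trainable parameters
epoch   1  loss 2.0558  val_loss 1.5860  val_miou 0.2840  lr 1.00e-04
epoch   2  loss 1.4603  val_loss 1.2867  val_miou 0.4785  lr 1.00e-04
...
epoch  10  loss 0.6352  val_loss 0.6105  val_miou 0.7227  lr 1.00e-04

test mIoU 0.615  mDSC 0.683  HD95 5.33 px  (0.007s/image)
all-background baseline mIoU 0.204
```

Reading the numbers: validation mIoU rises from 0.28 (epoch 1) to ~0.72 as
the composite loss falls; on the held-out split the model reaches mean IoU
0.615 versus 0.204 for the trivial all-background predictor, and its
boundaries sit within ~5 px of the reference at the 95th percentile. The
longer desk-scale protocol (200 images, 20+ epochs — see below) reaches test
mIoU ≈ 0.88 and HD95 ≈ 1.3 px.

Other examples, one per capability: `01_spatial_biases.py` (the two
attention biases and the locality they induce), `02_generate_data.py`
(generator, augmentation, PNG round trip), `04_evaluate_metrics.py`
(hand-checkable metric values), `05_bland_altman.py` (agreement analysis).

A thin CLI wraps the same library functions:

```bash
spatioseg generate --n 100 --seed 7 --size 64 --out data/
spatioseg train --config configs/desk.yaml --data data/ --out run/
spatioseg predict --model run/ --data data/ --out preds/
spatioseg evaluate --pred preds/ --truth data/ --out report.csv
spatioseg agreement --csv areas.csv --col-a pred --col-b truth --out ba.csv
```

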