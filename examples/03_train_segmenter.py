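"""Train a small distance-biased transformer on synthetic data and evaluate it.

A shortened version of the desk-scale protocol (fewer images and epochs so
it finishes in about a minute): composite Dice + cross-entropy loss, Adam at
1e-4 with gradient clipping, batch size 1, plateau/early-stop callbacks.
"""

import numpy as np

from spatioseg.harness import TrainConfig, predict, train
from spatioseg.metrics import evaluate_dataset, overlap_metrics
from spatioseg.network import ModelConfig, build_model, count_parameters
from spatioseg.synthio import generate_dataset

data = generate_dataset(60, seed=11, image_size=64)
cfg = ModelConfig(
    input_size=(64, 64, 3), num_classes=4, strides=(4, 2), embed_dims=(8, 16),
    depths=(1, 1), num_heads=(1, 2), expansions=(4, 4), decoder_dim=32, seed=11,
)
model = build_model(cfg)
print(f"model: {count_parameters(model)} trainable parameters")

tconfig = TrainConfig(epochs=10, steps_per_epoch=48, validation_steps=6, seed=11)
state = train(model, data, tconfig, verbose=True)

preds, times = predict(model, np.stack([p.image for p in data["test"]]))
report = evaluate_dataset(preds, [p.mask for p in data["test"]], num_classes=4,
                          timings=times)
baseline = np.mean([
    overlap_metrics(np.zeros_like(p.mask), p.mask, 4)[0].mean() for p in data["test"]
])
print(f"\ntest mIoU {report.mean_iou:.3f}  mDSC {report.mean_dsc:.3f}  "
      f"HD95 {report.mean_hd95:.2f} px  ({report.mean_prediction_time:.3f}s/image)")
print(f"all-background baseline mIoU {baseline:.3f}")
print("-> the model recovers the anatomy far better than the trivial predictor;")
print("   HD95 is the 95th-percentile boundary error in pixels (lower is better)")
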