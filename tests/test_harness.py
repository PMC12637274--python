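"""Callback state machines, the training loop, and prediction contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatioseg.harness import (
    TrainConfig,
    TrainState,
    early_stop_step,
    plateau_step,
    predict,
    train,
)
from spatioseg.network import ModelConfig, build_model
from spatioseg.synthio import generate_dataset


def brute_force_callbacks(trace, lr0, factor=0.5, plateau_patience=15,
                          min_lr=1e-15, stop_patience=35):
    """Independent reference: replay the trace with explicit counters."""
    lr = lr0
    best_p = best_s = np.inf
    cp = cs = 0
    stopped_at = None
    lrs = []
    for epoch, v in enumerate(trace, start=1):
        if v < best_p:
            best_p, cp = v, 0
        else:
            cp += 1
            if cp >= plateau_patience:
                lr = max(lr * factor, min_lr)
                cp = 0
        if v < best_s:
            best_s, cs = v, 0
        else:
            cs += 1
            if cs >= stop_patience and stopped_at is None:
                stopped_at = epoch
        lrs.append(lr)
        if stopped_at is not None:
            break
    return lrs, stopped_at


def replay(trace, lr0=1e-4, **kw):
    state = TrainState(current_lr=lr0)
    lrs = []
    stopped_at = None
    for epoch, v in enumerate(trace, start=1):
        plateau_step(state, v, kw.get("factor", 0.5), kw.get("plateau_patience", 15),
                     kw.get("min_lr", 1e-15))
        early_stop_step(state, v, kw.get("stop_patience", 35))
        lrs.append(state.current_lr)
        if state.stopped:
            stopped_at = epoch
            break
    return lrs, stopped_at


class TestCallbacks:
    def test_improving_trace_never_reduces_lr_or_stops(self):
        trace = np.linspace(1.0, 0.01, 100)
        lrs, stopped = replay(trace)
        assert stopped is None
        assert all(lr == 1e-4 for lr in lrs)

    def test_constant_trace_halves_lr_at_epoch_16(self):
        trace = [1.0] * 20
        lrs, _ = replay(trace, lr0=1e-4)
        assert lrs[14] == 1e-4  # epoch 15: counter at 14, not yet triggered
        assert lrs[15] == pytest.approx(5e-5)  # epoch 16: 15 stagnant epochs

    def test_constant_trace_stops_at_epoch_36(self):
        trace = [1.0] * 50
        _, stopped = replay(trace)
        assert stopped == 36

    def test_lr_never_below_floor(self):
        trace = [1.0] * 2000
        lrs, _ = replay(trace, lr0=1e-4, stop_patience=10_000)
        assert min(lrs) >= 1e-15

    @given(st.lists(st.floats(0.0, 10.0, allow_nan=False), min_size=1, max_size=120),
           st.integers(1, 20), st.integers(1, 40))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_reference_on_random_traces(
        self, trace, plateau_patience, stop_patience
    ):
        got = replay(trace, plateau_patience=plateau_patience, stop_patience=stop_patience)
        expected = brute_force_callbacks(
            trace, 1e-4, plateau_patience=plateau_patience, stop_patience=stop_patience
        )
        assert got[0] == expected[0]
        assert got[1] == expected[1]


@pytest.fixture(scope="module")
def micro_run(tmp_path_factory):
    """A very small but real training run shared by the loop tests."""
    data = generate_dataset(20, seed=5, image_size=32)
    cfg = ModelConfig(
        input_size=(32, 32, 3), num_classes=4, strides=(4, 2), embed_dims=(8, 16),
        depths=(1, 1), num_heads=(1, 2), expansions=(4, 4), decoder_dim=16, seed=5,
    )
    model = build_model(cfg)
    tconfig = TrainConfig(epochs=4, steps_per_epoch=16, validation_steps=4, seed=5)
    ckpt = tmp_path_factory.mktemp("ckpt") / "best.npz"
    state = train(model, data, tconfig, checkpoint_path=ckpt)
    return model, data, tconfig, state, ckpt


class TestTrainLoop:
    def test_loss_decreases(self, micro_run):
        _, _, _, state, _ = micro_run
        hist = state.history
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]
        assert len(hist) == 4

    def test_best_checkpoint_reproduces_best_val_loss(self, micro_run):
        from spatioseg.harness import evaluate_loss_miou

        model, data, tconfig, state, ckpt = micro_run
        assert ckpt.exists()
        with np.load(ckpt) as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        val_loss, _ = evaluate_loss_miou(model, data["val"], tconfig, tconfig.validation_steps)
        assert val_loss == pytest.approx(state.best_val_loss, abs=1e-9)

    def test_restored_weights_match_best_epoch(self, micro_run):
        model, _, _, state, ckpt = micro_run
        with np.load(ckpt) as npz:
            for k, p in model.parameters().items():
                np.testing.assert_array_equal(p.data, npz[k])

    def test_history_records_all_series(self, micro_run):
        _, _, _, state, _ = micro_run
        for key in ("train_loss", "val_loss", "train_miou", "val_miou", "lr", "epoch"):
            assert all(key in h for h in state.history)

    def test_empty_dataset_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="non-empty"):
            train(tiny_model, {"train": [], "val": []}, TrainConfig(epochs=1))


class TestPredict:
    def test_constant_logit_model_yields_single_label_masks(self, tiny_model, rng):
        tiny_model.cls_w.data[:] = 0.0
        tiny_model.cls_b.data[:] = [0.0, 0.0, 2.0, 0.0]
        masks, times = predict(tiny_model, rng.uniform(0, 1, (2, 32, 32, 3)))
        assert all(np.all(m == 2) for m in masks)
        assert len(times) == 2 and all(t > 0 for t in times)

    def test_loop_equals_batched_forward(self, tiny_model, rng):
        imgs = rng.uniform(0, 1, (3, 32, 32, 3))
        masks, _ = predict(tiny_model, imgs)
        batched = tiny_model.predict(imgs)
        for m, b in zip(masks, batched):
            np.testing.assert_array_equal(m, b)

    def test_masks_are_integer_valid_labels(self, tiny_model, rng):
        masks, _ = predict(tiny_model, rng.uniform(0, 1, (1, 32, 32, 3)))
        assert masks[0].dtype.kind == "i"
        assert masks[0].max() < 4 and masks[0].min() >= 0
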