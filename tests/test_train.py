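"""Training loop: optimization sanity, seeding, checkpointing, prediction."""

import json
from dataclasses import replace

import numpy as np
import pytest

from patchvote.config import desk_config
from patchvote.model import PatchVoteNet, load_checkpoint
from patchvote.synthetic import SceneSpec, generate_dataset, generate_scene
from patchvote.train import TrainConfig, evaluate, export_prediction, predict, train
from patchvote.voting import LossSpec


def _fresh(seed=0, **kwargs):
    cfg = desk_config(seed=seed, **kwargs)
    return cfg, PatchVoteNet(cfg.backbone, cfg.attention, seed=seed)


def test_training_reduces_loss_and_logs(tiny_dataset, tmp_path):
    cfg, model = _fresh(seed=0)
    tc = replace(cfg.train, epochs=4)
    summary = train(model, tiny_dataset, tc, voting=cfg.voting,
                    loss_spec=cfg.loss, out_dir=tmp_path)
    losses = [r["train_loss"] for r in summary["log"]]
    assert losses[-1] < losses[0]
    log_lines = (tmp_path / "train_log.jsonl").read_text().strip().splitlines()
    assert len(log_lines) == 4
    row = json.loads(log_lines[0])
    assert {"epoch", "train_loss", "val_auc", "val_iou", "lr"} <= row.keys()


def test_same_seed_gives_identical_loss_curves(tiny_dataset):
    curves = []
    for _ in range(2):
        cfg, model = _fresh(seed=3)
        tc = replace(cfg.train, epochs=2)
        s = train(model, tiny_dataset, tc, voting=cfg.voting, loss_spec=cfg.loss)
        curves.append([r["train_loss"] for r in s["log"]])
    assert curves[0] == curves[1]


def test_checkpoint_roundtrip_preserves_metrics(tiny_dataset, tmp_path):
    cfg, model = _fresh(seed=1)
    tc = replace(cfg.train, epochs=2)
    train(model, tiny_dataset, tc, voting=cfg.voting, loss_spec=cfg.loss,
          out_dir=tmp_path)
    before = evaluate(model, tiny_dataset, split="val", voting=cfg.voting)
    reloaded, extra = load_checkpoint(tmp_path / "checkpoint.npz")
    after = evaluate(reloaded, tiny_dataset, split="val", voting=cfg.voting)
    assert extra["val_auc"] == pytest.approx(before.auc)
    assert after.to_dict() == pytest.approx(before.to_dict())


def test_mixed_supervision_trains(tiny_dataset):
    cfg, model = _fresh(seed=2)
    tc = replace(cfg.train, epochs=2)
    spec = LossSpec(supervision="mixed")
    s = train(model, tiny_dataset, tc, voting=cfg.voting, loss_spec=spec)
    assert np.isfinite([r["train_loss"] for r in s["log"]]).all()


def test_single_class_validation_still_retains_checkpoint(tmp_path):
    """AUC is undefined on a single-class validation split; training must
    still keep a best checkpoint (by IoU, then recency) instead of none."""
    base = tmp_path / "d"
    manifest = generate_dataset(SceneSpec(n=16, seed=9), base)
    # force the validation split to one class
    val_rows = manifest["split"] == "val"
    manifest.loc[val_rows, "label"] = 0
    manifest.loc[val_rows, "mask_path"] = ""
    manifest.to_csv(base / "manifest.csv", index=False)
    cfg, model = _fresh(seed=9)
    out = tmp_path / "run"
    summary = train(model, base, replace(cfg.train, epochs=2),
                    voting=cfg.voting, loss_spec=cfg.loss, out_dir=out)
    assert summary["best"]["epoch"] >= 0
    assert (out / "checkpoint.npz").exists()


def test_empty_split_raises(tmp_path):
    base = tmp_path / "d"
    manifest = generate_dataset(SceneSpec(n=8, seed=0), base)
    manifest["split"] = "train"          # destroy the validation split
    manifest.to_csv(base / "manifest.csv", index=False)
    cfg, model = _fresh(seed=0)
    with pytest.raises(ValueError, match="split"):
        train(model, base, replace(cfg.train, epochs=1))


def test_predict_exports_full_size_heatmap_and_mask(tmp_path):
    cfg, model = _fresh(seed=4)
    sample = generate_scene(SceneSpec(seed=4, lesion_prob=1.0), 0)
    result = predict(model, sample.pixels, voting=cfg.voting)
    assert len(result["probabilities"]) == 1
    # adaptive LSE keeps the full-grid normalizer, so a grid with few gated-in
    # patches is depressed by up to ln(h'w')/r below the patch range
    n_patches = (sample.pixels.shape[0] // 16) ** 2
    assert -np.log(n_patches) / 8 <= result["probabilities"][0] <= 1.0
    assert result["mask"].shape == sample.pixels.shape
    export_prediction(sample.pixels, result, tmp_path / "pred")
    from PIL import Image
    heat = Image.open(tmp_path / "pred.heatmap.png")
    assert heat.size == sample.pixels.shape[::-1]
    assert (tmp_path / "pred.mask.png").exists()


def test_untrained_model_probability_near_head_prior():
    """A fresh head starts near p=0.5 everywhere, so a blank image votes
    near 0.5 (the no-signal behavior)."""
    cfg, model = _fresh(seed=5)
    blank = np.zeros((64, 64))
    result = predict(model, blank, voting=cfg.voting)
    assert 0.05 < result["probabilities"][0] < 0.95


def test_non_divisible_image_dims_rejected():
    _, model = _fresh(seed=6)
    with pytest.raises(ValueError, match="divisible"):
        model.predict_grid(np.zeros((100, 100)))
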