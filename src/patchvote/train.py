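"""Training loop, evaluation and prediction export.

The protocol: stochastic gradient descent with momentum 0.9, initial
learning rate 0.001 multiplied by 0.3 when the training loss plateaus,
batch size 8, focal weak loss on voted image probabilities (or the mixed
loss when pixel masks participate).  One JSON line per epoch records the
training loss, validation AUC/IoU and learning rate; the checkpoint with
the best validation AUC is retained.  Everything (initialization, data
order) is driven by a single seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from ._tensor import Tensor, no_grad
from .backbone import ImageSample
from .metrics import ConfusionCounts, MetricsReport, auc, confusion_metrics, grid_to_mask, iou
from .model import PatchVoteNet, save_checkpoint
from .synthetic import load_manifest, load_sample
from .voting import LossSpec, VotingSpec, focal_weak_loss, mixed_loss

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "train", "evaluate", "predict", "export_prediction"]


@dataclass
class TrainConfig:
    lr: float = 0.001
    momentum: float = 0.9
    lr_factor: float = 0.3
    lr_patience: int = 10
    min_lr: float = 1e-6
    epochs: int = 30
    batch: int = 8
    seed: int = 0
    decision_threshold: float = 0.5  # operating point for sens/spec/F1
    mask_threshold: float = 0.5     # patch-grid binarization for IoU

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")


def _batches(n: int, batch: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch):
        yield order[start:start + batch]


def _forward_batch(model: PatchVoteNet, samples: list[ImageSample]) -> Tensor:
    imgs = []
    for s in samples:
        px = s.pixels[..., None] if s.pixels.ndim == 2 else s.pixels
        imgs.append(px.transpose(2, 0, 1))
    return model(Tensor(np.stack(imgs)))


def train(model: PatchVoteNet, dataset_dir: str | Path, cfg: TrainConfig,
          voting: VotingSpec | None = None, loss_spec: LossSpec | None = None,
          out_dir: str | Path | None = None,
          use_masks_for: set[str] | None = None) -> dict:
    """Train ``model`` on a manifest dataset; returns a summary dict.

    ``use_masks_for`` (sample ids) selects which training samples expose
    their pixel masks under mixed supervision; all other samples train
    weakly even if a mask exists on disk.
    """
    voting = voting or VotingSpec()
    loss_spec = loss_spec or LossSpec()
    manifest = load_manifest(dataset_dir)
    rng = np.random.default_rng(cfg.seed)

    splits = {name: manifest[manifest["split"] == name].reset_index(drop=True)
              for name in ("train", "val", "test")}
    for name in ("train", "val"):
        if not len(splits[name]):
            raise ValueError(f"split {name!r} is empty")
    train_samples = [load_sample(dataset_dir, row)
                     for _, row in splits["train"].iterrows()]
    val_samples = [load_sample(dataset_dir, row)
                   for _, row in splits["val"].iterrows()]

    params = model.parameters()
    opt = nn.SGD(params, lr=cfg.lr, momentum=cfg.momentum)
    sched = nn.ReduceLROnPlateau(opt, factor=cfg.lr_factor,
                                 patience=cfg.lr_patience, min_lr=cfg.min_lr)
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    log_rows = []
    best = {"auc": None, "iou": None, "epoch": -1}
    best_key = (-np.inf, -np.inf, -1)
    ckpt_path = out / "checkpoint.npz" if out else None

    for epoch in range(cfg.epochs):
        model.train()
        losses = []
        for idx in _batches(len(train_samples), cfg.batch, rng):
            batch = [train_samples[i] for i in idx]
            patch_probs = _forward_batch(model, batch)
            probs = model.image_probs(patch_probs, voting)
            labels = np.stack([s.labels for s in batch]).astype(np.float64)
            if loss_spec.supervision == "mixed":
                masks = [s.mask if (s.mask is not None and s.mask.any()
                                    and (use_masks_for is None or s.id in use_masks_for))
                         else None for s in batch]
                loss = mixed_loss(patch_probs, probs, labels, masks, loss_spec)
            else:
                loss = focal_weak_loss(probs, labels, loss_spec)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        train_loss = float(np.mean(losses))
        sched.step(train_loss)

        val = evaluate(model, dataset_dir, split="val", voting=voting, cfg=cfg,
                       samples=val_samples)
        row = {"epoch": epoch, "train_loss": train_loss,
               "val_auc": val.auc, "val_iou": val.iou, "lr": opt.lr}
        log_rows.append(row)
        if out:
            with open(out / "train_log.jsonl", "a") as fh:
                fh.write(json.dumps(row) + "\n")
        logger.info("epoch %d loss %.4f val_auc %s val_iou %s",
                    epoch, train_loss, val.auc, val.iou)
        # best validation AUC wins; AUC ties (it saturates early on easy
        # data) break in favour of better validation IoU, then recency.
        # Undefined metrics rank lowest, but some checkpoint is always kept.
        key = (val.auc if val.auc is not None else -np.inf,
               val.iou if val.iou is not None else -np.inf, epoch)
        if key >= best_key:
            best_key = key
            best = {"auc": val.auc, "iou": val.iou, "epoch": epoch}
            if ckpt_path:
                save_checkpoint(ckpt_path, model,
                                extra={"epoch": epoch, "val_auc": val.auc,
                                       "voting": voting.mode})
            best_state = {k: v.copy() for k, v in model.state_dict().items()}

    if best["epoch"] >= 0:
        model.load_state_dict(best_state)  # best-validation weights win
    return {"log": log_rows, "best": best, "checkpoint": str(ckpt_path) if ckpt_path else None}


def evaluate(model: PatchVoteNet, dataset_dir: str | Path, split: str = "test",
             voting: VotingSpec | None = None, cfg: TrainConfig | None = None,
             samples: list[ImageSample] | None = None) -> MetricsReport:
    """Classification AUC/F1/sensitivity/specificity and abnormal-image IoU.

    IoU is averaged over abnormal images only: against an empty ground
    truth the empty-empty convention would dominate the mean and hide
    localization quality.
    """
    voting = voting or VotingSpec()
    cfg = cfg or TrainConfig()
    if samples is None:
        manifest = load_manifest(dataset_dir)
        rows = manifest[manifest["split"] == split]
        if not len(rows):
            raise ValueError(f"split {split!r} is empty")
        samples = [load_sample(dataset_dir, row) for _, row in rows.iterrows()]
    scores, labels, ious = [], [], []
    for s in samples:
        grid = model.predict_grid(s.pixels)      # (h', w', K)
        prob = float(_vote_numpy(grid[..., 0], voting))
        scores.append(prob)
        labels.append(int(s.labels[0]))
        if s.labels[0] and s.mask is not None:
            pred = grid_to_mask(grid[..., 0], cfg.mask_threshold)
            ious.append(iou(pred, s.mask))
    labels_arr = np.asarray(labels)
    try:
        auc_val = auc(scores, labels_arr)
    except ValueError:
        auc_val = None
    counts = ConfusionCounts.from_predictions(
        np.asarray(scores) >= cfg.decision_threshold, labels_arr)
    cm = confusion_metrics(counts)
    return MetricsReport(auc=auc_val, f1=cm["f1"], sensitivity=cm["sensitivity"],
                         specificity=cm["specificity"],
                         iou=float(np.mean(ious)) if ious else None,
                         n_eval=len(samples))


def _vote_numpy(grid: np.ndarray, spec: VotingSpec) -> float:
    from .voting import vote
    return vote(grid, spec)


def predict(model: PatchVoteNet, pixels: np.ndarray,
            voting: VotingSpec | None = None,
            mask_threshold: float = 0.5) -> dict:
    """Image -> per-class probabilities, patch heatmap and binary mask."""
    voting = voting or VotingSpec()
    grid = model.predict_grid(pixels)
    probs = [float(_vote_numpy(grid[..., k], voting))
             for k in range(grid.shape[-1])]
    mask = grid_to_mask(grid[..., 0], mask_threshold)
    return {"probabilities": probs, "patch_grid": grid, "mask": mask}


def export_prediction(pixels: np.ndarray, result: dict, out_prefix: str | Path) -> None:
    """Write heatmap-overlay and mask PNGs next to ``out_prefix``."""
    import matplotlib
    matplotlib.use("Agg")
    from PIL import Image

    cmap = matplotlib.colormaps["jet"]

    out_prefix = Path(out_prefix)
    h, w = pixels.shape[:2]
    grid = result["patch_grid"][..., 0]
    heat = np.repeat(np.repeat(grid, h // grid.shape[0], axis=0),
                     w // grid.shape[1], axis=1)
    base = pixels if pixels.ndim == 3 else np.repeat(pixels[..., None], 3, axis=2)
    overlay = 0.6 * base + 0.4 * cmap(heat)[..., :3]
    Image.fromarray((np.clip(overlay, 0, 1) * 255).astype(np.uint8)).save(
        out_prefix.with_suffix(".heatmap.png"))
    Image.fromarray((result["mask"] * 255).astype(np.uint8)).save(
        out_prefix.with_suffix(".mask.png"))
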