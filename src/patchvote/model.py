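"""Full weakly supervised model: backbone -> position attention -> patch head.

``PatchVoteNet`` maps an image batch to an h'/w' patch-probability grid and
a voted image-level probability per class.  The attention stage is optional
(``use_attention=False`` reproduces the attention-free ablation), and the
voting aggregator is chosen at call time through a :class:`VotingSpec`, so
the ablation axes (restricted vs unrestricted backbone, voting function)
are plain configuration switches over the same code path.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import nn
from ._tensor import Tensor, no_grad
from .attention import AttentionConfig, PositionAttention
from .backbone import BackboneConfig, FeatureExtractor, build_backbone
from .voting import PatchHead, VotingSpec, vote

__all__ = ["PatchVoteNet", "save_checkpoint", "load_checkpoint"]


class PatchVoteNet(nn.Module):
    def __init__(self, backbone_cfg: BackboneConfig,
                 attention_cfg: AttentionConfig | None,
                 n_classes: int = 1, head_hidden: int = 256,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.backbone_cfg = backbone_cfg
        self.attention_cfg = attention_cfg
        self.n_classes = n_classes
        self.head_hidden = head_hidden
        self.backbone: FeatureExtractor = build_backbone(backbone_cfg, rng)
        if attention_cfg is not None:
            self.attention = PositionAttention(backbone_cfg.out_channels,
                                               attention_cfg, rng)
            head_in = attention_cfg.d
        else:
            self.attention = None
            head_in = backbone_cfg.out_channels
        self.head = PatchHead(head_in, n_classes, head_hidden, rng)

    def forward(self, x: Tensor) -> Tensor:
        """(N, C, H, W) images -> (N, K, H/16, W/16) patch probabilities."""
        feats = self.backbone(x)
        if self.attention is not None:
            feats = self.attention(feats)
        return self.head(feats)

    def image_probs(self, patch_probs: Tensor, spec: VotingSpec) -> Tensor:
        """Aggregate each sample's patch grid to (N, K) image probabilities."""
        n, k = patch_probs.shape[0], patch_probs.shape[1]
        votes = [vote(patch_probs[i][j], spec)
                 for i in range(n) for j in range(k)]
        stacked = _stack_scalars(votes)
        return stacked.reshape(n, k)

    def predict_grid(self, pixels: np.ndarray) -> np.ndarray:
        """Single image (h, w[, c]) in [0,1] -> (h', w', K) probabilities."""
        px = pixels[..., None] if pixels.ndim == 2 else pixels
        if px.shape[0] % 16 or px.shape[1] % 16:
            raise ValueError("image dimensions must be divisible by 16")
        was = self.training
        self.eval()
        try:
            with no_grad():
                out = self(Tensor(px.transpose(2, 0, 1)[None]))
        finally:
            self.train(was)
        return out.data[0].transpose(1, 2, 0)


def _stack_scalars(scalars: list[Tensor]) -> Tensor:
    from ._tensor import concatenate
    return concatenate([s.reshape(1) for s in scalars])


def save_checkpoint(path: str | Path, model: PatchVoteNet,
                    extra: dict | None = None) -> None:
    """Serialize parameters, buffers and the architecture to one .npz file."""
    meta = {
        "backbone": asdict(model.backbone_cfg),
        "attention": asdict(model.attention_cfg) if model.attention_cfg else None,
        "n_classes": model.n_classes,
        "head_hidden": model.head_hidden,
        "extra": extra or {},
    }
    arrays = {"param:" + k: v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[PatchVoteNet, dict]:
    """Rebuild a model from a checkpoint; returns (model, extra-metadata)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param:"):]: data[k] for k in data.files
                 if k.startswith("param:")}
    bcfg = BackboneConfig(**{**meta["backbone"],
                             "stage_block_counts": tuple(meta["backbone"]["stage_block_counts"]),
                             "stage_channels": tuple(meta["backbone"]["stage_channels"])})
    acfg = AttentionConfig(**meta["attention"]) if meta["attention"] else None
    model = PatchVoteNet(bcfg, acfg, meta["n_classes"], meta["head_hidden"])
    model.load_state_dict(state)
    return model, meta["extra"]
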