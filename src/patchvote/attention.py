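"""Positional-embedding self-attention over the patch-feature grid.

The h' x w' x c' feature grid is flattened row-major into h'*w' tokens,
projected to a d-dimensional embedding, and a learned positional table is
added so attention can condition on *where* a patch sits — the mechanism
that lets the model favour disease-prone areas.  The token sequence then
passes through L pre-norm residual attention layers:

    z_l' = MSA(LN(z_{l-1})) + z_{l-1}
    z_l  = MLP(LN(z_l'))    + z_l'

with M-head scaled dot-product attention (per head softmax(QK^T/sqrt(h))V,
heads concatenated and linearly projected back to d) and a one-hidden-layer
perceptron with a GELU nonlinearity.  The output sequence is reshaped back
to an h' x w' x d grid.

The positional table has exactly ``grid_tokens`` rows; no interpolation is
performed, so a grid of any other size is a configuration error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from ._tensor import Tensor, softmax

__all__ = ["AttentionConfig", "PositionAttention", "embed_patches",
           "attention_layer", "apply_position_attention"]


@dataclass
class AttentionConfig:
    d: int = 1024
    layers: int = 2
    heads: int = 12
    head_dim: int = 64
    mlp_hidden: int = 1024
    grid_tokens: int = 1024  # h' * w', fixed at configuration time

    def __post_init__(self):
        for name in ("d", "layers", "heads", "head_dim", "mlp_hidden", "grid_tokens"):
            if getattr(self, name) < (0 if name == "layers" else 1):
                raise ValueError(f"{name} must be at least 1")


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        inner = cfg.heads * cfg.head_dim
        self.cfg = cfg
        self.qkv = nn.Linear(cfg.d, 3 * inner, rng=rng)
        self.out = nn.Linear(inner, cfg.d, rng=rng)

    def forward(self, z: Tensor) -> Tensor:
        N, T, _ = z.shape
        M, hd = self.cfg.heads, self.cfg.head_dim
        qkv = self.qkv(z).reshape(N, T, 3, M, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]           # each (N, M, T, hd)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        attn = softmax(scores, axis=-1)            # rows sum to 1 per head
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(N, T, M * hd)
        return self.out(ctx)

    def attention_weights(self, z: Tensor) -> np.ndarray:
        """(N, M, T, T) softmax attention maps, for inspection."""
        N, T, _ = z.shape
        M, hd = self.cfg.heads, self.cfg.head_dim
        qkv = self.qkv(z).reshape(N, T, 3, M, hd).transpose(2, 0, 3, 1, 4)
        q, k = qkv[0], qkv[1]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        return softmax(scores, axis=-1).data


class AttentionLayer(nn.Module):
    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        self.ln1 = nn.LayerNorm(cfg.d)
        self.msa = MultiHeadSelfAttention(cfg, rng)
        self.ln2 = nn.LayerNorm(cfg.d)
        self.fc1 = nn.Linear(cfg.d, cfg.mlp_hidden, rng=rng)
        self.fc2 = nn.Linear(cfg.mlp_hidden, cfg.d, rng=rng)

    def forward(self, z: Tensor) -> Tensor:
        z = self.msa(self.ln1(z)) + z
        return self.fc2(self.fc1(self.ln2(z)).gelu()) + z


class PositionAttention(nn.Module):
    """Patch embedding + positional table + L residual attention layers."""

    def __init__(self, c_in: int, cfg: AttentionConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.projection = nn.Linear(c_in, cfg.d, bias=False, rng=rng)
        self.pos_table = Tensor(rng.normal(0.0, 0.02, (cfg.grid_tokens, cfg.d)),
                                requires_grad=True)
        self.blocks = nn.Sequential(
            *[AttentionLayer(cfg, rng) for _ in range(cfg.layers)])

    def embed(self, x: Tensor) -> Tensor:
        """(N, T, c') tokens -> (N, T, d) embedded tokens with position."""
        if x.shape[1] != self.cfg.grid_tokens:
            raise ValueError(
                f"grid has {x.shape[1]} tokens but the positional table was "
                f"built for {self.cfg.grid_tokens}; positional tables are not "
                f"interpolated")
        return x @ self.projection.weight + self.pos_table

    def forward(self, x: Tensor) -> Tensor:
        """(N, c', h', w') feature batch -> (N, d, h', w') attended batch."""
        N, C, H, W = x.shape
        tokens = x.reshape(N, C, H * W).transpose(0, 2, 1)   # row-major
        z = self.blocks(self.embed(tokens))
        return z.transpose(0, 2, 1).reshape(N, self.cfg.d, H, W)


# -- functional grid-level interface --------------------------------------

def embed_patches(grid, module: PositionAttention) -> np.ndarray:
    """Flatten an (h', w', c') grid row-major and embed it; returns z_0."""
    arr = np.asarray(grid.values if hasattr(grid, "values") else grid)
    h, w, c = arr.shape
    tokens = Tensor(arr.reshape(1, h * w, c))
    return module.embed(tokens).data[0]


def attention_layer(tokens: np.ndarray, layer: AttentionLayer) -> np.ndarray:
    """Apply one residual attention layer to a (T, d) token matrix."""
    return layer(Tensor(np.asarray(tokens)[None])).data[0]


def apply_position_attention(grid, module: PositionAttention):
    """(h', w', c') grid -> (h', w', d) grid through the whole block."""
    from .backbone import FeatureGrid
    arr = np.asarray(grid.values if hasattr(grid, "values") else grid)
    h, w, c = arr.shape
    x = Tensor(arr.transpose(2, 0, 1)[None])
    out = module(x).data[0].transpose(1, 2, 0)
    if hasattr(grid, "values"):
        return FeatureGrid(values=out, stride=grid.stride, rf=grid.rf)
    return out
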