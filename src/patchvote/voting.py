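"""Patch-probability head, patch-vote aggregators and weak-supervision losses.

The segmentation head maps each attended patch feature to a per-class
probability with two pointwise (1x1) convolutions and a sigmoid, giving an
h' x w' x K probability grid.  Because only image-level labels are available
at training time, the grid must be aggregated to a single image probability
per class; this is multiple-instance learning where every patch is an
instance and the aggregator decides how much each instance's evidence
counts:

* average voting weighs all patches equally (lesion evidence is diluted),
* max voting listens to a single patch (training signal is sparse),
* Log-Sum-Exp (LSE) voting interpolates between them,

      p^k = (1/r) log( (1/(h'w')) sum_{i,j} exp(r p^k_{i,j}) ),

  smooth and convex, with the smoothness r weighting strong-evidence
  patches more as r grows (mean as r -> 0, max as r -> infinity),
* adaptive LSE voting additionally gates out patches below the adaptive
  threshold t * max(p^k): only patches comparable to the strongest one
  vote.  The normalizer stays h'*w' and the gate is held constant during
  gradient computation.

The image-level loss is an alpha-balanced focal loss summed over classes,

    L = sum_k [ -a y^k (1-p^k)^g log p^k - (1-a)(1-y^k) (p^k)^g log(1-p^k) ],

which concentrates training on hard images.  For mixed supervision, samples
carrying pixel masks instead contribute a patch-level binary cross-entropy
plus soft-Dice term against the mask downsampled to the patch grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from ._tensor import Tensor

__all__ = [
    "VotingSpec", "LossSpec", "PatchHead", "PatchProbGrid",
    "vote_lse", "vote_adaptive_lse", "vote_average", "vote_max", "vote",
    "focal_weak_loss", "mixed_loss", "downsample_mask",
]

logger = logging.getLogger(__name__)

_CLAMP = 1e-7  # keep probabilities away from {0,1} before logarithms


@dataclass
class PatchProbGrid:
    """Per-patch, per-class probabilities: (h', w', K) values in [0, 1]."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("patch probabilities must lie in [0, 1]")


@dataclass
class VotingSpec:
    mode: str = "adaptive_lse"
    r: float = 8.0
    t: float = 0.6

    def __post_init__(self):
        if self.mode not in ("average", "max", "lse", "adaptive_lse"):
            raise ValueError(f"unknown voting mode {self.mode!r}")
        if self.r <= 0:
            raise ValueError("smoothness r must be positive")
        if not 0 < self.t <= 1:
            raise ValueError("threshold t must lie in (0, 1]")


@dataclass
class LossSpec:
    alpha: float = 0.6
    gamma: float = 2.0
    supervision: str = "weak"
    dice_smooth: float = 1.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.supervision not in ("weak", "mixed"):
            raise ValueError("supervision must be 'weak' or 'mixed'")


class PatchHead(nn.Module):
    """Two pointwise convolutions and a sigmoid: features -> patch probs."""

    def __init__(self, c_in: int, n_classes: int = 1, hidden: int = 256,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.conv1 = nn.Conv2d(c_in, hidden, 1, rng=rng)
        self.conv2 = nn.Conv2d(hidden, n_classes, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """(N, c, h', w') -> (N, K, h', w') probabilities in (0, 1)."""
        return self.conv2(self.conv1(x).relu()).sigmoid()


def _as_grid_tensor(grid) -> tuple[Tensor, bool]:
    """Accept an ndarray-like or Tensor patch grid; note which it was."""
    if isinstance(grid, Tensor):
        return grid, True
    if isinstance(grid, PatchProbGrid):
        grid = grid.probs
    arr = np.asarray(grid, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("patch grid must be non-empty")
    return Tensor(arr), False


def _ret(value: Tensor, was_tensor: bool):
    return value if was_tensor else float(value.data)


def vote_lse(grid, r: float):
    """Log-Sum-Exp vote over a patch-probability grid.

    Evaluated stably by factoring the grid maximum out of the exponentials
    (algebraically identical to the direct form).  The result always lies
    between the grid mean and the grid maximum.
    """
    if r <= 0:
        raise ValueError("smoothness r must be positive")
    g, was = _as_grid_tensor(grid)
    m = float(g.data.max())                     # constant shift
    p = m + (((g - m) * r).exp().mean()).log() * (1.0 / r)
    return _ret(p, was)


def vote_adaptive_lse(grid, r: float, t: float):
    """Adaptive LSE vote: only patches with p >= t * max(p) participate.

    The excluded patches are gated out of the sum but the normalizer stays
    the full patch count h'*w'; the gate is a constant during gradient
    computation, so excluded patches receive zero gradient.
    """
    if r <= 0:
        raise ValueError("smoothness r must be positive")
    if not 0 < t <= 1:
        raise ValueError("threshold t must lie in (0, 1]")
    g, was = _as_grid_tensor(grid)
    m = float(g.data.max())
    gate = (g.data >= t * m).astype(g.data.dtype)   # constant, no gradient
    summed = (((g - m) * r).exp() * gate).mean()
    p = m + summed.log() * (1.0 / r)
    return _ret(p, was)


def vote_average(grid):
    """Arithmetic-mean vote."""
    g, was = _as_grid_tensor(grid)
    return _ret(g.mean(), was)


def vote_max(grid):
    """Maximum vote (gradient flows to the arg-max patch only)."""
    g, was = _as_grid_tensor(grid)
    flat = g.reshape(g.data.size)
    idx = int(np.argmax(flat.data))
    return _ret(flat[idx], was)


def vote(grid, spec: VotingSpec):
    """Dispatch on the configured aggregator."""
    if spec.mode == "average":
        return vote_average(grid)
    if spec.mode == "max":
        return vote_max(grid)
    if spec.mode == "lse":
        return vote_lse(grid, spec.r)
    return vote_adaptive_lse(grid, spec.r, spec.t)


def naive_lse_reference(grid: np.ndarray, r: float) -> float:
    """Direct textbook evaluation of the LSE vote (oracle; may overflow)."""
    arr = np.asarray(grid, dtype=np.float64)
    return float(np.log(np.mean(np.exp(r * arr))) / r)


def focal_weak_loss(p, y, spec: LossSpec):
    """Alpha-balanced focal loss on image-level probabilities.

    ``p``: (K,) or (N, K) probabilities (Tensor or array); ``y``: matching
    binary labels.  Summed over classes, averaged over the batch axis when
    present.  Probabilities are clamped to [1e-7, 1 - 1e-7] before logs.
    """
    pt, was = (p, True) if isinstance(p, Tensor) else (Tensor(np.asarray(p, dtype=np.float64)), False)
    yarr = np.asarray(y, dtype=np.float64)
    if yarr.shape != pt.data.shape:
        raise ValueError("probability and label shapes differ")
    pc = pt.clip(_CLAMP, 1.0 - _CLAMP)
    a, g = spec.alpha, spec.gamma
    pos = (1.0 - pc) ** g * pc.log() * (-a)
    neg = pc ** g * (1.0 - pc).log() * (a - 1.0)
    per = pos * yarr + neg * (1.0 - yarr)
    if pt.data.ndim == 2:
        loss = per.sum(axis=1).mean()
    else:
        loss = per.sum()
    return loss if was else float(loss.data)


def downsample_mask(mask: np.ndarray, patch: int = 16,
                    min_cover: float = 0.5) -> np.ndarray:
    """Pixel mask -> patch-grid mask; a patch is positive at >= 50% cover."""
    m = np.asarray(mask, dtype=np.float64)
    h, w = m.shape
    if h % patch or w % patch:
        raise ValueError("mask dimensions must be divisible by the patch size")
    cover = m.reshape(h // patch, patch, w // patch, patch).mean(axis=(1, 3))
    return cover >= min_cover


def soft_dice(probs: Tensor, target: np.ndarray, smooth: float = 1.0):
    """1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps) over a patch grid."""
    t = np.asarray(target, dtype=np.float64)
    inter = (probs * t).sum()
    denom = probs.sum() + float(t.sum()) + smooth
    return 1.0 - (inter * 2.0 + smooth) / denom


def patch_bce(probs: Tensor, target: np.ndarray):
    pc = probs.clip(_CLAMP, 1.0 - _CLAMP)
    t = np.asarray(target, dtype=np.float64)
    per = pc.log() * (-t) + (1.0 - pc).log() * (t - 1.0)
    return per.mean()


def mixed_loss(patch_grids: Tensor, image_probs: Tensor, labels: np.ndarray,
               masks: list[np.ndarray | None], spec: LossSpec,
               patch: int = 16):
    """Mixed-supervision batch loss.

    ``patch_grids``: (N, K, h', w') patch probabilities; ``image_probs``:
    (N, K) voted probabilities; ``masks``: per-sample pixel masks or None.
    Samples with masks contribute patch-level BCE + soft Dice against the
    downsampled mask; samples without masks contribute the focal weak loss.
    The two populations are averaged separately, then summed.  A mixed-mode
    batch with no masked sample falls back to the weak term with a warning.
    """
    if spec.supervision != "mixed":
        raise ValueError("mixed_loss requires supervision='mixed'")
    n = patch_grids.shape[0]
    masked = [i for i in range(n) if masks[i] is not None]
    unmasked = [i for i in range(n) if masks[i] is None]
    terms = []
    if masked:
        pixel_terms = []
        for i in masked:
            for k in range(patch_grids.shape[1]):
                target = downsample_mask(_class_mask(masks[i], k), patch)
                probs_k = patch_grids[i][k]
                pixel_terms.append(patch_bce(probs_k, target)
                                   + soft_dice(probs_k, target, spec.dice_smooth))
        total = pixel_terms[0]
        for t in pixel_terms[1:]:
            total = total + t
        terms.append(total * (1.0 / len(pixel_terms)))
    elif unmasked:
        logger.warning("mixed supervision batch contains no masked sample; "
                       "using the weak loss only")
    if unmasked:
        terms.append(focal_weak_loss(image_probs[np.array(unmasked)],
                                     labels[np.array(unmasked)], spec))
    loss = terms[0]
    for t in terms[1:]:
        loss = loss + t
    return loss


def _class_mask(mask: np.ndarray, k: int) -> np.ndarray:
    return mask[..., k] if mask.ndim == 3 else mask
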