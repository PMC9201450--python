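"""Restricted-receptive-field grouped-convolution backbone.

The feature extractor is a ResNeXt-style residual network (split-transform-
merge bottlenecks with grouped convolutions) in which almost every 3x3
convolution is replaced by a 1x1 one.  Exactly four grouped convolutions
keep a 3x3 kernel: one stride-1 conv in the first block of stage 1, and the
stride-2 downsampling convs entering stages 2-4.  With a 7x7 stride-2 stem
and no pooling layer this yields a total stride of 16 and a receptive field
of exactly 39x39 input pixels at the topmost convolutional layer, so each
output cell summarizes one 16x16 image patch plus a limited neighbourhood.
Restricting the receptive field ties the feature space to the pixel space:
evidence for a lesion can only appear near the lesion, which is what makes
the patch grid usable as a weakly supervised segmentation output and
prevents bilaterally symmetric context (the mirrored healthy side) from
leaking into a local decision.

Setting ``restricted=False`` restores 3x3 kernels in *all* grouped
convolutions (the unrestricted ablation); stage strides are unchanged so the
output grid stays ``h/16 x w/16`` and results remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from ._tensor import Tensor, no_grad, shift2d

__all__ = [
    "BackboneConfig", "ImageSample", "FeatureGrid", "FeatureExtractor",
    "build_backbone", "extract_features", "receptive_field",
    "empirical_receptive_field",
]

PATCH = 16  # input pixels per output grid cell (total stride)


@dataclass
class ImageSample:
    """One image with its image-level labels and optional pixel mask.

    ``pixels`` is (h, w) or (h, w, c) scaled to [0, 1]; ``labels`` is a
    length-K binary vector; ``mask`` (optional) is (h, w) or (h, w, K)
    binary, and when present each label must equal mask non-emptiness.
    """

    pixels: np.ndarray
    labels: np.ndarray
    mask: np.ndarray | None = None
    id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.labels = np.atleast_1d(np.asarray(self.labels)).astype(np.int64)
        h, w = self.pixels.shape[:2]
        for axis, size in (("height", h), ("width", w)):
            if size % PATCH:
                raise ValueError(f"image {axis} {size} is not divisible by {PATCH}")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            masks = self.mask if self.mask.ndim == 3 else self.mask[..., None]
            has = masks.any(axis=(0, 1)).astype(np.int64)
            if not np.array_equal(has, self.labels):
                raise ValueError("labels inconsistent with mask emptiness")


@dataclass
class FeatureGrid:
    """Local-feature tensor: one c'-vector per 16x16 input patch."""

    values: np.ndarray  # (h', w', c')
    stride: int = PATCH
    rf: int = 39


@dataclass
class BackboneConfig:
    stage_block_counts: tuple[int, ...] = (3, 4, 6, 3)
    cardinality: int = 32
    stage_channels: tuple[int, ...] = (256, 512, 1024, 2048)
    width_scale: float = 1.0
    restricted: bool = True
    in_channels: int = 1
    stem_channels: int = 64
    # With symmetric convolution padding, output cell (i, j) has its
    # receptive field centred on input pixel (16i, 16j) — the *corner* of
    # the 16x16 patch the cell is read out as.  patch_centered shifts the
    # input by half a patch so the receptive field is centred on the patch
    # centre (16i+8, 16j+8), aligning patch evidence with the patch.
    patch_centered: bool = True

    def __post_init__(self):
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")
        if len(self.stage_block_counts) != len(self.stage_channels):
            raise ValueError("stage_block_counts and stage_channels lengths differ")
        for c in self.stage_channels:
            width = self._scaled(c) // 2
            if width < self.cardinality or width % self.cardinality:
                raise ValueError(
                    f"cardinality {self.cardinality} must divide the grouped-conv "
                    f"width {width} (stage with {c} channels, "
                    f"width_scale {self.width_scale})")

    def _scaled(self, c: int) -> int:
        return max(int(round(c * self.width_scale)), 1)

    def scaled_channels(self) -> list[int]:
        return [self._scaled(c) for c in self.stage_channels]

    @property
    def out_channels(self) -> int:
        return self.scaled_channels()[-1]

    def layer_sequence(self) -> list[tuple[int, int]]:
        """(kernel, stride) of every convolution along the main path."""
        layers = [(7, 2)]  # stem
        for si, nblocks in enumerate(self.stage_block_counts):
            for bi in range(nblocks):
                stride = 2 if (si > 0 and bi == 0) else 1
                grouped_k = self._grouped_kernel(si, bi)
                layers += [(1, 1), (grouped_k, stride), (1, 1)]
        return layers

    def _grouped_kernel(self, stage: int, block: int) -> int:
        if not self.restricted:
            return 3
        # surviving 3x3s: stage-1 first block (stride 1) and the stride-2
        # downsampler entering each later stage
        return 3 if block == 0 else 1


class Bottleneck(nn.Module):
    """1x1 reduce -> grouped conv -> 1x1 expand, with residual shortcut."""

    def __init__(self, c_in: int, c_out: int, groups: int, grouped_kernel: int,
                 stride: int, rng: np.random.Generator):
        super().__init__()
        mid = c_out // 2
        self.reduce = nn.Conv2d(c_in, mid, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid)
        self.grouped = nn.Conv2d(mid, mid, grouped_kernel, stride=stride,
                                 groups=groups, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid)
        self.expand = nn.Conv2d(mid, c_out, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(c_out)
        if c_in != c_out or stride != 1:
            self.proj = nn.Conv2d(c_in, c_out, 1, stride=stride, bias=False, rng=rng)
            self.bn_proj = nn.BatchNorm2d(c_out)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.reduce(x)).relu()
        y = self.bn2(self.grouped(y)).relu()
        y = self.bn3(self.expand(y))
        shortcut = x if self.proj is None else self.bn_proj(self.proj(x))
        return (y + shortcut).relu()


class FeatureExtractor(nn.Module):
    def __init__(self, config: BackboneConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        stem_c = config._scaled(config.stem_channels)
        self.stem = nn.Conv2d(config.in_channels, stem_c, 7, stride=2,
                              bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem_c)
        c_prev = stem_c
        stages = []
        for si, (nblocks, c_out) in enumerate(
                zip(config.stage_block_counts, config.scaled_channels())):
            blocks = []
            for bi in range(nblocks):
                stride = 2 if (si > 0 and bi == 0) else 1
                blocks.append(Bottleneck(c_prev, c_out, config.cardinality,
                                         config._grouped_kernel(si, bi),
                                         stride, rng))
                c_prev = c_out
            stages.append(nn.Sequential(*blocks))
        self.stages = nn.Sequential(*stages)

    def forward(self, x: Tensor) -> Tensor:
        """(N, C, H, W) image batch -> (N, c', H/16, W/16) feature batch."""
        if self.config.patch_centered:
            x = shift2d(x, PATCH // 2, PATCH // 2)
        y = self.stem_bn(self.stem(x)).relu()
        return self.stages(y)


def build_backbone(config: BackboneConfig,
                   rng: np.random.Generator | None = None) -> FeatureExtractor:
    """Build a feature extractor; validates the restricted kernel layout."""
    if config.restricted:
        seq = config.layer_sequence()
        n3 = sum(1 for k, _ in seq if k == 3)
        expected = len(config.stage_block_counts)  # one per stage
        if n3 != expected:
            raise ValueError(
                f"restricted layout expects {expected} grouped 3x3 convolutions, "
                f"found {n3}")
    return FeatureExtractor(config, rng)


def receptive_field(config: BackboneConfig) -> tuple[int, int]:
    """Analytic receptive field and stride of the topmost convolution.

    Composes rf_l = rf_{l-1} + (k_l - 1) * j_{l-1} and j_l = j_{l-1} * s_l
    over the main-path layer sequence, starting from rf = 1, j = 1.
    """
    rf, j = 1, 1
    for k, s in config.layer_sequence():
        rf += (k - 1) * j
        j *= s
    return rf, j


def extract_features(extractor: FeatureExtractor, sample: ImageSample) -> FeatureGrid:
    """Run one image through the extractor (evaluation mode, no gradients)."""
    px = sample.pixels
    if px.ndim == 2:
        px = px[..., None]
    if px.shape[2] != extractor.config.in_channels:
        raise ValueError(
            f"sample has {px.shape[2]} channels, extractor expects "
            f"{extractor.config.in_channels}")
    x = Tensor(px.transpose(2, 0, 1)[None])
    was_training = extractor.training
    extractor.eval()
    try:
        with no_grad():
            y = extractor(x)
    finally:
        extractor.train(was_training)
    rf, stride = receptive_field(extractor.config)
    return FeatureGrid(values=y.data[0].transpose(1, 2, 0), stride=stride, rf=rf)


def empirical_receptive_field(extractor: FeatureExtractor,
                              input_size: int | None = None,
                              seed: int = 0) -> int:
    """Measure the receptive field with a gradient-footprint probe.

    Backpropagates a unit gradient from every channel of one interior output
    cell of a random-weight extractor and measures the bounding-box side of
    input pixels receiving non-zero gradient.  Evaluation-mode batch norm is
    used so normalization statistics do not couple distant pixels.  The probe
    is repeated over a few random inputs and the footprints are unioned so a
    rectifier zeroing individual paths cannot shrink the measured field.
    """
    rf, stride = receptive_field(extractor.config)
    if input_size is None:
        # smallest grid with a cell whose rf window is strictly interior
        input_size = int(np.ceil((rf + 2 * stride) / stride)) * stride + 2 * stride
        input_size = ((input_size + PATCH - 1) // PATCH) * PATCH
    rng = np.random.default_rng(seed)
    was_training = extractor.training
    extractor.eval()
    try:
        footprint = np.zeros((input_size, input_size), dtype=bool)
        cell = input_size // stride // 2
        for _ in range(2):
            x = Tensor(rng.uniform(0.2, 1.0,
                                   (1, extractor.config.in_channels,
                                    input_size, input_size)),
                       requires_grad=True)
            y = extractor(x)
            g = np.zeros_like(y.data)
            g[0, :, cell, cell] = 1.0
            y.backward(g)
            footprint |= (np.abs(x.grad).sum(axis=(0, 1)) > 0)
    finally:
        extractor.train(was_training)
    rows = np.flatnonzero(footprint.any(axis=1))
    cols = np.flatnonzero(footprint.any(axis=0))
    if rows.size == 0:
        return 0
    return int(max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1))
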