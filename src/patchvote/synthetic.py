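"""Synthetic symmetric-phantom generator.

Renders desk-scale stand-ins for frontal chest radiographs that carry the
two structural properties the method is designed around: bilateral (left-
right) symmetry of the bright "lung fields", and a position-dependent prior
over lesion locations (disease-prone areas).  Every image shows two
mirrored bright elliptical fields on a dark background; abnormal images
additionally contain 1-3 soft-edged bright blobs placed inside ONE field at
centers drawn from a spatial prior biased toward the upper lung zones, and
never mirrored.  Optional symmetric distractors — small bright blobs placed
at mirrored positions in BOTH fields — provide structure that is visible to
a classifier but carries no label information, emulating symmetric anatomy.

Images and masks are deterministic functions of ``(seed, index)``, so any
sample can be regenerated without storing data.  ``generate_dataset``
writes 8-bit PNGs plus a CSV manifest with a seeded 7:1:2
train:validation:test split.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .backbone import ImageSample

__all__ = ["SceneSpec", "generate_scene", "generate_dataset",
           "default_position_bias", "load_manifest", "load_sample"]


def default_position_bias(size: int, midline_guard: float = 0.0) -> np.ndarray:
    """Upper-field-biased prior over lesion centers, normalized to sum 1.

    The prior is the product of a vertical Gaussian centered in the upper
    lung zone with the indicator of the two elliptical fields (eroded so
    centers sit well inside a field).  ``midline_guard`` zeroes a central
    column band so that a blob of that radius centered anywhere in the
    prior's support can never cross the left/right midline.  The prior is
    left-right symmetric, so drawing a side uniformly and then a center
    from the prior restricted to that side reproduces the full prior.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    upper = np.exp(-0.5 * ((yy - 0.38 * size) / (0.20 * size)) ** 2)
    inside = _field_interior(size, margin=0.22 * size / 2)
    prior = upper * inside
    if midline_guard > 0:
        prior[np.abs(xx - (size - 1) / 2) < midline_guard] = 0.0
    total = prior.sum()
    if total <= 0:
        raise ValueError("degenerate position prior")
    return prior / total


def _field_params(size: int) -> tuple[float, float, float, float]:
    """(center_y, center_x_left, semi_axis_x, semi_axis_y) of the fields."""
    return 0.52 * size, 0.285 * size, 0.155 * size, 0.36 * size


def _field_interior(size: int, margin: float = 0.0) -> np.ndarray:
    cy, cxl, ax, ay = _field_params(size)
    cxr = (size - 1) - cxl          # exact mirror about the center line
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    axm, aym = max(ax - margin, 1.0), max(ay - margin, 1.0)
    left = ((xx - cxl) / axm) ** 2 + ((yy - cy) / aym) ** 2 <= 1.0
    right = ((xx - cxr) / axm) ** 2 + ((yy - cy) / aym) ** 2 <= 1.0
    return (left | right).astype(np.float64)


@dataclass
class SceneSpec:
    size: int = 64
    lesion_prob: float = 0.5
    lesion_radius_range: tuple[float, float] = (7.0, 13.0)
    position_bias: np.ndarray | None = None   # defaults to upper-field prior
    symmetric_distractors: bool = True
    noise_sd: float = 0.02
    n: int = 400
    seed: int = 0

    def __post_init__(self):
        if self.size % 16:
            raise ValueError(f"size {self.size} is not divisible by 16")
        if not 0 <= self.lesion_prob <= 1:
            raise ValueError("lesion_prob must lie in [0, 1]")
        rmin, rmax = self.lesion_radius_range
        if rmin < 1 or rmax < rmin:
            raise ValueError("lesion radii must satisfy 1 <= rmin <= rmax")
        if self.position_bias is None:
            self.position_bias = default_position_bias(
                self.size, midline_guard=self.lesion_radius_range[1])
        else:
            self.position_bias = np.asarray(self.position_bias, dtype=np.float64)
            if self.position_bias.shape != (self.size, self.size):
                raise ValueError("position_bias shape must match the image size")
            if abs(self.position_bias.sum() - 1.0) > 1e-6:
                raise ValueError("position_bias must sum to 1")


def _soft_blob(size: int, cy: float, cx: float, radius: float,
               edge: float = 1.5) -> np.ndarray:
    """Radial profile: 1 inside the disk, smooth sigmoid falloff at the rim."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return 1.0 / (1.0 + np.exp((d - radius) / edge))


def _render(spec: SceneSpec, index: int):
    """Deterministic scene synthesis shared by the public entry points."""
    rng = np.random.default_rng([spec.seed, index])
    size = spec.size
    image = np.full((size, size), 0.08)
    image += 0.42 * _field_interior(size)

    if spec.symmetric_distractors:
        n_d = int(rng.integers(1, 3))          # 1-2 mirrored pairs
        half = _field_interior(size, margin=5.0)
        half[:, size // 2:] = 0
        cand = np.argwhere(half > 0)
        for _ in range(n_d):
            cy, cx = cand[rng.integers(len(cand))]
            r_d = rng.uniform(2.0, 4.0)
            image += 0.30 * _soft_blob(size, cy, cx, r_d, edge=1.0)
            image += 0.30 * _soft_blob(size, cy, (size - 1) - cx, r_d, edge=1.0)

    mask = np.zeros((size, size), dtype=bool)
    centers: list[tuple[int, int]] = []
    if rng.uniform() < spec.lesion_prob:
        side_left = rng.uniform() < 0.5
        prior = spec.position_bias.copy()
        if side_left:
            prior[:, size // 2:] = 0
        else:
            prior[:, :size // 2] = 0
        flat = (prior / prior.sum()).ravel()
        yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
        for _ in range(int(rng.integers(1, 4))):   # 1-3 blobs, same field
            idx = int(rng.choice(flat.size, p=flat))
            cy, cx = idx // size, idx % size
            centers.append((cy, cx))
            radius = rng.uniform(*spec.lesion_radius_range)
            image += 0.38 * _soft_blob(size, cy, cx, radius)
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2

    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, image.shape)
    return np.clip(image, 0.0, 1.0), mask, centers


def generate_scene(spec: SceneSpec, index: int) -> ImageSample:
    """Render scene ``index``; fully determined by ``(spec.seed, index)``."""
    image, mask, _ = _render(spec, index)
    return ImageSample(pixels=image, labels=[int(mask.any())], mask=mask,
                       id=f"scene_{spec.seed}_{index:05d}")


def lesion_centers(spec: SceneSpec, index: int) -> list[tuple[int, int]]:
    """Lesion centers of scene ``index`` (empty list for normal scenes)."""
    return _render(spec, index)[2]


def _write_png(path: Path, array: np.ndarray) -> None:
    Image.fromarray((np.clip(array, 0, 1) * 255).round().astype(np.uint8)).save(path)


def split_indices(n: int, seed: int) -> dict[int, str]:
    """Seeded 7:1:2 train:validation:test assignment, no index in two splits."""
    order = np.random.default_rng([seed, 7, 1, 2]).permutation(n)
    n_train = int(0.7 * n)
    n_val = int(0.1 * n)
    assign = {}
    for pos, idx in enumerate(order):
        if pos < n_train:
            assign[int(idx)] = "train"
        elif pos < n_train + n_val:
            assign[int(idx)] = "val"
        else:
            assign[int(idx)] = "test"
    return assign


def generate_dataset(spec: SceneSpec, out_dir: str | Path,
                     overwrite: bool = False) -> pd.DataFrame:
    """Write ``spec.n`` scenes as PNGs plus a CSV manifest; returns the manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{out} exists and is not empty; pass overwrite=True")
        shutil.rmtree(out)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    assign = split_indices(spec.n, spec.seed)
    rows = []
    for i in range(spec.n):
        sample = generate_scene(spec, i)
        img_path = out / "images" / f"{sample.id}.png"
        _write_png(img_path, sample.pixels)
        mask_path = ""
        if sample.labels[0]:
            mask_path = str(Path("masks") / f"{sample.id}.png")
            _write_png(out / mask_path, sample.mask.astype(np.float64))
        rows.append({"id": sample.id,
                     "path": str(Path("images") / img_path.name),
                     "label": int(sample.labels[0]),
                     "split": assign[i],
                     "mask_path": mask_path})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_manifest(dataset_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(dataset_dir) / "manifest.csv",
                       keep_default_na=False)


def load_sample(dataset_dir: str | Path, row) -> ImageSample:
    """Read one manifest row back into an :class:`ImageSample`."""
    base = Path(dataset_dir)
    pixels = np.asarray(Image.open(base / row["path"]), dtype=np.float64) / 255.0
    mask = None
    if row["mask_path"]:
        mask = np.asarray(Image.open(base / row["mask_path"])) > 127
    return ImageSample(pixels=pixels, labels=[int(row["label"])],
                       mask=mask, id=str(row["id"]))
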