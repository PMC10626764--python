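"""Synthetic surgical-scene generator.

Emulates the gross structure of cataract-surgery frames that makes HOG maps
informative for segmentation: large smooth low-gradient "anatomy" regions
(soft-edged ellipses over a gently ramping background) and elongated
straight-edged high-gradient "instrument" shapes (rotated capsules with
sharp boundaries and distinct intensity). The class plan mirrors the
8-class cataract benchmark at small scale: background + 4 anatomy classes +
1 instrument class by default.

Every scene is deterministic in (seed, index), so datasets regenerate
bit-identically and fixtures never need to be stored.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image


class SceneError(RuntimeError):
    pass


# a fixed, visually distinct palette (RGB per class index)
_PALETTE = np.array([
    [40, 26, 24],     # background: dark surgical field
    [196, 110, 100],  # anatomy 1: sclera/skin tone
    [150, 60, 60],    # anatomy 2: iris
    [90, 30, 40],     # anatomy 3: pupil
    [210, 170, 150],  # anatomy 4: cornea highlight
    [190, 195, 205],  # instrument: metallic
    [120, 160, 120],  # extra classes cycle through
    [80, 110, 170],
], dtype=np.float64)


@dataclasses.dataclass(frozen=True)
class SceneConfig:
    """Generator parameters; image_size is (width, height)."""

    image_size: tuple[int, int] = (64, 128)
    n_anatomy_classes: int = 4
    n_instrument_classes: int = 1
    instrument_length_range: tuple[float, float] = (0.5, 0.9)   # of min dim
    instrument_width_range: tuple[float, float] = (0.08, 0.16)  # of min dim
    texture_noise_sd: float = 2.0       # intensity units (0-255 scale)
    background_gradient_scale: float = 30.0
    min_shape_pixels: int = 16
    max_attempts: int = 25
    seed: int = 0

    def __post_init__(self):
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValueError("image_size must be positive")
        if self.n_anatomy_classes < 0 or self.n_instrument_classes < 0:
            raise ValueError("class counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return 1 + self.n_anatomy_classes + self.n_instrument_classes


def _class_color(c: int) -> np.ndarray:
    return _PALETTE[c % len(_PALETTE)]


def _scene_rng(config: SceneConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, int(index)])


def generate_scene(config: SceneConfig, index: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One (image, mask) pair, deterministic in (seed, index).

    Image is (H, W, 3) uint8; mask is (H, W) int with exact per-pixel class.
    Shapes that land with too few visible pixels are re-drawn; after
    ``max_attempts`` failures a SceneError is raised.
    """
    rng = _scene_rng(config, index)
    W, H = config.image_size
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)

    # smooth background: linear ramp + radial falloff, low gradient everywhere
    cx, cy = rng.uniform(0.3, 0.7) * W, rng.uniform(0.3, 0.7) * H
    r = np.hypot((xx - cx) / W, (yy - cy) / H)
    ramp = (xx / W * rng.uniform(-1, 1) + yy / H * rng.uniform(-1, 1))
    shade = 1.0 - config.background_gradient_scale / 255.0 * (r + 0.5 * ramp)
    image = _class_color(0)[None, None, :] * shade[..., None]
    mask = np.zeros((H, W), dtype=np.int64)

    # anatomy: soft-edged ellipses, low-gradient interiors, drawn large→small
    for j in range(config.n_anatomy_classes):
        cls = 1 + j
        placed = False
        for _ in range(config.max_attempts):
            ecx, ecy = rng.uniform(0.2, 0.8) * W, rng.uniform(0.2, 0.8) * H
            ax = rng.uniform(0.18, 0.45) * W * (1.0 - 0.12 * j)
            ay = rng.uniform(0.18, 0.45) * H * (1.0 - 0.12 * j)
            theta = rng.uniform(0, np.pi)
            ct, st = np.cos(theta), np.sin(theta)
            u = ((xx - ecx) * ct + (yy - ecy) * st) / ax
            v = (-(xx - ecx) * st + (yy - ecy) * ct) / ay
            d = u * u + v * v
            inside = d <= 1.0
            if inside.sum() >= config.min_shape_pixels:
                placed = True
                break
        if not placed:
            raise SceneError(f"could not place anatomy class {cls}")
        # soft edge: alpha fades over the outer 15% of the ellipse radius
        alpha = np.clip((1.15 - np.sqrt(np.maximum(d, 0))) / 0.15, 0, 1)
        color = _class_color(cls) * rng.uniform(0.85, 1.15)
        image = image * (1 - alpha[..., None]) + color[None, None, :] * alpha[..., None]
        mask[inside] = cls

    # instruments: rotated capsules with sharp straight edges
    min_dim = min(W, H)
    for j in range(config.n_instrument_classes):
        cls = 1 + config.n_anatomy_classes + j
        placed = False
        for _ in range(config.max_attempts):
            length = rng.uniform(*config.instrument_length_range) * min_dim
            width = rng.uniform(*config.instrument_width_range) * min_dim
            theta = rng.uniform(0, np.pi)
            icx, icy = rng.uniform(0.25, 0.75) * W, rng.uniform(0.25, 0.75) * H
            dx, dy = np.cos(theta), np.sin(theta)
            # distance from the capsule's axis segment
            px, py = xx - icx, yy - icy
            t = np.clip(px * dx + py * dy, -length / 2, length / 2)
            dist = np.hypot(px - t * dx, py - t * dy)
            inside = dist <= width / 2
            if inside.sum() >= config.min_shape_pixels:
                placed = True
                break
        if not placed:
            raise SceneError(f"could not place instrument class {cls}")
        shine = 1.0 + 0.25 * (t / (length / 2))  # axial highlight
        color = _class_color(cls)[None, None, :] * shine[..., None]
        image = np.where(inside[..., None], color, image)  # hard edge, no AA
        mask[inside] = cls

    noisy = image + rng.normal(0.0, config.texture_noise_sd, size=image.shape)
    return np.clip(noisy, 0, 255).astype(np.uint8), mask


def save_indexed_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a label grid as an indexed (palette-mode) PNG."""
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = np.clip(_PALETTE, 0, 255).astype(np.uint8)
    flat = np.zeros((256, 3), dtype=np.uint8)
    flat[: len(palette)] = palette
    im.putpalette(flat.ravel().tolist())
    im.save(path)


def generate_dataset(config: SceneConfig, n_train: int, n_val: int,
                     n_test: int, out_dir: str | Path,
                     overwrite: bool = False) -> pd.DataFrame:
    """Write a dataset tree: images/, masks/, manifest.csv.

    Splits get disjoint scene indices (train first, then val, then test),
    so the same config always yields identical files. Refuses to write into
    a non-empty directory unless ``overwrite``.
    """
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split sizes must be non-negative")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty")
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    index = 0
    for split, n in (("train", n_train), ("val", n_val), ("test", n_test)):
        for _ in range(n):
            image, mask = generate_scene(config, index)
            sid = f"scene_{index:05d}"
            img_rel = f"images/{sid}.png"
            mask_rel = f"masks/{sid}.png"
            Image.fromarray(image).save(out_dir / img_rel)
            save_indexed_mask(mask, out_dir / mask_rel)
            # paths are relative to the dataset root so trees are relocatable
            rows.append({"id": sid, "image_path": img_rel,
                         "mask_path": mask_rel, "split": split})
            index += 1
    manifest = pd.DataFrame(rows, columns=["id", "image_path", "mask_path",
                                           "split"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def generate_samples(config: SceneConfig, n: int, start_index: int = 0):
    """In-memory LabeledSamples (images scaled to [0, 1]) without disk I/O."""
    from .training import LabeledSample

    samples = []
    for i in range(start_index, start_index + n):
        image, mask = generate_scene(config, i)
        samples.append(LabeledSample(image=image.astype(np.float64) / 255.0,
                                     mask=mask, sample_id=f"scene_{i:05d}"))
    return samples


def dataset_tree_hash(out_dir: str | Path) -> str:
    """SHA-256 over all files in a dataset tree, for determinism checks."""
    out_dir = Path(out_dir)
    h = hashlib.sha256()
    for p in sorted(out_dir.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
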