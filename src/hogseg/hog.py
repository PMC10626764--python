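"""Histogram-of-Oriented-Gradients pseudo-labels.

HOG descriptors computed from images serve as free, unsupervised regression
targets for an auxiliary task trained jointly with semantic segmentation.
The descriptor follows the classic recipe: resize to a fixed window,
grayscale, central-difference gradients, magnitude-weighted orientation
histograms over non-overlapping cells ("patches"), and L2-normalized
overlapping blocks of cells concatenated into one vector.

Two deliberate departures from the Dalal–Triggs original: votes go entirely
to the single bin whose half-open interval contains the orientation (no
bilinear vote splitting), and block normalization is plain L2 (no clipping).
Setting ``block_cells=1`` disables blocking and yields the naive
concatenation of per-cell histograms.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

#: RGB → luminance weights used before gradient computation.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class HOGConfigError(ValueError):
    """Raised for invalid descriptor hyperparameters."""


@dataclasses.dataclass(frozen=True)
class HOGConfig:
    """Descriptor hyperparameters.

    Parameters
    ----------
    resize_width, resize_height
        Detection-window size the image is resized to before anything else
        (width × height, pedestrian-window convention: 64 × 128 default).
    cell_width, cell_height
        Size in pixels of the non-overlapping cells over which one
        orientation histogram is accumulated.
    n_bins
        Number of orientation bins covering ``[0, angle_range)`` degrees;
        6 bins over 180° gives 30° per bin.
    block_cells
        Cells per block edge; blocks of ``block_cells × block_cells`` cells
        are L2-normalized jointly. ``1`` means no blocking.
    block_stride
        Block step in cells (1 = maximally overlapping blocks).
    angle_range
        180 for unsigned orientations (opposite directions identified).
    norm_eps
        Small constant guarding the block L2 normalization.
    """

    resize_width: int = 64
    resize_height: int = 128
    cell_width: int = 16
    cell_height: int = 16
    n_bins: int = 6
    block_cells: int = 2
    block_stride: int = 1
    angle_range: float = 180.0
    norm_eps: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("resize_width", "resize_height", "cell_width",
                     "cell_height", "n_bins", "block_cells", "block_stride"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise HOGConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.cell_width > self.resize_width:
            raise HOGConfigError("cell_width exceeds resize_width")
        if self.cell_height > self.resize_height:
            raise HOGConfigError("cell_height exceeds resize_height")
        if self.angle_range <= 0:
            raise HOGConfigError("angle_range must be positive")
        if self.norm_eps <= 0:
            raise HOGConfigError("norm_eps must be positive")

    @property
    def n_cells_x(self) -> int:
        return self.resize_width // self.cell_width

    @property
    def n_cells_y(self) -> int:
        return self.resize_height // self.cell_height

    @property
    def bin_width(self) -> float:
        """Angular width of one orientation bin in degrees."""
        return self.angle_range / self.n_bins

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HOGConfig":
        return cls(**d)


@dataclasses.dataclass
class GradientField:
    """Per-pixel signed gradients with magnitude and unsigned orientation."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    orientation: np.ndarray  # degrees in [0, 180)


@dataclasses.dataclass
class CellHistogramGrid:
    """Magnitude-weighted orientation votes, shape (n_cells_y, n_cells_x, k)."""

    hist: np.ndarray


@dataclasses.dataclass
class HOGDescriptor:
    """The flat pseudo-label vector with the config that produced it."""

    vector: np.ndarray
    config: HOGConfig

    def __len__(self) -> int:
        return int(self.vector.shape[0])


def descriptor_length(config: HOGConfig) -> int:
    """Closed-form length of the descriptor produced under ``config``.

    For cells of (w, h) inside a (W, H) window with b-cell blocks at stride
    s: ``n_blocks_x * n_blocks_y * b^2 * k`` with
    ``n_blocks_x = (floor(W/w) - b) // s + 1`` (and likewise in y).
    """
    ncx, ncy = config.n_cells_x, config.n_cells_y
    b, s = config.block_cells, config.block_stride
    if ncx < b or ncy < b:
        raise HOGConfigError(
            f"cell grid {ncy}x{ncx} smaller than one {b}x{b} block")
    nbx = (ncx - b) // s + 1
    nby = (ncy - b) // s + 1
    return nbx * nby * b * b * config.n_bins


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) RGB array to float luminance; pass 2-D through."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        r, g, b = LUMA_WEIGHTS
        return r * img[..., 0] + g * img[..., 1] + b * img[..., 2]
    raise ValueError(f"expected 2-D or RGB image, got shape {img.shape}")


def compute_gradients(image: np.ndarray) -> GradientField:
    """Central-difference gradients of a single-channel image.

    ``gx(r, c) = I(r, c+1) - I(r, c-1)`` (correlation with [-1, 0, 1]) and
    the transpose vertically; borders use replicate padding. Orientation is
    unsigned, folded into [0, 180), and set to 0 where the magnitude is 0.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D intensity grid, got ndim={img.ndim}")
    if img.size == 0:
        raise ValueError("empty image")
    padded = np.pad(img, 1, mode="edge")
    gx = padded[1:-1, 2:] - padded[1:-1, :-2]
    gy = padded[2:, 1:-1] - padded[:-2, 1:-1]
    magnitude = np.hypot(gx, gy)
    orientation = np.degrees(np.arctan2(gy, gx)) % 180.0
    orientation[magnitude == 0] = 0.0
    return GradientField(gx=gx, gy=gy, magnitude=magnitude, orientation=orientation)


def cell_histograms(grad: GradientField, config: HOGConfig) -> CellHistogramGrid:
    """Accumulate magnitude votes into nearest-bin orientation histograms.

    The grid is partitioned into non-overlapping cells; trailing pixels that
    do not fill a cell are dropped. Each pixel contributes its full gradient
    magnitude to the single bin whose interval
    ``[i * angle_range/k, (i+1) * angle_range/k)`` contains its orientation.
    """
    mag = np.asarray(grad.magnitude, dtype=np.float64)
    ori = np.asarray(grad.orientation, dtype=np.float64)
    H, W = mag.shape
    w, h, k = config.cell_width, config.cell_height, config.n_bins
    ncx, ncy = W // w, H // h
    if ncx < 1 or ncy < 1:
        raise HOGConfigError(
            f"cell {h}x{w} larger than image {H}x{W}")
    mag = mag[: ncy * h, : ncx * w]
    ori = ori[: ncy * h, : ncx * w]
    bins = np.floor_divide(ori, config.bin_width).astype(np.int64)
    np.clip(bins, 0, k - 1, out=bins)  # orientation 180.0 folds to bin k-1 guard
    # cell index per pixel, then a bincount over (cell, bin) pairs
    cy = np.arange(ncy * h) // h
    cx = np.arange(ncx * w) // w
    cell_idx = cy[:, None] * ncx + cx[None, :]
    flat = (cell_idx * k + bins).ravel()
    hist = np.bincount(flat, weights=mag.ravel(), minlength=ncy * ncx * k)
    return CellHistogramGrid(hist=hist.reshape(ncy, ncx, k))


def block_normalize(cells: CellHistogramGrid, config: HOGConfig) -> HOGDescriptor:
    """Slide blocks over the cell grid, L2-normalize each, concatenate.

    Each ``block_cells × block_cells`` window of cells (stride
    ``block_stride``) is flattened row-major and normalized as
    ``v / sqrt(||v||^2 + norm_eps^2)``; blocks are concatenated row-major.
    ``block_cells=1`` degenerates to per-cell normalized concatenation.
    """
    hist = cells.hist
    ncy, ncx, k = hist.shape
    b, s = config.block_cells, config.block_stride
    if ncx < b or ncy < b:
        raise HOGConfigError(
            f"cell grid {ncy}x{ncx} smaller than one {b}x{b} block")
    segments = []
    for by in range(0, ncy - b + 1, s):
        for bx in range(0, ncx - b + 1, s):
            v = hist[by:by + b, bx:bx + b, :].ravel()
            norm = np.sqrt(np.dot(v, v) + config.norm_eps ** 2)
            segments.append(v / norm)
    vector = np.concatenate(segments)
    return HOGDescriptor(vector=vector, config=config)


def resize_image(image: np.ndarray, width: int, height: int) -> np.ndarray:
    """Bilinear resize of an image array to (height, width)."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    pil = Image.fromarray(arr)
    return np.asarray(pil.resize((width, height), Image.BILINEAR), dtype=np.float64)


def hog_descriptor(image: np.ndarray, config: HOGConfig | None = None) -> HOGDescriptor:
    """Full pipeline: resize → grayscale → gradients → cells → blocks.

    Deterministic: identical input bytes produce an identical vector.
    """
    if config is None:
        config = HOGConfig()
    resized = resize_image(image, config.resize_width, config.resize_height)
    gray = to_grayscale(resized)
    grad = compute_gradients(gray)
    cells = cell_histograms(grad, config)
    return block_normalize(cells, config)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG image as an RGB uint8 array."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc


def batch_extract(
    image_paths: Sequence[str | Path],
    config: HOGConfig,
    out_store: str | Path,
    ids: Sequence[str] | None = None,
) -> dict[str, bool]:
    """Extract descriptors for many images into an HDF5 pseudo-label store.

    One dataset per image id (default: file stem), config in root attributes.
    Unreadable images are logged and skipped; the partial store stays valid.
    Re-running with the same inputs overwrites deterministically.

    Returns a map id → success flag.
    """
    out_store = Path(out_store)
    out_store.parent.mkdir(parents=True, exist_ok=True)
    if ids is None:
        ids = [Path(p).stem for p in image_paths]
    status: dict[str, bool] = {}
    with h5py.File(out_store, "w") as f:
        for key, val in config.to_dict().items():
            f.attrs[key] = val
        f.attrs["descriptor_length"] = descriptor_length(config)
        for image_id, path in zip(ids, image_paths):
            try:
                img = load_image(path)
            except OSError as exc:
                logger.error("skipping %s: %s", image_id, exc)
                status[image_id] = False
                continue
            desc = hog_descriptor(img, config)
            f.create_dataset(image_id, data=desc.vector)
            status[image_id] = True
    return status


def read_store_config(store: str | Path) -> HOGConfig:
    """Recover the HOGConfig embedded in a pseudo-label store."""
    with h5py.File(store, "r") as f:
        fields = {k: f.attrs[k] for k in f.attrs if k != "descriptor_length"}
    for k in ("resize_width", "resize_height", "cell_width", "cell_height",
              "n_bins", "block_cells", "block_stride"):
        fields[k] = int(fields[k])
    for k in ("angle_range", "norm_eps"):
        fields[k] = float(fields[k])
    return HOGConfig(**fields)


def read_store_vectors(store: str | Path) -> dict[str, np.ndarray]:
    """Load every descriptor in a store as id → vector."""
    with h5py.File(store, "r") as f:
        return {k: np.asarray(f[k]) for k in f.keys()}


def export_store_csv(store: str | Path, out_csv: str | Path) -> None:
    """Flat CSV export of a pseudo-label store for eyeballing."""
    vectors = read_store_vectors(store)
    with open(out_csv, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "dim", "vector"])
        for key in sorted(vectors):
            v = vectors[key]
            writer.writerow([key, v.shape[0], " ".join(f"{x:.8g}" for x in v)])


def extract_for_images(
    images: Iterable[np.ndarray], config: HOGConfig
) -> np.ndarray:
    """Stack descriptors for in-memory images into an (n, D) array."""
    return np.stack([hog_descriptor(img, config).vector for img in images])
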