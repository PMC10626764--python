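"""Dataset readers: manifest-driven sample provider with pseudo-label joins.

A dataset is a CSV manifest with columns (id, image_path, mask_path, split)
pointing at PNG/JPEG images and indexed-PNG masks. Masks are decoded by
their palette index, never by RGB matching; images resize bilinearly, masks
with nearest neighbour. Pseudo-labels are joined from an HDF5 store by id
and their absence is a hard error — never a silent zero vector.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .evaluation import resize_mask
from .hog import read_store_config, read_store_vectors
from .training import LabeledSample

MANIFEST_COLUMNS = ("id", "image_path", "mask_path", "split")


class DatasetError(RuntimeError):
    pass


def load_mask(path: str | Path) -> np.ndarray:
    """Read an indexed PNG mask as an integer label grid."""
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"mask file missing: {path}")
    with Image.open(path) as im:
        if im.mode == "P":
            return np.asarray(im, dtype=np.int64)
        if im.mode in ("L", "I", "I;16"):
            return np.asarray(im, dtype=np.int64)
        raise DatasetError(
            f"mask {path} has mode {im.mode}; expected palette or grayscale")


class DatasetProvider:
    """Lazily yields LabeledSamples in manifest order."""

    def __init__(self, manifest: pd.DataFrame,
                 image_size: tuple[int, int] | None = None,
                 n_classes: int | None = None,
                 base_dir: str | Path = "."):
        missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
        if missing:
            raise DatasetError(f"manifest missing columns {sorted(missing)}")
        self.manifest = manifest.reset_index(drop=True)
        self.base_dir = Path(base_dir)
        self.image_size = image_size  # (W, H) or None = native
        self.n_classes = n_classes
        self._store_vectors: dict[str, np.ndarray] | None = None
        self._store_dim: int | None = None

    def __len__(self) -> int:
        return len(self.manifest)

    def attach_store(self, store_path: str | Path) -> None:
        """Join HOG pseudo-labels from an HDF5 store by sample id."""
        from .hog import descriptor_length

        self._store_vectors = read_store_vectors(store_path)
        self._store_dim = descriptor_length(read_store_config(store_path))

    def subset(self, split: str) -> "DatasetProvider":
        sub = DatasetProvider(
            self.manifest[self.manifest["split"] == split],
            image_size=self.image_size, n_classes=self.n_classes,
            base_dir=self.base_dir)
        sub._store_vectors = self._store_vectors
        sub._store_dim = self._store_dim
        return sub

    def __getitem__(self, i: int) -> LabeledSample:
        row = self.manifest.iloc[i]
        sid = str(row["id"])
        img_path = self._resolve(row["image_path"])
        if not img_path.exists():
            raise DatasetError(f"sample {sid!r}: image file missing {img_path}")
        with Image.open(img_path) as im:
            im = im.convert("RGB")
            if self.image_size is not None:
                im = im.resize(self.image_size, Image.BILINEAR)
            image = np.asarray(im, dtype=np.float64) / 255.0
        mask = load_mask(self._resolve(row["mask_path"]))
        if self.image_size is not None:
            mask = resize_mask(mask, self.image_size[1], self.image_size[0])
        if self.n_classes is not None and mask.size and mask.max() >= self.n_classes:
            raise DatasetError(
                f"sample {sid!r}: mask label {int(mask.max())} >= "
                f"n_classes {self.n_classes}")
        pseudo = None
        if self._store_vectors is not None:
            if sid not in self._store_vectors:
                raise DatasetError(f"sample {sid!r}: pseudo-label missing from store")
            pseudo = self._store_vectors[sid]
        return LabeledSample(image=image, mask=mask, pseudo_label=pseudo,
                             sample_id=sid)

    def _resolve(self, p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    def samples(self) -> list[LabeledSample]:
        return [self[i] for i in range(len(self))]


def load_dataset(manifest_path: str | Path,
                 image_size: tuple[int, int] | None = None,
                 n_classes: int | None = None) -> DatasetProvider:
    """Open a manifest CSV as a sample provider."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DatasetError(f"manifest not found: {manifest_path}")
    return DatasetProvider(pd.read_csv(manifest_path),
                           image_size=image_size, n_classes=n_classes,
                           base_dir=manifest_path.parent)
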