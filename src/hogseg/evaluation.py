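"""Segmentation metrics: per-class IoU, mIoU, and experiment protocols.

IoU for class c is TP_c / (TP_c + FP_c + FN_c) counted over pixels; mIoU is
the arithmetic mean over evaluated classes. Classes absent from both the
prediction and the ground truth (TP+FP+FN = 0) are excluded from the mean
rather than scored 0 or 1 — a convention this package fixes explicitly.

Two pooling modes are provided: ``dataset_level`` pools confusion counts
over all images before computing per-class IoUs (the default), and
``image_level`` averages per-image mean IoUs (the quantity shown in
per-image distribution plots).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class EvaluationError(ValueError):
    pass


@dataclasses.dataclass
class ConfusionAccumulator:
    """Per-class TP/FP/FN pixel counts, accumulated over mask pairs."""

    n_classes: int
    tp: np.ndarray = None
    fp: np.ndarray = None
    fn: np.ndarray = None

    def __post_init__(self):
        if self.n_classes <= 0:
            raise EvaluationError("n_classes must be positive")
        z = np.zeros(self.n_classes, dtype=np.int64)
        self.tp = z.copy() if self.tp is None else self.tp
        self.fp = z.copy() if self.fp is None else self.fp
        self.fn = z.copy() if self.fn is None else self.fn

    def update(self, pred: np.ndarray, gt: np.ndarray,
               ignore_index: int | None = None) -> None:
        pred = np.asarray(pred)
        gt = np.asarray(gt)
        if pred.shape != gt.shape:
            raise EvaluationError(
                f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
        if ignore_index is not None:
            keep = gt != ignore_index
            pred, gt = pred[keep], gt[keep]
        for name, m in (("pred", pred), ("gt", gt)):
            if m.size and (m.min() < 0 or m.max() >= self.n_classes):
                bad = int(m.min()) if m.min() < 0 else int(m.max())
                raise EvaluationError(
                    f"{name} mask contains out-of-range label {bad} "
                    f"(n_classes={self.n_classes})")
        k = self.n_classes
        conf = np.bincount(gt.ravel() * k + pred.ravel(),
                           minlength=k * k).reshape(k, k)
        self.tp += np.diag(conf)
        self.fp += conf.sum(axis=0) - np.diag(conf)
        self.fn += conf.sum(axis=1) - np.diag(conf)

    def merge(self, other: "ConfusionAccumulator") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn

    def per_class_iou(self) -> dict[int, float]:
        """Class → IoU; classes never seen (TP+FP+FN=0) are omitted."""
        denom = self.tp + self.fp + self.fn
        return {c: self.tp[c] / denom[c]
                for c in range(self.n_classes) if denom[c] > 0}

    def miou(self) -> float:
        ious = self.per_class_iou()
        if not ious:
            raise EvaluationError("no class was ever present; mIoU undefined")
        return float(np.mean(list(ious.values())))


@dataclasses.dataclass
class IoUReport:
    """Per-class IoUs with their mean and the per-image distribution."""

    per_class_iou: dict[int, float]
    miou: float
    per_image_iou: list[float] = dataclasses.field(default_factory=list)

    def to_frame(self, class_names: Mapping[int, str] | None = None
                 ) -> pd.DataFrame:
        rows = [{"class": (class_names or {}).get(c, str(c)), "iou": v}
                for c, v in sorted(self.per_class_iou.items())]
        rows.append({"class": "mean", "iou": self.miou})
        return pd.DataFrame(rows)


def iou_per_class(pred_mask: np.ndarray, gt_mask: np.ndarray,
                  n_classes: int) -> dict[int, float]:
    """Per-class IoU of one mask pair; absent classes are omitted."""
    acc = ConfusionAccumulator(n_classes)
    acc.update(pred_mask, gt_mask)
    return acc.per_class_iou()


def miou(accumulations: Sequence[ConfusionAccumulator],
         averaging: str = "dataset_level") -> float:
    """Mean IoU over per-image accumulations.

    ``dataset_level`` pools the confusion counts first; ``image_level``
    averages each image's own mean IoU.
    """
    accs = list(accumulations)
    if not accs:
        raise EvaluationError("no accumulations given")
    if averaging == "dataset_level":
        pooled = ConfusionAccumulator(accs[0].n_classes)
        for a in accs:
            pooled.merge(a)
        return pooled.miou()
    if averaging == "image_level":
        return float(np.mean([a.miou() for a in accs]))
    raise EvaluationError(f"unknown averaging mode {averaging!r}")


def evaluate_masks(pred_masks: Sequence[np.ndarray],
                   gt_masks: Sequence[np.ndarray], n_classes: int,
                   averaging: str = "dataset_level") -> IoUReport:
    """Full report over a collection of prediction/ground-truth pairs."""
    accs = []
    for p, g in zip(pred_masks, gt_masks):
        a = ConfusionAccumulator(n_classes)
        a.update(p, g)
        accs.append(a)
    pooled = ConfusionAccumulator(n_classes)
    for a in accs:
        pooled.merge(a)
    score = miou(accs, averaging=averaging)
    return IoUReport(per_class_iou=pooled.per_class_iou(), miou=score,
                     per_image_iou=[a.miou() for a in accs])


def resize_mask(mask: np.ndarray, height: int, width: int) -> np.ndarray:
    """Nearest-neighbour resize of an integer label mask."""
    H, W = mask.shape
    ri = (np.arange(height) * H) // height
    ci = (np.arange(width) * W) // width
    return mask[ri[:, None], ci[None, :]]


def nested_subsets(ids: Sequence[str], fractions: Sequence[float],
                   seed: int) -> dict[float, list[str]]:
    """Per-fraction training subsets, nested so smaller ⊂ larger.

    One seeded permutation is drawn; fraction f takes its first
    ceil(f·n) elements, guaranteeing comparability across fractions.
    """
    for f in fractions:
        if not 0 < f <= 1:
            raise EvaluationError(f"fraction {f} outside (0, 1]")
    order = list(np.random.default_rng(seed).permutation(list(ids)))
    out = {}
    for f in sorted(fractions):
        k = max(1, int(np.ceil(f * len(order))))
        if k == 0:
            raise EvaluationError(f"fraction {f} yields 0 samples")
        out[f] = order[:k]
    return out


def size_sweep(train_samples, test_samples, model_spec, train_config,
               fractions: Sequence[float], seeds: Sequence[int],
               variants: Sequence[str] = ("single_task", "multi_task"),
               split_seed: int = 0) -> pd.DataFrame:
    """Varying-training-size protocol at desk scale.

    Trains every (fraction, variant, seed) cell on nested subsets of the
    training set and reports test mIoU; the multi-task variant uses the
    configured loss weights, the single-task variant sets beta = 0 and drops
    the heads. Returns columns (fraction, variant, seed, test_miou,
    subset_ids).
    """
    import dataclasses as dc

    from .training import LossWeights, train

    by_id = {s.sample_id: s for s in train_samples}
    subsets = nested_subsets(list(by_id), fractions, split_seed)
    rows = []
    for f in sorted(fractions):
        subset = [by_id[i] for i in subsets[f]]
        for variant in variants:
            if variant == "single_task":
                spec = dc.replace(model_spec, head_placement="none")
                cfg = dc.replace(train_config, loss_weights=LossWeights(
                    alpha=train_config.loss_weights.alpha, beta=0.0))
            elif variant == "multi_task":
                spec, cfg = model_spec, train_config
            else:
                raise EvaluationError(f"unknown variant {variant!r}")
            for seed in seeds:
                cfg_s = dc.replace(cfg, seed=int(seed))
                res = train(subset, spec, cfg_s)
                acc_report = evaluate_masks(
                    [res.model.predict_mask(s.image) for s in test_samples],
                    [s.mask for s in test_samples], model_spec.n_classes)
                rows.append({"fraction": f, "variant": variant,
                             "seed": int(seed), "test_miou": acc_report.miou,
                             "subset_ids": ";".join(subsets[f])})
    return pd.DataFrame(rows)
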