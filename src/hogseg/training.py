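"""Joint optimization of segmentation and HOG regression.

The objective is a weighted sum of the primary and auxiliary losses,

    L = (1/N) * sum_i  alpha * L_ce(x_i, y_i) + beta * L_hog(x_i, y_i_pl),

where ``L_ce`` is mean per-pixel categorical cross-entropy (averaged over
deep-supervision side maps when the backbone emits them), ``L_hog`` is the
mean over attached heads of the mean-squared error against the HOG
pseudo-label, and the 1/N is realized as the mini-batch mean. With beta = 0
the auxiliary branch is skipped entirely, so the trajectory is bit-identical
to training the plain single-task backbone under the same seed.

Optimization is Adam with a stepped learning-rate schedule: the initial rate
is halved every ``decay_every`` iterations (defaults: 2e-4, 50k-iteration
steps, 150k iterations, validation every 1k). Desk-scale runs override the
iteration budget, not the schedule shape.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .evaluation import ConfusionAccumulator
from .hog import HOGConfig, descriptor_length, extract_for_images
from .models import MultiTaskModel, MultiTaskModelSpec, MultiTaskOutput, build_model

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class LossWeights:
    """Weights of the primary (alpha) and auxiliary (beta) losses."""

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha + self.beta == 0:
            raise ValueError("alpha + beta must be positive")


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule; defaults are the full-scale settings."""

    loss_weights: LossWeights = LossWeights()
    lr0: float = 2e-4
    lr_decay: float = 0.5
    decay_every: int = 50_000
    max_iters: int = 150_000
    validate_every: int = 1_000
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.max_iters <= 0 or self.validate_every <= 0 or self.batch_size <= 0:
            raise ValueError("iteration counts and batch size must be positive")
        if self.validate_every > self.max_iters:
            raise ValueError("validate_every exceeds max_iters")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if isinstance(d.get("loss_weights"), dict):
            d["loss_weights"] = LossWeights(**d["loss_weights"])
        return cls(**d)


@dataclasses.dataclass
class LabeledSample:
    """One training triplet: image, ground-truth mask, HOG pseudo-label."""

    image: np.ndarray        # (H, W, 3) float in [0, 1]
    mask: np.ndarray         # (H, W) int class indices
    pseudo_label: np.ndarray | None = None  # (D,) float
    sample_id: str = ""

    def validate(self, n_classes: int, hog_dim: int | None = None) -> None:
        if self.mask.min() < 0 or self.mask.max() >= n_classes:
            raise ValueError(
                f"sample {self.sample_id!r}: mask labels outside [0, {n_classes})")
        if hog_dim is not None:
            if self.pseudo_label is None:
                raise ValueError(f"sample {self.sample_id!r}: pseudo-label missing")
            if self.pseudo_label.shape[0] != hog_dim:
                raise ValueError(
                    f"sample {self.sample_id!r}: pseudo-label length "
                    f"{self.pseudo_label.shape[0]} != hog_dim {hog_dim}")
            if not np.all(np.isfinite(self.pseudo_label)):
                raise ValueError(f"sample {self.sample_id!r}: non-finite pseudo-label")


def lr_at(iteration: int, config: TrainConfig) -> float:
    """Stepped learning rate: lr0 * decay^floor(iteration / decay_every)."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return config.lr0 * config.lr_decay ** (iteration // config.decay_every)


def joint_loss(output: MultiTaskOutput, mask: np.ndarray,
               target_hog: np.ndarray | None, weights: LossWeights
               ) -> tuple[nn.Tensor, float, float]:
    """Weighted multi-task loss.

    Returns (total tensor for backprop, ce value, hog value). The
    cross-entropy part averages over all segmentation maps (fused + side
    maps); the HOG part averages over heads. When beta is 0 or no heads are
    attached the auxiliary term is exactly 0 and never computed.
    """
    ce = nn.mean_tensors([nn.softmax_cross_entropy(m, mask)
                          for m in output.all_seg_maps])
    use_hog = weights.beta != 0 and len(output.hog_preds) > 0
    if use_hog:
        if target_hog is None:
            raise ValueError("target_hog required when beta > 0 and heads attached")
        target = np.asarray(target_hog, dtype=np.float64)
        for p in output.hog_preds:
            if p.data.shape[-1] != target.shape[-1]:
                raise ValueError(
                    f"HOG prediction length {p.data.shape[-1]} != "
                    f"target length {target.shape[-1]}")
        hog = nn.mean_tensors([nn.mse(p, target) for p in output.hog_preds])
        total = weights.alpha * ce + weights.beta * hog
        hog_val = hog.item()
    else:
        total = weights.alpha * ce
        hog_val = 0.0
    if not np.isfinite(total.item()):
        raise FloatingPointError(
            f"non-finite loss (ce={ce.item()}, hog={hog_val})")
    return total, ce.item(), hog_val


@dataclasses.dataclass
class TrainResult:
    model: MultiTaskModel
    metrics: pd.DataFrame
    best_state: dict[str, np.ndarray]
    best_miou: float
    best_iteration: int
    initial_loss: float
    final_loss: float


def _batch_arrays(samples: Sequence[LabeledSample], idx: np.ndarray,
                  need_hog: bool):
    imgs = np.stack([np.transpose(samples[i].image, (2, 0, 1)) for i in idx])
    masks = np.stack([samples[i].mask for i in idx])
    hogs = (np.stack([samples[i].pseudo_label for i in idx])
            if need_hog else None)
    return imgs, masks, hogs


def evaluate_miou(model: MultiTaskModel, samples: Sequence[LabeledSample],
                  n_classes: int) -> float:
    """Pooled-confusion mIoU of the model over a sample collection."""
    acc = ConfusionAccumulator(n_classes)
    for s in samples:
        acc.update(model.predict_mask(s.image), s.mask)
    return acc.miou()


def train(dataset: Sequence[LabeledSample], model_spec: MultiTaskModelSpec,
          config: TrainConfig, val_dataset: Sequence[LabeledSample] = (),
          checkpoint_path: str | Path | None = None) -> TrainResult:
    """Adam training of the joint objective with a seeded sampler.

    Logs (iteration, lr, total/ce/hog losses, validation mIoU) every
    ``validate_every`` iterations and keeps the best-by-validation-mIoU
    parameter set (falling back to training mIoU when no validation split is
    given). Fully deterministic for a fixed seed and dataset.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    weights = config.loss_weights
    need_hog = weights.beta != 0 and model_spec.resolved_placement != "none"
    for s in dataset:
        s.validate(model_spec.n_classes, model_spec.hog_dim if need_hog else None)
    model = build_model(model_spec)
    opt = nn.Adam(model.parameters(), lr=config.lr0)
    rng = np.random.default_rng(config.seed)
    rows = []
    best_state = model.state_dict()
    best_miou, best_iter = -1.0, 0
    initial_loss = final_loss = float("nan")
    val_pool = val_dataset if len(val_dataset) else dataset
    for it in range(config.max_iters):
        idx = rng.integers(0, len(dataset), size=min(config.batch_size,
                                                     len(dataset)))
        imgs, masks, hogs = _batch_arrays(dataset, idx, need_hog)
        out = model(imgs, with_heads=need_hog)
        try:
            total, ce_val, hog_val = joint_loss(out, masks, hogs, weights)
        except FloatingPointError:
            logger.error("NaN loss at iteration %d; keeping last checkpoint", it)
            break
        if it == 0:
            initial_loss = total.item()
        final_loss = total.item()
        model.zero_grad()
        total.backward()
        opt.lr = lr_at(it, config)
        opt.step()
        if (it + 1) % config.validate_every == 0 or it + 1 == config.max_iters:
            val_miou = evaluate_miou(model, val_pool, model_spec.n_classes)
            rows.append({"iteration": it + 1, "lr": lr_at(it, config),
                         "total": total.item(), "ce": ce_val, "hog": hog_val,
                         "val_miou": val_miou})
            if val_miou > best_miou:
                best_miou, best_iter = val_miou, it + 1
                best_state = model.state_dict()
            logger.info("iter %d lr %.2e total %.4f ce %.4f hog %.4f miou %.4f",
                        it + 1, lr_at(it, config), total.item(), ce_val,
                        hog_val, val_miou)
    metrics = pd.DataFrame(rows)
    result = TrainResult(model=model, metrics=metrics, best_state=best_state,
                         best_miou=best_miou, best_iteration=best_iter,
                         initial_loss=initial_loss, final_loss=final_loss)
    if checkpoint_path is not None:
        save_checkpoint(result, model_spec, config, checkpoint_path)
    return result


def save_checkpoint(result: TrainResult, model_spec: MultiTaskModelSpec,
                    config: TrainConfig, path: str | Path) -> None:
    """npz checkpoint: best parameters plus the specs that produced them."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({"model_spec": model_spec.to_dict(),
                       "train_config": config.to_dict(),
                       "best_miou": result.best_miou,
                       "best_iteration": result.best_iteration})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **result.best_state)


def load_checkpoint(path: str | Path) -> tuple[MultiTaskModel, dict]:
    """Rebuild a model from an npz checkpoint."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = build_model(MultiTaskModelSpec.from_dict(meta["model_spec"]))
    model.load_state_dict(state)
    return model, meta


def attach_pseudo_labels(samples: Sequence[LabeledSample],
                         hog_config: HOGConfig) -> None:
    """Compute each sample's HOG pseudo-label in place from its image."""
    vecs = extract_for_images(
        ((s.image * 255).astype(np.uint8) for s in samples), hog_config)
    for s, v in zip(samples, vecs):
        s.pseudo_label = v


def sweep(dataset: Sequence[LabeledSample], model_spec: MultiTaskModelSpec,
          config: TrainConfig, weight_grid: Sequence[tuple[float, float]],
          hog_configs: Sequence[HOGConfig],
          val_dataset: Sequence[LabeledSample] = ()) -> pd.DataFrame:
    """Cross-validation sweep over loss weights and HOG dimensions.

    One training run per (alpha, beta) × HOG-config cell, every cell on the
    identical dataset and split; returns a table with columns
    (alpha, beta, hog_dim, val_miou) plus the split hash for audit.
    """
    if not weight_grid or not hog_configs:
        raise ValueError("empty sweep grid")
    split_hash = dataset_hash(dataset)
    rows = []
    for hcfg in hog_configs:
        dim = descriptor_length(hcfg)
        attach_pseudo_labels(dataset, hcfg)
        spec = dataclasses.replace(model_spec, hog_dim=dim)
        for alpha, beta in weight_grid:
            cfg = dataclasses.replace(
                config, loss_weights=LossWeights(alpha=alpha, beta=beta))
            res = train(dataset, spec, cfg, val_dataset=val_dataset)
            rows.append({"alpha": alpha, "beta": beta, "hog_dim": dim,
                         "val_miou": res.best_miou, "split_hash": split_hash})
    return pd.DataFrame(rows)


def hog_dim_curve(sweep_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a sweep table to (hog_dim, val_miou) at equal loss weights."""
    eq = sweep_table[sweep_table["alpha"] == sweep_table["beta"]]
    if eq.empty:
        eq = sweep_table
    return (eq.groupby("hog_dim", as_index=False)["val_miou"].max()
            .sort_values("hog_dim").reset_index(drop=True))


def dataset_hash(samples: Sequence[LabeledSample]) -> str:
    """Stable hash of sample ids + mask bytes, for split-reuse audits."""
    import hashlib

    h = hashlib.sha256()
    for s in samples:
        h.update(s.sample_id.encode())
        h.update(np.ascontiguousarray(s.mask).tobytes())
    return h.hexdigest()[:16]


#: The loss-weight grid of the ablation study.
ABLATION_WEIGHT_GRID: tuple[tuple[float, float], ...] = (
    (0.01, 1.0), (0.1, 1.0), (1.0, 1.0), (1.0, 0.1), (1.0, 0.01))
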