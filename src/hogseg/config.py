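"""Run configuration: one YAML document wiring HOG, model, training and data.

The single cross-field invariant is enforced here: the model's ``hog_dim``
must equal the descriptor length implied by the HOG configuration. Every
artifact the pipeline writes embeds the short hash of the config that
produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .hog import HOGConfig, descriptor_length
from .models import MultiTaskModelSpec
from .synthetic import SceneConfig
from .training import TrainConfig


class RunConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    hog: HOGConfig = dataclasses.field(default_factory=HOGConfig)
    model: MultiTaskModelSpec = dataclasses.field(default_factory=MultiTaskModelSpec)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    scene: SceneConfig = dataclasses.field(default_factory=SceneConfig)
    data_dir: str = "data"
    output_dir: str = "runs"

    def validate(self, check_paths: bool = False) -> None:
        d = descriptor_length(self.hog)
        if self.model.hog_dim != d:
            raise RunConfigError(
                f"model.hog_dim={self.model.hog_dim} inconsistent with the HOG "
                f"configuration (descriptor_length={d})")
        if check_paths and not Path(self.data_dir).exists():
            raise RunConfigError(f"data_dir does not exist: {self.data_dir}")

    def to_dict(self) -> dict:
        return {
            "hog": self.hog.to_dict(),
            "model": self.model.to_dict(),
            "train": self.train.to_dict(),
            "scene": dataclasses.asdict(self.scene),
            "data_dir": self.data_dir,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        scene = dict(d.get("scene", {}))
        for key in ("image_size", "instrument_length_range",
                    "instrument_width_range"):
            if key in scene:
                scene[key] = tuple(scene[key])
        return cls(
            hog=HOGConfig.from_dict(d.get("hog", {})),
            model=MultiTaskModelSpec.from_dict(d.get("model", {})),
            train=TrainConfig.from_dict(d.get("train", {})),
            scene=SceneConfig(**scene),
            data_dir=d.get("data_dir", "data"),
            output_dir=d.get("output_dir", "runs"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """Short stable hash embedded in every artifact this config produces."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def desk_scale_config(seed: int = 0) -> RunConfig:
    """The shipped small-footprint profile: 64×128 inputs, narrow models,
    a few hundred iterations — trains in seconds on one CPU."""
    hog = HOGConfig()
    return RunConfig(
        hog=hog,
        model=MultiTaskModelSpec(backbone="unet", n_classes=6,
                                 input_size=(64, 128),
                                 hog_dim=descriptor_length(hog),
                                 width_scale=0.125, n_stages=3, seed=seed),
        train=TrainConfig(max_iters=300, validate_every=100, batch_size=2,
                          seed=seed),
        scene=SceneConfig(seed=seed),
    )
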