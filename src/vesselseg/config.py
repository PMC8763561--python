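"""Run configuration: one serialisable object reproducing a whole run.

A :class:`RunConfig` bundles the preprocessing, augmentation, model and
training settings plus the dataset preset and the top-level seed from
which every stage's randomness is derived.  ``to_yaml``/``from_yaml``
round-trip exactly, so a saved config re-creates a run.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .network import ModelConfig, preset
from .patches import CHASE_AUGMENT, DRIVE_AUGMENT, AugmentConfig
from .preprocessing import PreprocessConfig
from .training import TrainConfig

__all__ = ["RunConfig", "dataset_augment", "dataset_batch_size"]

_DATASET_AUGMENT = {"drive": DRIVE_AUGMENT, "chase": CHASE_AUGMENT}
_DATASET_BATCH = {"drive": 8, "chase": 16}


def dataset_augment(preset_name: str) -> AugmentConfig:
    return _DATASET_AUGMENT.get(preset_name, DRIVE_AUGMENT)


def dataset_batch_size(preset_name: str) -> int:
    return _DATASET_BATCH.get(preset_name, 8)


@dataclasses.dataclass
class RunConfig:
    dataset: str = "synthetic"  # drive | chase | synthetic
    data_root: str = "data"
    output_root: str = "runs"
    seed: int = 42
    model_preset: str = "a5"
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    augment: AugmentConfig = dataclasses.field(default_factory=lambda: DRIVE_AUGMENT)
    model: ModelConfig = dataclasses.field(default_factory=lambda: preset("a5"))
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    per_image_patches: int = 100
    patch_size: int = 64
    train_frac: float = 0.8

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("preprocess", PreprocessConfig),
                         ("augment", AugmentConfig),
                         ("model", ModelConfig),
                         ("train", TrainConfig)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for f in dataclasses.fields(typ):
                    if f.name in sub and isinstance(sub[f.name], list):
                        sub[f.name] = tuple(sub[f.name])
                d[key] = typ(**sub)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(Path(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _listify(obj):
    """YAML-safe copy: tuples become lists (round-trip restores them)."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj
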