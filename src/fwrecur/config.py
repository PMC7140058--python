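"""Run configuration: one serializable object drives the whole pipeline.

Every stochastic step derives its stream from the single ``seed`` through
named ``numpy.random.SeedSequence`` spawns, so a config file fully
determines a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .phantom import PhantomParams
from .freewater import TrainConfig
from .tensors import RestoreConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # cohort
    n_patients: int = 10
    snr: float = 30.0
    s0: float = 1000.0
    seed: int = 0
    # gradient scheme
    n_directions: int = 32
    b_value: float = 800.0
    n_b0: int = 1
    scheme_seed: int = 7
    # ANN training
    n_training_samples: int = 50_000
    # correction
    f_floor: float = 0.1
    d_free: float = 3.0e-3
    # tensor fitting
    fit_method: str = "restore"
    noise_debias: bool = True
    # prediction
    n_patches_per_class: int = 4
    patch_voxels: tuple[int, int, int] = (3, 3, 3)
    cv_folds: int = 3
    # nested parameter blocks
    phantom: PhantomParams = field(default_factory=PhantomParams)
    training: TrainConfig = field(default_factory=TrainConfig)
    restore: RestoreConfig = field(default_factory=RestoreConfig)

    def seeds(self) -> dict[str, int]:
        """Named derived seeds (stable, below 2**31) for each stage."""
        root = np.random.SeedSequence(self.seed)
        names = ["cohort", "training", "patches", "cv"]
        children = root.spawn(len(names))
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_to_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "phantom" in kwargs and isinstance(kwargs["phantom"], dict):
            kwargs["phantom"] = PhantomParams(**_tuplify(kwargs["phantom"]))
        if "training" in kwargs and isinstance(kwargs["training"], dict):
            kwargs["training"] = TrainConfig(**kwargs["training"])
        if "restore" in kwargs and isinstance(kwargs["restore"], dict):
            kwargs["restore"] = RestoreConfig(**kwargs["restore"])
        if "patch_voxels" in kwargs:
            kwargs["patch_voxels"] = tuple(kwargs["patch_voxels"])
        return cls(**kwargs)


_TUPLE_FIELDS = {
    "shape", "voxel_size", "wm_eigs", "wm_f", "tumor_eigs", "tumor_f",
    "edema_eigs", "edema_f",
}


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
            for k, v in d.items()}


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
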