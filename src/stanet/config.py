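"""Pipeline configuration: every tunable in one validated record."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # simulation
    n_pos: int = 51
    n_neg: int = 21
    timepoints: int = 100
    voxels: int = 1000
    n_sources: int = 17
    effect_size: float = 2.0
    snr: float = 10.0
    # feature extraction
    discard: int = 5
    n_components: int = 17
    n_networks: int = 90
    restarts: int = 10
    # fusion
    kernel_sizes: tuple[int, ...] = (3, 5, 7, 9, 11)
    n_filters: int = 8
    pool: int = 6
    # balancing
    sampler: str = "smote"
    smote_k: int = 5
    # classifier
    hidden: int = 200
    layers: int = 3
    attn_dim: int = 64
    lr: float = 0.01
    rounds: int = 500
    epochs: int | None = None  # gradient epochs; defaults to rounds
    val_fraction: float = 0.2
    # evaluation
    folds: int = 10
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.kernel_sizes = tuple(int(k) for k in self.kernel_sizes)
        positive = (
            "n_pos", "n_neg", "timepoints", "voxels", "n_sources",
            "n_components", "n_networks", "restarts", "n_filters", "pool",
            "smote_k", "hidden", "layers", "attn_dim", "rounds", "folds",
        )
        for name in positive:
            if getattr(self, name) < 1:
                raise ValueError(f"config field {name!r} must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs is not None and self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in [0, 0.5)")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.discard < 0 or self.discard >= self.timepoints:
            raise ValueError("discard must be in [0, timepoints)")
        if self.sampler not in ("smote", "random", "none"):
            raise ValueError("sampler must be one of smote/random/none")
        for k in self.kernel_sizes:
            if k < 1 or k % 2 == 0:
                raise ValueError("kernel sizes must be odd and >= 1")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel_sizes"] = list(self.kernel_sizes)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
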