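"""Pipeline configuration with defaults matching the reference protocol."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Validated knobs for the extraction/classification pipeline.

    Defaults reproduce the reference protocol: 1000 resample points, 0.5 s
    annotation padding, displacement/velocity/acceleration derivative orders,
    alpha = 0.05 with one million null replicates, equal face-size weights.
    """

    n_points: int = 1000
    pad_s: float = 0.5
    orders: tuple[int, ...] = (0, 1, 2)
    alpha: float = 0.05
    n_sim: int = 1_000_000
    seed: int = 0
    fps: float = 60.0
    refine_timings: bool = True
    cubic_resampling: bool = False
    face_size_weights: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.pad_s < 0:
            raise ValueError("pad_s must be nonnegative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if any(o not in (0, 1, 2) for o in self.orders):
            raise ValueError("orders must be within (0, 1, 2)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "orders" in data:
            data["orders"] = tuple(data["orders"])
        if data.get("face_size_weights") is not None:
            data["face_size_weights"] = tuple(data["face_size_weights"])
        return cls(**data)
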