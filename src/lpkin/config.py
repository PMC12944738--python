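"""Run configuration: one serializable object mirroring every stage's knobs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .signal_filters import FilterConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything the analysis pipeline needs besides the detections.

    Defaults are the standard study conditions: 50 fps video, a 2.20 m
    Olympic bar, SG(9, 3) smoothing, a 6 Hz zero-phase low-pass, a 0.5 m/s
    concentric threshold with a 5-frame minimum interval, and linear
    interpolation across detector dropouts of at most 5 frames.
    """

    fps: float = 50.0
    L_real: float = 2.20          # m
    mass_m: float = 25.0          # kg, bar plus plates
    g: float = 9.81               # m/s^2
    sg_window: int = 9
    sg_order: int = 3
    butter_cutoff: float = 6.0    # Hz
    butter_order: int = 4
    v_threshold: float = 0.5      # m/s
    min_frames: int = 5
    max_gap: int = 5              # frames
    dialect: str = "yolo_obb_txt"
    image_width: int = 1920
    image_height: int = 1080

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.L_real <= 0 or self.mass_m <= 0:
            raise ConfigurationError("fps, L_real and mass_m must be positive")
        if self.min_frames < 2:
            raise ConfigurationError("min_frames must be >= 2")
        # delegate filter-parameter validation
        self.filter_config()

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            fs=self.fps,
            sg_window=self.sg_window,
            sg_order=self.sg_order,
            butter_cutoff=self.butter_cutoff,
            butter_order=self.butter_order,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def dump_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def replace(self, **overrides) -> "RunConfig":
        data = self.to_dict()
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig.from_dict(data)
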