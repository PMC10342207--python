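"""Pipeline configuration: time grid, fitting, segmentation and ML settings."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import TimeGrid
from .features import SegmentationConfig
from .fitting import FitConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run.

    The grid defaults mirror a 256-channel TCSPC acquisition at an 80 MHz
    repetition rate (12.5 ns period); ``frequency`` is in GHz (cycles/ns) and
    must equal ``1/period``.
    """

    n_channels: int = 256
    period_ns: float = 12.5
    frequency_ghz: float = 0.08
    irf_fwhm_ns: float = 0.3
    irf_center_ns: float = 1.0
    fit: FitConfig = field(default_factory=FitConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    seed: int = 0
    n_estimators: int = 500
    group_by_field: bool = False

    def __post_init__(self) -> None:
        if abs(self.period_ns - 1.0 / self.frequency_ghz) > 1e-9:
            raise ValueError(
                f"period {self.period_ns} ns inconsistent with frequency "
                f"{self.frequency_ghz} GHz (expected period = 1/frequency)"
            )

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(n_channels=self.n_channels, period=self.period_ns)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fit"] = asdict(self.fit)
        d["segmentation"] = asdict(self.segmentation)
        return d

    def write_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        fit = FitConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in payload.pop("fit", {}).items()})
        seg = SegmentationConfig(**payload.pop("segmentation", {}))
        return cls(fit=fit, segmentation=seg, **payload)
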