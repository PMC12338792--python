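"""Pipeline configuration with YAML round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .io import SCALES


@dataclass
class PipelineConfig:
    """All tunables of the simulate/analyze workflow.

    Defaults reproduce the study conditions: averaging window 10, edge trim
    15, prominence = 3x air-region SD, minimum dermal fit length 5 points,
    alpha 0.05, IQR multiplier 3, optical-path thickness (refractive index
    1.0), natural-log intensity scale.
    """

    window: int = 10
    edge_trim: int = 15
    prominence_multiplier: float = 3.0
    prominence_value: float | None = None
    min_fit_points: int = 5
    roi_trim_start: int = 2
    roi_trim_end: int = 1
    alpha: float = 0.05
    iqr_k: float = 3.0
    refractive_index: float = 1.0
    scale: str = "log"
    seed: int = 0
    # simulate-only settings
    n_mice: int = 6
    n_months: int = 8
    n_ascans_per_bscan: int = 1355
    n_bscans: int = 120
    n_axial: int = 256
    out_dir: str = "skinoct_out"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValidationError("window must be >= 1")
        if self.edge_trim < 0:
            raise ValidationError("edge_trim must be >= 0")
        if self.prominence_multiplier <= 0:
            raise ValidationError("prominence_multiplier must be positive")
        if self.min_fit_points < 2:
            raise ValidationError("min_fit_points must be >= 2")
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")
        if self.iqr_k <= 0:
            raise ValidationError("iqr_k must be positive")
        if self.refractive_index <= 0:
            raise ValidationError("refractive_index must be positive")
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}")
        if not 1 <= self.n_months <= 8:
            raise ValidationError("n_months must be in 1..8")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
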