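"""Run configuration: every tunable threshold of the pipeline in one place.

A config can be loaded from YAML or JSON; unknown keys are rejected so a
typo in a config file fails loudly rather than silently falling back to a
default.  ``config_hash`` gives a stable digest used in provenance records.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # calibration
    pixels_per_cm: float | None = None  # manual override; wins over everything
    page_width_cm: float | None = None  # None = auto A4 by orientation
    strict_calibration: bool = False
    # ink extraction
    min_speck_px: int | None = None  # None = auto (25 px at 300 dpi, scaled)
    margin_frac: float = 0.08
    closing_radius_px: int = 3
    # segmentation
    alpha: float = 0.45  # crown collapse fraction of max extent
    beta: float = 1.6  # root flare multiple of trunk median extent
    run_rows: int | None = None  # None = auto (1% of silhouette height, >= 3)
    smooth_window_rows: int | None = None  # None = auto (2% of height, odd)
    # orchestration
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.pixels_per_cm is not None and self.pixels_per_cm <= 0:
            raise ValueError("pixels_per_cm must be positive")
        if self.page_width_cm is not None and self.page_width_cm <= 0:
            raise ValueError("page_width_cm must be positive")
        if self.min_speck_px is not None and self.min_speck_px < 0:
            raise ValueError("min_speck_px must be >= 0")
        if not 0 <= self.margin_frac < 0.5:
            raise ValueError("margin_frac must lie in [0, 0.5)")
        if self.closing_radius_px < 0:
            raise ValueError("closing_radius_px must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.beta <= 1:
            raise ValueError("beta must exceed 1")
        if self.run_rows is not None and self.run_rows < 1:
            raise ValueError("run_rows must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
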