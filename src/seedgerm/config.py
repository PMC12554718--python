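"""Pipeline configuration.

All thresholds are pixel-unit quantities tied to the reference imaging setup
(1920x1080 top-view dish photographs); they are resolution dependent and
exposed here so users with different optics can rescale them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import yaml

CountingMode = Literal["floor", "rounded"]
RatioVariant = Literal["body", "whole"]


@dataclasses.dataclass
class PipelineConfig:
    """Tunable parameters of the germination pipeline.

    Defaults are the reference values of the published pipeline where one is
    printed (noise floor 200 px, stability gap 30 px, radicle RGB floor 160,
    ratio RGB floor 100, T_g 100, ratio standard 0.4); the rest are this
    package's own documented choices.
    """

    #: connected components below this area (px) are discarded as noise
    noise_min_area: int = 200
    #: maximal area gap (px) between consecutive sorted components still
    #: considered "stable" when estimating the single-seed area
    stability_gap: float = 30.0
    #: minimum number of consecutive stable gaps for a stable run
    stability_run_length: int = 2
    #: radicle candidates need all of R, G, B strictly above this value
    radicle_rgb_floor: int = 160
    #: within a seed crop, pixels with all channels above this are radicle
    ratio_rgb_floor: int = 100
    #: which standard the batch pipeline applies: "area" compares radicle
    #: region area against tg; "ratio" compares the region's area ratio
    #: (relative to the estimated single-seed area) against ratio_standard
    standard_mode: Literal["area", "ratio"] = "area"
    #: germination area threshold T_g: radicle regions with area > T_g count
    tg: float = 100.0
    #: area-ratio germination standard (used in ratio mode)
    ratio_standard: float = 0.4
    #: which ratio definition the standard refers to: "body" compares
    #: radicle/seed-body, "whole" compares radicle/(body+radicle)
    ratio_variant: RatioVariant = "body"
    #: smallest radicle region kept by the size filter (px)
    radicle_min_area: int = 20
    #: largest radicle region kept, as a multiple of the single-seed area
    radicle_max_area_factor: float = 5.0
    #: seed counting rule: "floor" (multiplicity floor(s_i/s_opt)) or
    #: "rounded" (max(1, round(s_i/s_opt)))
    counting_mode: CountingMode = "floor"
    #: pixel connectivity for component extraction
    connectivity: Literal[4, 8] = 8
    #: IoU threshold for detection matching in evaluation
    iou_threshold: float = 0.5
    #: Gaussian pre-smoothing sigma (3x3 kernel)
    gaussian_sigma: float = 0.8

    def __post_init__(self) -> None:
        if self.noise_min_area < 0:
            raise ValueError("noise_min_area must be non-negative")
        if self.stability_gap <= 0 or self.stability_run_length < 1:
            raise ValueError("invalid stability parameters")
        if self.tg <= 0:
            raise ValueError("tg must be positive")
        if not 0 < self.ratio_standard <= 1:
            raise ValueError("ratio_standard must lie in (0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not 0 < self.iou_threshold < 1:
            raise ValueError("iou_threshold must lie in (0, 1)")
        if self.standard_mode not in ("area", "ratio"):
            raise ValueError("standard_mode must be 'area' or 'ratio'")
        if self.counting_mode not in ("floor", "rounded"):
            raise ValueError("counting_mode must be 'floor' or 'rounded'")
        if self.ratio_variant not in ("body", "whole"):
            raise ValueError("ratio_variant must be 'body' or 'whole'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML mapping; unknown keys raise."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )
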