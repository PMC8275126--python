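"""Simulation and run configuration with strict validation.

Unknown keys are rejected everywhere so that a typo in a YAML file fails
loudly instead of silently falling back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

__all__ = [
    "CohortConfig",
    "ImageConfig",
    "TrackConfig",
    "SimConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated fluorescence-onset cohort."""

    n_traces: int = 17
    onset_mean_h: float = 15.5
    onset_sd_h: float = 0.36
    frame_interval_min: float = 30.0
    duration_h: float = 20.0
    rise_time_h: float = 2.0  # 10-90% rise of the logistic
    noise_sd: float = 0.02  # fraction of plateau
    baseline: float = 0.05  # fraction of plateau

    def __post_init__(self) -> None:
        _require(self.n_traces >= 1, "cohort.n_traces must be >= 1")
        _require(self.onset_mean_h > 0, "cohort.onset_mean_h must be positive")
        _require(self.onset_sd_h >= 0, "cohort.onset_sd_h must be >= 0")
        _require(self.frame_interval_min > 0, "cohort.frame_interval_min must be positive")
        _require(self.duration_h > 0, "cohort.duration_h must be positive")
        _require(self.rise_time_h > 0, "cohort.rise_time_h must be positive")
        _require(self.noise_sd >= 0, "cohort.noise_sd must be >= 0")
        _require(0 <= self.baseline < 1, "cohort.baseline must be in [0, 1)")


@dataclass(frozen=True)
class ImageConfig:
    """Parameters of a simulated organoid image pair."""

    size_px: int = 512
    pixel_size_um: float = 1.0
    organoid_radius_um: float = 150.0
    n_domains: int = 1
    domain_radius_um: float = 40.0
    fg_intensity: float = 200.0
    bg_intensity: float = 40.0
    noise_sd: float = 5.0
    min_domain_gap_um: float = 10.0

    def __post_init__(self) -> None:
        _require(self.size_px >= 8, "image.size_px must be >= 8")
        _require(self.pixel_size_um > 0, "image.pixel_size_um must be positive")
        _require(self.organoid_radius_um > 0, "image.organoid_radius_um must be positive")
        _require(self.n_domains in (1, 2, 3, 4), "image.n_domains must be in {1,2,3,4}")
        _require(self.domain_radius_um > 0, "image.domain_radius_um must be positive")
        _require(self.fg_intensity > self.bg_intensity, "image.fg_intensity must exceed bg_intensity")
        _require(self.noise_sd >= 0, "image.noise_sd must be >= 0")
        _require(self.min_domain_gap_um >= 0, "image.min_domain_gap_um must be >= 0")
        _require(
            self.domain_radius_um <= self.organoid_radius_um,
            "image.domain_radius_um must fit inside the organoid",
        )


@dataclass(frozen=True)
class TrackConfig:
    """Parameters of simulated 3D nuclear tracks.

    Cells diffuse (per-axis step variance 2*D*dt) until ``t_switch_h``,
    then move radially at ``v_um_per_min``; each cell is outward with
    probability ``p_outward`` (label fixed for the whole track).
    """

    n_cells: int = 500
    aggregate_radius_um: float = 150.0
    D_um2_per_min: float = 0.5
    v_um_per_min: float = 0.45
    p_outward: float = 0.51
    t_switch_h: float = 10.0
    duration_h: float = 16.0
    dt_min: float = 15.0
    loc_noise_um: float = 0.5
    miss_rate: float = 0.0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 1, "tracks.n_cells must be >= 1")
        _require(self.aggregate_radius_um > 0, "tracks.aggregate_radius_um must be positive")
        _require(self.D_um2_per_min >= 0, "tracks.D_um2_per_min must be >= 0")
        _require(self.v_um_per_min >= 0, "tracks.v_um_per_min must be >= 0")
        _require(0 <= self.p_outward <= 1, "tracks.p_outward must be in [0, 1]")
        _require(self.t_switch_h < self.duration_h, "tracks.t_switch_h must precede duration_h")
        _require(self.t_switch_h >= 0, "tracks.t_switch_h must be >= 0")
        _require(self.duration_h > 0, "tracks.duration_h must be positive")
        _require(self.dt_min > 0, "tracks.dt_min must be positive")
        _require(self.loc_noise_um >= 0, "tracks.loc_noise_um must be >= 0")
        _require(0 <= self.miss_rate <= 1, "tracks.miss_rate must be in [0, 1]")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_h * 60.0 / self.dt_min))

    @property
    def switch_frame(self) -> int:
        """First frame index whose time is >= t_switch_h."""
        import math

        return int(math.ceil(self.t_switch_h * 60.0 / self.dt_min - 1e-9))


def _build(cls, data: dict, prefix: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {prefix} key(s): {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class SimConfig:
    """Full generative parameter set for one synthetic experiment.

    Identical configs (including seed) produce bit-identical outputs.
    """

    seed: int = 0
    cohort: Optional[CohortConfig] = None
    image: Optional[ImageConfig] = None
    tracks: Optional[TrackConfig] = None

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        known = {"seed", "cohort", "image", "tracks"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kw: dict[str, Any] = {"seed": int(data.get("seed", 0))}
        if "cohort" in data and data["cohort"] is not None:
            kw["cohort"] = _build(CohortConfig, dict(data["cohort"]), "cohort")
        if "image" in data and data["image"] is not None:
            kw["image"] = _build(ImageConfig, dict(data["image"]), "image")
        if "tracks" in data and data["tracks"] is not None:
            kw["tracks"] = _build(TrackConfig, dict(data["tracks"]), "tracks")
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"seed": self.seed}
        for name in ("cohort", "image", "tracks"):
            block = getattr(self, name)
            if block is not None:
                out[name] = dataclasses.asdict(block)
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)
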