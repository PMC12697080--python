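"""Pipeline configuration: dataclasses + YAML loading.

One flat YAML file drives the whole pipeline; the seed is mandatory.
Period windows default to the historical / near-future / far-future
convention (1962-2021 / 2022-2051 / 2071-2100 at demo scale).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .synthetic import SyntheticConfig

__all__ = ["ModelSpec", "PipelineConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class ModelSpec:
    """One pseudo-GCM member: its name and true distortion parameters."""

    name: str
    bias: float = 2.0
    var_inflation: float = 1.3
    noise_sd: float = 0.5


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    models: list[ModelSpec] = field(
        default_factory=lambda: [
            ModelSpec("GCM-A", bias=2.5, var_inflation=1.4),
            ModelSpec("GCM-B", bias=-1.5, var_inflation=0.8),
        ]
    )
    #: scenario label -> future warming trend (degC / year past the switch)
    scenarios: dict[str, float] = field(
        default_factory=lambda: {"SSP2-4.5": 0.04, "SSP5-8.5": 0.08}
    )
    periods: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "historical": (1962, 2021),
            "near": (2022, 2051),
            "far": (2071, 2100),
        }
    )
    min_duration: int = 3
    window_halfwidth: int = 7
    percentile: float = 90.0
    alpha: float = 0.05
    rr: float = 1.20
    rr_low: float = 1.02
    rr_high: float = 1.41
    raster_indices: list[str] = field(default_factory=lambda: ["tx90p", "hwf"])
    raster_cell_size: float = 0.5
    idw_k: int = 4
    idw_power: float = 2.0
    write_netcdf: bool = True

    def __post_init__(self) -> None:
        if "historical" not in self.periods:
            raise ConfigurationError("periods must include 'historical'")
        hist = self.periods["historical"]
        if (hist[0], hist[1]) != (self.synthetic.start_year, self.synthetic.end_year):
            raise ConfigurationError(
                "historical period must match the synthetic start/end years"
            )
        if not self.models:
            raise ConfigurationError("at least one model required")
        if not self.scenarios:
            raise ConfigurationError("at least one scenario required")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file; ``synthetic.seed`` is
    mandatory."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    syn_raw = dict(raw.get("synthetic", {}))
    if "seed" not in syn_raw:
        raise ConfigurationError("config must set synthetic.seed")
    if "bbox" in syn_raw:
        syn_raw["bbox"] = tuple(syn_raw["bbox"])
    synthetic = SyntheticConfig(**syn_raw)
    kwargs: dict = {"synthetic": synthetic}
    if "models" in raw:
        kwargs["models"] = [ModelSpec(**m) for m in raw["models"]]
    if "scenarios" in raw:
        kwargs["scenarios"] = {str(k): float(v) for k, v in raw["scenarios"].items()}
    if "periods" in raw:
        kwargs["periods"] = {
            str(k): (int(v[0]), int(v[1])) for k, v in raw["periods"].items()
        }
    for key in (
        "min_duration",
        "window_halfwidth",
        "percentile",
        "alpha",
        "rr",
        "rr_low",
        "rr_high",
        "raster_indices",
        "raster_cell_size",
        "idw_k",
        "idw_power",
        "write_netcdf",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable sha256 of the canonicalized configuration."""
    d = asdict(cfg)
    d["synthetic"]["bbox"] = list(d["synthetic"]["bbox"])
    d["periods"] = {k: list(v) for k, v in d["periods"].items()}
    blob = yaml.safe_dump(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
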