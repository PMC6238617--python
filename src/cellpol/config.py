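"""Run configuration: the pipeline's tunable parameters, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .image_ops import DEFAULT_BACKGROUND_RADIUS_UM, DEFAULT_BAND, FilterBand
from .synthetic import DEFAULT_PIXEL_SIZE_UM

__all__ = ["RunConfig", "load_config", "default_config_path"]

CONFIG_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters, with published constants as defaults."""

    pixel_size: float | None = None  # μm/px; None = take from image metadata
    cell_radius: float | None = None  # μm; None = nucleus equal-area radius
    band_low: float = DEFAULT_BAND.low_scale  # μm
    band_high: float = DEFAULT_BAND.high_scale  # μm
    background_radius: float = DEFAULT_BACKGROUND_RADIUS_UM  # μm
    otsu_bins: int = 256
    min_cluster_area: int = 4  # px
    connectivity: int = 8
    channel_roles: dict[str, str] = field(
        default_factory=lambda: {
            "nucleus": "nucleus",
            "compartment_a": "puncta",
            "compartment_b": "puncta_2",
        }
    )
    coloc_regression: str = "orthogonal"
    coloc_mask_shape: str = "circle"
    coloc_padding: float = 0.0  # μm
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.pixel_size is not None and not self.pixel_size > 0:
            raise ConfigError("pixel_size must be > 0")
        if self.cell_radius is not None and not self.cell_radius > 0:
            raise ConfigError("cell_radius must be > 0")
        for name in ("band_low", "band_high", "background_radius"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if not self.band_low < self.band_high:
            raise ConfigError("band_low must be < band_high")
        if self.otsu_bins < 2:
            raise ConfigError("otsu_bins must be ≥ 2")
        if self.min_cluster_area < 1:
            raise ConfigError("min_cluster_area must be ≥ 1")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        for role in ("nucleus", "compartment_a"):
            if role not in self.channel_roles:
                raise ConfigError(f"channel_roles must define {role!r}")

    @property
    def band(self) -> FilterBand:
        return FilterBand(self.band_low, self.band_high)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        version = data.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported config schema version {version} "
                f"(expected {CONFIG_SCHEMA_VERSION})"
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def default_config_path() -> Path:
    """Path of the shipped default configuration file."""
    return Path(str(resources.files("cellpol").joinpath("data/default_config.yaml")))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; with no path, load the shipped defaults."""
    path = Path(path) if path is not None else default_config_path()
    try:
        data = yaml.safe_load(path.read_text())
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return RunConfig.from_dict(data)
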