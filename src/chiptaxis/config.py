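"""Flat YAML run configuration with strict parsing.

One flat key/value file parameterizes a whole run. Unknown keys are
rejected (a typo must fail loudly, not fall back to a default), and the
fully-resolved configuration — every default materialized — is echoed into
each output directory so a run is reproducible from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .geometry import DeviceGeometry
from .quantify import QuantConfig


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Forward-solver and estimator settings."""

    dx_um: float | None = None          # None -> L/104
    dt_h: float | None = None           # None -> largest stable step
    n_bins: int = 26
    estimator: str = "likelihood"       # for D; chi is always likelihood
    min_cells: int = 30
    bootstrap_reps: int = 0
    chi_max: float | None = None        # None -> 10 * D * L
    fit_time_h: float | None = None     # None -> latest common timepoint


@dataclass(frozen=True)
class SimulationConfig:
    """Synthetic-data generation settings (the emulated study conditions)."""

    n_luminal: int = 30
    n_extravasated: int = 40
    n_recruited: int = 30
    snr: float = 10.0
    n_cells: int = 5000
    times_h: tuple[float, ...] = (24.0, 48.0)
    dt_h: float = 0.01
    D_um2_per_h: float = 1000.0
    chi_um2_per_h: float = 13000.0


@dataclass(frozen=True)
class RunConfig:
    geometry: DeviceGeometry = DeviceGeometry()
    image: QuantConfig = QuantConfig()
    model: ModelConfig = ModelConfig()
    simulation: SimulationConfig = SimulationConfig()
    seed: int = 0

    def to_flat_dict(self) -> dict:
        flat: dict = {"seed": self.seed}
        for prefix, obj in (
            ("geometry", self.geometry),
            ("image", self.image),
            ("model", self.model),
            ("simulation", self.simulation),
        ):
            for f in dataclasses.fields(obj):
                value = getattr(obj, f.name)
                if isinstance(value, tuple):
                    value = list(value)
                flat[f"{prefix}.{f.name}"] = value
        return flat


_SECTIONS = {
    "geometry": DeviceGeometry,
    "image": QuantConfig,
    "model": ModelConfig,
    "simulation": SimulationConfig,
}


def load_config(path: str | Path | None) -> RunConfig:
    """Load a flat ``section.key: value`` YAML file; missing file -> defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a flat mapping, got {type(raw).__name__}")

    by_section: dict[str, dict] = {name: {} for name in _SECTIONS}
    seed = 0
    for key, value in raw.items():
        if key == "seed":
            seed = int(value)
            continue
        if "." not in key:
            raise ConfigError(f"invalid config key: {key!r}")
        section, _, field_name = key.partition(".")
        cls = _SECTIONS.get(section)
        if cls is None:
            raise ConfigError(f"invalid config key: {key!r} (unknown section)")
        valid = {f.name for f in dataclasses.fields(cls)}
        if field_name not in valid:
            raise ConfigError(f"invalid config key: {key!r} (unknown field)")
        if isinstance(value, list):
            value = tuple(value)
        by_section[section][field_name] = value

    try:
        return RunConfig(
            geometry=DeviceGeometry(**by_section["geometry"]),
            image=QuantConfig(**by_section["image"]),
            model=ModelConfig(**by_section["model"]),
            simulation=SimulationConfig(**by_section["simulation"]),
            seed=seed,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def echo_config(config: RunConfig, out_dir: str | Path) -> Path:
    """Write the fully-resolved flat config into the output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.yaml"
    path.write_text(yaml.safe_dump(config.to_flat_dict(), sort_keys=True))
    return path
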