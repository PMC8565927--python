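"""Run configuration: validated parameter blocks for the pipeline commands.

Configurations are YAML files validated against pydantic models (unknown
keys are rejected); command-line flags override file values.  Every run
writes a manifest echoing the resolved configuration, the package version
and the seed, which suffices to reproduce the run.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "RunConfig",
    "load_config",
    "write_manifest",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid run configuration (message names the offending key)."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CableConstantsConfig(_Block):
    diameter_um: float = 0.47
    Rm: float = 20000.0
    Ri: float = 150.0
    Cm: float = 0.9
    frequency_hz: float = 1000.0


class ModelConfig(_Block):
    """Morphology + passive-property block shared by simulation commands."""

    swc_path: str | None = None
    soma_diameter: float = 8.0
    n_dendrites: int = 1
    dendrite_length: float = 90.0
    dendrite_diameter: float = 0.47
    branches_per_dendrite: int = 1
    node_spacing: float = 1.0
    Rm: float = 20000.0
    Ri: float = 150.0
    Cm: float = 0.9
    E_leak: float = -70.0
    max_compartment_length: float = 1.0


class SynapseConfig(_Block):
    tau0: float = 0.073
    tau1: float = 0.26
    gmax: float = 0.004
    E_rev: float = 0.0


class ClampConfig(_Block):
    hold: float = -70.0
    dt: float = 0.005
    duration: float = 10.0
    series_resistance: float = 0.0


class SweepConfig(_Block):
    distances: list[float] = Field(
        default_factory=lambda: [float(d) for d in range(0, 91, 10)]
    )


class PPRConfig(_Block):
    conductance_ratio: float = 2.25
    interval: float = 20.0
    distance: float = 0.0


class IOCurveConfig(_Block):
    quanta: list[float] = Field(
        default_factory=lambda: [1.0, 2.0, 5.0, 10.0, 15.0, 20.0]
    )
    distance: float = 0.0
    reference_quanta: float = 0.1
    dt: float = 0.01
    duration: float = 30.0


class SublinearityConfig(_Block):
    soma_distance: float = 0.0
    dendrite_distance: float = 45.0


class WeightsConfig(_Block):
    bin_width: float = 10.0
    relative_frequency: list[float] = Field(
        default_factory=lambda: [0.3, 0.3, 0.2, 0.1, 0.1]
    )


class MappingConfig(_Block):
    """Defaults for background statistics match the synthetic spot
    generator's intensity scale; set them from measured background regions
    when mapping real spot tables."""

    puncta_path: str | None = None
    swc_path: str | None = None
    psf_xyz: tuple[float, float, float] = (0.3, 0.3, 1.1)
    background_mean: float = 100.0
    background_sd: float = 10.0
    alpha: float = 0.2
    resample_step: float = 0.1
    bin_width: float = 10.0
    cumulative_step: float = 1.0


class EventsConfig(_Block):
    trace_path: str | None = None
    threshold_sd: float = 4.0
    min_interval: float = 2.0


class SyntheticConfig(_Block):
    stage: Literal["immature", "adult"] = "immature"
    puncta_density: float = 0.46
    decoy_fraction: float = 0.2
    recording_duration_s: float = 10.0


class RunConfig(_Block):
    """Top-level run configuration: global seed, output dir, verbosity and
    one optional block per command."""

    seed: int = 0
    output_dir: str = "stellate_out"
    verbosity: Literal["quiet", "info", "debug"] = "info"
    cable_constants: CableConstantsConfig = Field(default_factory=CableConstantsConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    synapse: SynapseConfig = Field(default_factory=SynapseConfig)
    clamp: ClampConfig = Field(default_factory=ClampConfig)
    sweep: SweepConfig = Field(default_factory=SweepConfig)
    ppr: PPRConfig = Field(default_factory=PPRConfig)
    io_curve: IOCurveConfig = Field(default_factory=IOCurveConfig)
    sublinearity: SublinearityConfig = Field(default_factory=SublinearityConfig)
    weights: WeightsConfig = Field(default_factory=WeightsConfig)
    mapping: MappingConfig = Field(default_factory=MappingConfig)
    events: EventsConfig = Field(default_factory=EventsConfig)
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML configuration file and apply flag overrides.

    ``overrides`` maps dotted keys ('clamp.dt') to values.  Unknown keys
    raise :class:`ConfigError` naming the key.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for dotted, value in (overrides or {}).items():
        parts = dotted.split(".")
        d = data
        for p in parts[:-1]:
            d = d.setdefault(p, {})
        d[parts[-1]] = value
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        err = exc.errors()[0]
        key = ".".join(str(p) for p in err["loc"])
        raise ConfigError(f"invalid configuration key '{key}': {err['msg']}") from None


def write_manifest(out_dir: str | Path, command: str, cfg: RunConfig) -> Path:
    """Write the run manifest (resolved config + version) as JSON."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package": "stellate",
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(cfg.model_dump_json()),
    }
    path = out / f"manifest_{command.replace('-', '_')}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
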