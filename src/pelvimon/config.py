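"""Structured run configuration with documented defaults.

A :class:`RunConfig` bundles every tunable of the pipeline — tissue circuit,
recruitment tuning, contraction kinetics, electrode setup, stimulation
protocol, measurement chain and analysis thresholds — plus the single
global seed.  The defaults reproduce the reference run: 3 x (30 s
stimulation at 15 mA / 1000 us / 30 Hz at the vesicouterine ligament +
120 s rest), four needle electrodes on the bladder, quadrature (version
two) demodulation.  Unknown keys anywhere in a config file are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .analog_frontend import ChainConfig
from .errors import ConfigError
from .stimulation import StimulationProtocol, default_protocol
from .tissue_sim import (
    ContractionConfig,
    ElectrodeSetup,
    RecruitmentParams,
    SETUP_REGISTRY,
    TissueElectricalModel,
)


@dataclass(frozen=True)
class ProtocolConfig:
    """Parametric form of the repeated stim/rest protocol."""

    amplitude_ma: float = 15.0
    frequency_hz: float = 30.0
    pulse_width_us: float = 1000.0
    n_cycles: int = 3
    stim_s: float = 30.0
    rest_s: float = 120.0
    site: str = "vesicouterine_ligament"

    def build(self) -> StimulationProtocol:
        return default_protocol(
            amplitude_ma=self.amplitude_ma,
            frequency_hz=self.frequency_hz,
            pulse_width_us=self.pulse_width_us,
            n_cycles=self.n_cycles,
            stim_s=self.stim_s,
            rest_s=self.rest_s,
            site=self.site,
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-stage parameters."""

    baseline_s: float = 5.0          # baseline window length before first stim
    detection_k: float = 5.0         # threshold in baseline-noise sigmas
    min_event_s: float = 2.0
    merge_gap_s: float = 1.0
    artifact_slope_factor: float = 10.0  # x max physiological slope
    demod_version: str = "v2"        # "v1" | "v2"
    manometry_fill_ml: float = 150.0
    manometry_gain: float = 0.3
    manometry_noise_rms: float = 0.003
    store_raw: bool = False

    def __post_init__(self) -> None:
        if self.demod_version not in ("v1", "v2"):
            raise ConfigError("demod_version must be 'v1' or 'v2'")
        if self.baseline_s <= 0:
            raise ConfigError("baseline_s must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Complete, seeded description of one pipeline run."""

    tissue: TissueElectricalModel = field(default_factory=TissueElectricalModel)
    recruitment: RecruitmentParams = field(default_factory=RecruitmentParams)
    contraction: ContractionConfig = field(default_factory=ContractionConfig)
    setup: ElectrodeSetup = field(default_factory=lambda: SETUP_REGISTRY["bladder_setup2"])
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    chain: ChainConfig = field(default_factory=ChainConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    control_rate_hz: float = 100.0
    seed: int = 1
    outdir: Optional[str] = None


_SECTION_TYPES = {
    "tissue": TissueElectricalModel,
    "recruitment": RecruitmentParams,
    "contraction": ContractionConfig,
    "setup": ElectrodeSetup,
    "protocol": ProtocolConfig,
    "chain": ChainConfig,
    "analysis": AnalysisConfig,
}
_SCALAR_KEYS = {"control_rate_hz", "seed", "outdir"}


def _build_section(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown keys in section {section!r}: {sorted(unknown)}; "
            f"expected subset of {sorted(names)}"
        )
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    """Build a :class:`RunConfig` from nested dictionaries, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - set(_SECTION_TYPES) - _SCALAR_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            section = data[name]
            if name == "setup" and isinstance(section, str):
                if section not in SETUP_REGISTRY:
                    raise ConfigError(
                        f"unknown electrode setup {section!r}; "
                        f"expected one of {sorted(SETUP_REGISTRY)}"
                    )
                kwargs[name] = SETUP_REGISTRY[section]
                continue
            if not isinstance(section, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, section, name)
    for key in _SCALAR_KEYS:
        if key in data:
            kwargs[key] = data[key]
    return RunConfig(**kwargs)


def config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
    return path
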