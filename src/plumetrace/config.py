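"""Run configuration: a flat YAML file with four sections plus a seed.

Every field has a documented default reproducing the published measurement
design (three voltages 3.5/4.5/5.5 kV, four 1-mm probe slabs at 0.6–4.6 mm,
delays 0–500 ns in 50-ns steps, ~20-shot averaging).  Unknown keys are
rejected by name; out-of-range values raise errors naming the key.
Interfaces use the measurement's units — ns, mm, kV — converted once at the
boundary to the strict-SI internals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import yaml

from .constants import KV, MM, NS
from .kinematics import InstrumentConfig
from .plume import TE_SHAPES, PlumeModel, ScenarioGrid
from .species import get_species

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration problem, naming the offending key."""


@dataclass
class SpeciesPlumeConfig:
    species: str = "(CHCA)H+"
    tE_mean_ns: float = 46.0
    tE_sd_ns: float = 11.0
    tE_shape: str = "gaussian_truncated_at_zero"
    v0_mean: float = 500.0
    v0_sd: float = 150.0


@dataclass
class InstrumentSection:
    voltage_kV: list = dc_field(default_factory=lambda: [3.5, 4.5, 5.5])
    gap_mm: float = 4500.0 / 3.54e5 / MM  # 12.712 mm, from the 4.5 kV pair
    drift_m: float = 1.0
    bin_ns: float = 10.0


@dataclass
class PlumeSection:
    species: list = dc_field(
        default_factory=lambda: [
            SpeciesPlumeConfig("(CHCA)H+", 46.0, 11.0),
            SpeciesPlumeConfig("(CHCA)2H+", 64.0, 12.0),
        ]
    )
    ions_per_shot: int = 5000
    shots_per_spectrum: int = 20


@dataclass
class ProbeSection:
    slabs_mm: list = dc_field(
        default_factory=lambda: [[0.6 + i, 1.6 + i] for i in range(4)]
    )
    delays_ns: list = dc_field(default_factory=lambda: [50.0 * i for i in range(11)])
    dissociation_prob: float = 1.0
    jitter_ns: float = 0.0


@dataclass
class AnalysisSection:
    min_depth: float = 0.15
    min_width_bins: int = 3
    center_tolerance: float = 0.5
    baseline_floor: float = 0.01
    v0_assumed: float = 500.0
    hist_bin_ns: float = 10.0
    tE_window_ns: list = dc_field(default_factory=lambda: [0.0, 250.0])
    v0_window: list = dc_field(default_factory=lambda: [0.0, 1500.0])


@dataclass
class RunConfig:
    """The full effective configuration of a pipeline run."""

    instrument: InstrumentSection = dc_field(default_factory=InstrumentSection)
    plume: PlumeSection = dc_field(default_factory=PlumeSection)
    probe: ProbeSection = dc_field(default_factory=ProbeSection)
    analysis: AnalysisSection = dc_field(default_factory=AnalysisSection)
    seed: int = 1

    # -- derived objects ----------------------------------------------------
    def instrument_template(self) -> InstrumentConfig:
        return InstrumentConfig(
            voltage=self.instrument.voltage_kV[0] * KV,
            gap=self.instrument.gap_mm * MM,
            drift_length=self.instrument.drift_m,
            bin_width=self.instrument.bin_ns * NS,
        )

    def plume_models(self) -> list:
        return [
            PlumeModel(
                species=get_species(s.species),
                tE_mean=s.tE_mean_ns * NS,
                tE_sd=s.tE_sd_ns * NS,
                v0_mean=s.v0_mean,
                v0_sd=s.v0_sd,
                ions_per_shot=self.plume.ions_per_shot,
                tE_shape=s.tE_shape,
            )
            for s in self.plume.species
        ]

    def scenario_grid(self, seed: int | None = None) -> ScenarioGrid:
        return ScenarioGrid(
            slabs=tuple((s[0] * MM, s[1] * MM) for s in self.probe.slabs_mm),
            delays=tuple(d * NS for d in self.probe.delays_ns),
            voltages=tuple(v * KV for v in self.instrument.voltage_kV),
            shots_per_spectrum=self.plume.shots_per_spectrum,
            seed=self.seed if seed is None else seed,
        )

    def scan_kwargs(self) -> dict:
        a = self.analysis
        return {
            "min_depth": a.min_depth,
            "min_width_bins": a.min_width_bins,
            "center_tolerance": a.center_tolerance,
            "baseline_floor": a.baseline_floor,
            "te_range": tuple(t * NS for t in a.tE_window_ns),
            "v0_range": tuple(a.v0_window),
        }

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable sha256 of the effective configuration (12 hex chars)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        from . import __version__

        return {
            "config": self.to_dict(),
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "package_version": __version__,
        }


_SECTION_TYPES = {
    "instrument": InstrumentSection,
    "plume": PlumeSection,
    "probe": ProbeSection,
    "analysis": AnalysisSection,
}


def _build_section(name: str, cls, data: dict):
    defaults = cls()
    known = set(vars(defaults))
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{name}': {sorted(unknown)}"
        )
    for key, value in data.items():
        default = getattr(defaults, key)
        if key == "species" and name == "plume":
            value = [_build_species(v) for v in value]
        elif isinstance(default, float):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"wrong type for '{name}.{key}': expected a number")
            value = float(value)
        elif isinstance(default, int):
            if not isinstance(value, int) or isinstance(value, bool):
                raise ConfigError(f"wrong type for '{name}.{key}': expected an integer")
        elif isinstance(default, list):
            if not isinstance(value, list):
                raise ConfigError(f"wrong type for '{name}.{key}': expected a list")
        elif isinstance(default, str):
            if not isinstance(value, str):
                raise ConfigError(f"wrong type for '{name}.{key}': expected a string")
        setattr(defaults, key, value)
    _validate_section(name, defaults)
    return defaults


def _build_species(data: dict) -> SpeciesPlumeConfig:
    if not isinstance(data, dict):
        raise ConfigError(f"plume.species entries must be mappings, got {data!r}")
    known = set(vars(SpeciesPlumeConfig()))
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in plume.species entry: {sorted(unknown)}")
    out = SpeciesPlumeConfig(**data)
    if out.tE_mean_ns < 0 or out.tE_sd_ns < 0:
        raise ConfigError("plume.species tE_mean_ns/tE_sd_ns must be >= 0")
    if out.tE_shape not in TE_SHAPES:
        raise ConfigError(f"plume.species tE_shape must be one of {TE_SHAPES}")
    return out


def _validate_section(name: str, section) -> None:
    if name == "instrument":
        if not section.voltage_kV or any(v <= 0 for v in section.voltage_kV):
            raise ConfigError("instrument.voltage_kV must be positive and non-empty")
        for key in ("gap_mm", "drift_m", "bin_ns"):
            if getattr(section, key) <= 0:
                raise ConfigError(f"instrument.{key} must be > 0")
    elif name == "plume":
        if section.ions_per_shot < 1:
            raise ConfigError("plume.ions_per_shot must be >= 1")
        if section.shots_per_spectrum < 1:
            raise ConfigError("plume.shots_per_spectrum must be >= 1")
    elif name == "probe":
        for slab in section.slabs_mm:
            if len(slab) != 2 or slab[1] <= slab[0]:
                raise ConfigError(
                    f"probe.slabs_mm entry {slab} must be [low, high] with high > low"
                )
        if sorted(section.delays_ns) != list(section.delays_ns):
            raise ConfigError("probe.delays_ns must be sorted ascending")
        if not 0.0 <= section.dissociation_prob <= 1.0:
            raise ConfigError("probe.dissociation_prob must be in [0, 1]")
    elif name == "analysis":
        if not 0.0 < section.min_depth <= 1.0:
            raise ConfigError("analysis.min_depth must be in (0, 1]")
        if section.min_width_bins < 1:
            raise ConfigError("analysis.min_width_bins must be >= 1")
        if section.center_tolerance <= 0:
            raise ConfigError("analysis.center_tolerance must be > 0")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; an empty or missing file yields all defaults.

    Raises
    ------
    ConfigError
        For unknown keys, wrong types or out-of-range values, naming the key.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded)}")
        data = loaded
    unknown = set(data) - set(_SECTION_TYPES) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    sections = {
        name: _build_section(name, cls, data.get(name, {}) or {})
        for name, cls in _SECTION_TYPES.items()
    }
    seed = data.get("seed", 1)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")
    return RunConfig(seed=seed, **sections)
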