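"""Scenario configuration: schema, validation and YAML round-trip.

A scenario file has the nested sections ``physiology``, ``strains``,
``environment``, ``heat_shock``, ``engine``, ``init`` and (optionally)
``toggles``.  Every dimensioned quantity carries an explicit unit tag
(``"0.15 /h"``, ``"15 pg"``); unknown keys are rejected with an itemized
report and every defaulted key is logged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import (BATCH, CHEMOSTAT, AgentManagerConfig, ChemostatState,
                     HeatShockSchedule)
from .exceptions import ConfigurationError
from .params import (PHYSIOLOGY_DIMENSIONS, STRAIN_DIMENSIONS,
                     HeterogeneityToggles, PhysiologyParams, StrainParams)
from .units import format_quantity, parse_quantity


@dataclass
class EnvSettings:
    mode: str = CHEMOSTAT
    D: float = 0.15          # h^-1
    G_in: float = 1.0        # g L^-1
    V: float = 1e-5          # L

    def __post_init__(self):
        # delegate range checks to ChemostatState
        ChemostatState(G=self.G_in, G_in=self.G_in, D=self.D, V=self.V,
                       mode=self.mode)


@dataclass
class EngineSettings:
    dt: float = 0.05         # h
    duration: float = 120.0  # h
    N_min: int = 300
    N_max: int = 800
    record_every: float = 1.0  # h
    snapshot_every: float | None = None   # per-agent dumps are opt-in
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.duration <= 0 or self.record_every <= 0:
            raise ConfigurationError("dt, duration, record_every must be > 0")
        if self.snapshot_every is not None and self.snapshot_every <= 0:
            raise ConfigurationError("snapshot_every must be > 0 when set")
        AgentManagerConfig(self.N_min, self.N_max)


@dataclass
class InitSettings:
    cells_per_strain: int = 2000
    agents_per_strain: int = 50
    G0: float | None = None   # initial glucose; defaults to G_in

    def __post_init__(self):
        if self.cells_per_strain < self.agents_per_strain or \
                self.agents_per_strain < 1:
            raise ConfigurationError(
                "need agents_per_strain >= 1 and cells_per_strain >= "
                "agents_per_strain")


@dataclass
class ScenarioConfig:
    phys: PhysiologyParams = field(default_factory=PhysiologyParams)
    strains: list = field(default_factory=lambda: [StrainParams()])
    env: EnvSettings = field(default_factory=EnvSettings)
    schedule: HeatShockSchedule = field(default_factory=HeatShockSchedule)
    engine: EngineSettings = field(default_factory=EngineSettings)
    init: InitSettings = field(default_factory=InitSettings)
    toggles: HeterogeneityToggles = field(
        default_factory=HeterogeneityToggles)

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)


_ENV_DIMENSIONS = {"mode": "str", "D": "rate", "G_in": "mass_conc",
                   "V": "volume"}
_SCHEDULE_DIMENSIONS = {"H_a": "dimensionless", "F_h": "rate",
                        "phase_offset": "time", "mode": "str",
                        "times": "time_list"}
_ENGINE_DIMENSIONS = {"dt": "time", "duration": "time",
                      "N_min": "int", "N_max": "int",
                      "record_every": "time", "snapshot_every": "time",
                      "seed": "int"}
_INIT_DIMENSIONS = {"cells_per_strain": "int", "agents_per_strain": "int",
                    "G0": "mass_conc"}

_SECTIONS = ("physiology", "strains", "environment", "heat_shock", "engine",
             "init", "toggles")

#: keys that are legitimately absent (None-able or mode-dependent)
_OPTIONAL_KEYS = {"init": ("G0",), "engine": ("snapshot_every",),
                  "heat_shock": ("times",)}


def validate_config(source) -> tuple[ScenarioConfig, list[str]]:
    """Build a fully-typed :class:`ScenarioConfig` from a path, YAML string
    or dict.  Returns ``(config, report)`` where the report lists every
    default substitution.  Raises :class:`ConfigurationError` with an
    itemized problem list on any unknown key, missing unit or bad range."""
    raw = _load(source)
    problems: list[str] = []
    report: list[str] = []
    for key in raw:
        if key not in _SECTIONS:
            problems.append(f"unknown top-level section {key!r}")

    phys = _parse_block(raw.get("physiology", {}), PHYSIOLOGY_DIMENSIONS,
                        "physiology", problems, report)
    env = _parse_block(raw.get("environment", {}), _ENV_DIMENSIONS,
                       "environment", problems, report)
    schedule = _parse_block(raw.get("heat_shock", {}), _SCHEDULE_DIMENSIONS,
                            "heat_shock", problems, report)
    engine = _parse_block(raw.get("engine", {}), _ENGINE_DIMENSIONS,
                          "engine", problems, report)
    init = _parse_block(raw.get("init", {}), _INIT_DIMENSIONS, "init",
                        problems, report)

    strains_raw = raw.get("strains", [{}])
    if not isinstance(strains_raw, list) or not strains_raw:
        problems.append("strains must be a non-empty list")
        strains_raw = [{}]
    strains = [_parse_block(s, STRAIN_DIMENSIONS, f"strains[{i}]",
                            problems, report)
               for i, s in enumerate(strains_raw)]

    toggles_raw = raw.get("toggles", {})
    toggle_fields = {f.name for f in
                     dataclasses.fields(HeterogeneityToggles)}
    for key, val in dict(toggles_raw).items():
        if key not in toggle_fields:
            problems.append(f"toggles: unknown flag {key!r}")
        elif not isinstance(val, bool):
            problems.append(f"toggles.{key}: must be a boolean")

    if problems:
        raise ConfigurationError(problems)

    try:
        cfg = ScenarioConfig(
            phys=PhysiologyParams(**phys),
            strains=[StrainParams(**s) for s in strains],
            env=EnvSettings(**env),
            schedule=HeatShockSchedule(**_tuplify(schedule)),
            engine=EngineSettings(**engine),
            init=InitSettings(**init),
            toggles=HeterogeneityToggles(
                **{k: v for k, v in toggles_raw.items()}),
        )
    except ConfigurationError:
        raise
    except TypeError as exc:
        raise ConfigurationError([str(exc)]) from exc
    return cfg, report


def config_to_dict(cfg: ScenarioConfig) -> dict:
    """Emit a unit-tagged dict that round-trips losslessly through
    :func:`validate_config`."""
    def block(obj, dims):
        out = {}
        for name, dim in dims.items():
            val = getattr(obj, name)
            if val is None:
                continue
            if dim in ("str", "int"):
                out[name] = val
            elif dim == "time_list":
                out[name] = [format_quantity(t, "time") for t in val]
            else:
                out[name] = format_quantity(val, dim)
        return out

    return {
        "physiology": block(cfg.phys, PHYSIOLOGY_DIMENSIONS),
        "strains": [block(s, STRAIN_DIMENSIONS) for s in cfg.strains],
        "environment": block(cfg.env, _ENV_DIMENSIONS),
        "heat_shock": block(cfg.schedule, _SCHEDULE_DIMENSIONS),
        "engine": block(cfg.engine, _ENGINE_DIMENSIONS),
        "init": block(cfg.init, _INIT_DIMENSIONS),
        "toggles": dataclasses.asdict(cfg.toggles),
    }


def save_config(cfg: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg),
                                         sort_keys=False))


def default_config() -> ScenarioConfig:
    """The shipped default scenario: one wild-type-like strain in a
    glucose-limited chemostat at D = 0.15 h^-1, no heat shocks."""
    return ScenarioConfig()


# ----------------------------------------------------------------------

def _load(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    text = Path(source).read_text() if _is_path(source) else str(source)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError("config must be a YAML mapping")
    return data


def _is_path(source) -> bool:
    if isinstance(source, Path):
        return True
    return isinstance(source, str) and "\n" not in source and \
        (source.endswith((".yaml", ".yml")) or Path(source).exists())


def _parse_block(raw, dims, section, problems, report) -> dict:
    out = {}
    if not isinstance(raw, dict):
        problems.append(f"{section}: must be a mapping")
        return out
    for key, value in raw.items():
        if key not in dims:
            problems.append(f"{section}: unknown key {key!r}")
            continue
        dim = dims[key]
        try:
            if dim == "str":
                out[key] = str(value)
            elif dim == "int":
                if isinstance(value, bool) or not isinstance(value, int):
                    raise ConfigurationError(
                        f"{section}.{key}: expected an integer")
                out[key] = value
            elif dim == "time_list":
                out[key] = [parse_quantity(v, "time", f"{section}.{key}")
                            for v in value]
            else:
                out[key] = parse_quantity(value, dim, f"{section}.{key}")
        except ConfigurationError as exc:
            problems.extend(exc.problems)
    for key in dims:
        if key not in out and key not in _OPTIONAL_KEYS.get(section, ()):
            report.append(f"{section}.{key}: using default")
    return out


def _tuplify(schedule_kwargs: dict) -> dict:
    if "times" in schedule_kwargs:
        schedule_kwargs = dict(schedule_kwargs,
                               times=tuple(schedule_kwargs["times"]))
    return schedule_kwargs
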