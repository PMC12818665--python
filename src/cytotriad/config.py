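"""Run configuration: YAML/JSON loading with strict key checking."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import DEFAULT_INITIAL_STATE, ParameterSet, validate_parameters
from .simulate import BolusEvent, InterventionSchedule, ParameterModulation

__all__ = ["RunConfig", "load_config", "dump_config"]

_TOP_KEYS = {"parameters", "initial_state", "t_end", "dt", "schedule",
             "sweep", "sensitivity", "seed"}
_SCHEDULE_KEYS = {"boluses", "modulations"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run settings; defaults are the reference study conditions."""

    parameters: ParameterSet = field(default_factory=ParameterSet)
    initial_state: tuple[float, float, float] = DEFAULT_INITIAL_STATE
    t_end: float = 72.0
    dt: float = 0.01
    schedule: InterventionSchedule = field(default_factory=InterventionSchedule)
    sweep: dict = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        validate_parameters(self.parameters)
        if not (self.t_end > 0):
            raise ValueError("t_end must be > 0")
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        if len(self.initial_state) != 3 or any(c < 0 for c in self.initial_state):
            raise ValueError("initial_state must be 3 nonnegative concentrations")


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {', '.join(unknown)}")


def _parse_schedule(raw: dict) -> InterventionSchedule:
    _check_keys(raw, _SCHEDULE_KEYS, "schedule")
    boluses = tuple(
        BolusEvent(time=float(b["time"]), species=str(b["species"]),
                   amount=float(b["amount"]))
        for b in raw.get("boluses", ()))
    modulations = tuple(
        ParameterModulation(parameter=str(m["parameter"]), factor=float(m["factor"]),
                            start=float(m["start"]), end=float(m["end"]))
        for m in raw.get("modulations", ()))
    return InterventionSchedule(boluses=boluses, modulations=modulations)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON) run configuration.

    Omitted fields take the reference defaults; unknown keys anywhere are an
    error so that typos (e.g. ``gamma_t10``) cannot silently fall back to a
    default.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, str(path))
    kwargs: dict = {}
    if "parameters" in raw:
        kwargs["parameters"] = ParameterSet.from_dict(raw["parameters"] or {})
    if "initial_state" in raw:
        kwargs["initial_state"] = tuple(float(c) for c in raw["initial_state"])
    for key in ("t_end", "dt"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "schedule" in raw:
        kwargs["schedule"] = _parse_schedule(raw["schedule"] or {})
    for key in ("sweep", "sensitivity"):
        if key in raw:
            kwargs[key] = dict(raw[key] or {})
    if "seed" in raw and raw["seed"] is not None:
        kwargs["seed"] = int(raw["seed"])
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a config so that ``load_config`` round-trips it."""
    raw = {
        "parameters": config.parameters.to_dict(),
        "initial_state": list(config.initial_state),
        "t_end": config.t_end,
        "dt": config.dt,
        "schedule": {
            "boluses": [{"time": b.time, "species": b.species, "amount": b.amount}
                        for b in config.schedule.boluses],
            "modulations": [{"parameter": m.parameter, "factor": m.factor,
                             "start": m.start, "end": m.end}
                            for m in config.schedule.modulations],
        },
        "sweep": config.sweep,
        "sensitivity": config.sensitivity,
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
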