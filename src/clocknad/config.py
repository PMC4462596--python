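"""YAML run configuration: fixture selection, parameter overrides, forcing
schedule, solver settings and variant flags.

Example::

    fixture: current
    overrides:
      VNADc: 1.311975      # 25% of the shipped value
    t_end: 480
    solver: {rtol: 1.0e-8, atol: 1.0e-10, step: 0.05}
    variant: {tf_sirt1_release: true, nampt_acetylation_gain: true}
    schedule:
      - {type: pulse, target: kPARP, start: 130, duration: 2, amplitude: 20}
      - {type: square_wave, target: Dex, high: 0.125, low: 0,
         on_duration: 12, off_duration: 12, phase_offset: 0}

Validation collects *every* problem before failing, so a config with three
mistakes produces three messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from .forcing import ForcingSchedule, Pulse, ScheduleError, SquareWave
from .model import ModelVariant
from .parameters import (
    FIXTURE_NAMES,
    PARAM_NAMES,
    ModelParameters,
    ModelState,
    NamedFixture,
    load_fixture,
)
from .simulate import SolverSettings


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


@dataclass
class RunConfig:
    """A fully validated run configuration."""

    fixture_name: str
    parameters: ModelParameters
    initial_state: ModelState
    schedule: ForcingSchedule
    solver: SolverSettings
    variant: ModelVariant
    t_end: float
    raw: dict = field(default_factory=dict)


_PULSE_KEYS = {"type", "target", "start", "duration", "amplitude"}
_WAVE_KEYS = {"type", "target", "high", "low", "on_duration", "off_duration",
              "phase_offset"}
_TOP_KEYS = {"fixture", "overrides", "schedule", "solver", "variant", "t_end"}


def _build_schedule(entries: Any, errors: list[str]) -> ForcingSchedule:
    if entries is None:
        return ForcingSchedule()
    if not isinstance(entries, list):
        errors.append("schedule: must be a list of entries")
        return ForcingSchedule()
    built = []
    for i, entry in enumerate(entries):
        loc = f"schedule[{i}]"
        if not isinstance(entry, dict):
            errors.append(f"{loc}: must be a mapping")
            continue
        kind = entry.get("type", "pulse")
        try:
            if kind == "pulse":
                extra = set(entry) - _PULSE_KEYS
                if extra:
                    raise ScheduleError(f"unknown keys {sorted(extra)}")
                built.append(Pulse(entry["target"], float(entry["start"]),
                                   float(entry["duration"]), float(entry["amplitude"])))
            elif kind == "square_wave":
                extra = set(entry) - _WAVE_KEYS
                if extra:
                    raise ScheduleError(f"unknown keys {sorted(extra)}")
                built.append(SquareWave(entry["target"], float(entry["high"]),
                                        float(entry["low"]),
                                        float(entry["on_duration"]),
                                        float(entry["off_duration"]),
                                        float(entry.get("phase_offset", 0.0))))
            else:
                raise ScheduleError(f"unknown entry type {kind!r}")
        except (ScheduleError, KeyError, TypeError, ValueError) as exc:
            errors.append(f"{loc}: {exc}")
    try:
        return ForcingSchedule(built)
    except ScheduleError as exc:
        errors.append(f"schedule: {exc}")
        return ForcingSchedule()


def validate_config(data: dict) -> tuple[Optional[RunConfig], list[str]]:
    """Validate a parsed config mapping; returns (config-or-None, errors)."""
    errors: list[str] = []
    if not isinstance(data, dict):
        return None, ["configuration root must be a mapping"]
    extra = set(data) - _TOP_KEYS
    if extra:
        errors.append(f"unknown top-level keys: {sorted(extra)}")

    fixture_name = data.get("fixture", "current")
    if fixture_name not in FIXTURE_NAMES:
        errors.append(f"fixture: unknown name {fixture_name!r}; expected one of {FIXTURE_NAMES}")
        fixture_name = "current"
    fixture = load_fixture(fixture_name)

    params = fixture.parameters
    overrides = data.get("overrides") or {}
    if not isinstance(overrides, dict):
        errors.append("overrides: must be a mapping of parameter name to value")
    else:
        for key, value in overrides.items():
            if key not in PARAM_NAMES:
                errors.append(f"overrides.{key}: unknown parameter name")
            elif not isinstance(value, (int, float)) or value < 0:
                errors.append(f"overrides.{key}: negative rate or non-numeric value {value!r}")
        valid = {k: v for k, v in overrides.items()
                 if k in PARAM_NAMES and isinstance(v, (int, float)) and v >= 0}
        if valid:
            params = params.replace(**valid)

    schedule = _build_schedule(data.get("schedule"), errors)

    solver_data = data.get("solver") or {}
    try:
        solver = SolverSettings(**solver_data)
    except (TypeError, ValueError) as exc:
        errors.append(f"solver: {exc}")
        solver = SolverSettings()

    variant_data = data.get("variant") or {}
    try:
        variant = ModelVariant(**variant_data)
    except TypeError as exc:
        errors.append(f"variant: {exc}")
        variant = ModelVariant()

    t_end = data.get("t_end", 480.0)
    if not isinstance(t_end, (int, float)) or t_end <= 0:
        errors.append(f"t_end: must be a positive number, got {t_end!r}")
        t_end = 480.0

    if errors:
        return None, errors
    return RunConfig(fixture_name=fixture_name, parameters=params,
                     initial_state=fixture.initial_state, schedule=schedule,
                     solver=solver, variant=variant, t_end=float(t_end),
                     raw=data), []


def parse_config(path) -> RunConfig:
    """Load and validate a YAML config file; raises :class:`ConfigError`
    listing every problem found."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    config, errors = validate_config(data)
    if errors:
        raise ConfigError(errors)
    return config
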