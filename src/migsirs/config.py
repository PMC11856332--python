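"""Run configuration: a validated, serializable bundle of everything a run
needs — scenario, parameter overrides, horizon, grids, tolerances, output."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import (
    ConfigFileError,
    ConfigSyntaxError,
    ConfigValidationError,
    ValidationError,
)
from .model import ModelParams
from .scenarios import SCENARIOS, get_scenario

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Fully validated description of one run.

    ``overrides`` are applied on top of the named scenario's parameters and
    re-checked against every model invariant before anything executes.
    """

    scenario: str = "baseline"
    overrides: dict = field(default_factory=dict)
    years: Optional[int] = None  # None -> the scenario's own horizon
    record_every: int = 1
    outdir: str = "migsirs-out"
    grid: str = "reduced"  # "reduced" or "default" sweep grids
    delta_I_mult: float = 4.0  # delta_I as a multiple of delta_S (sweeps)
    nu1_range: tuple = (0.0, 0.5)
    tol: float = 1e-3  # bisection tolerance on nu1
    rtol: float = 1e-8
    atol: float = 1e-10
    early_stop_tol: Optional[float] = None
    plot: bool = False

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigValidationError(
                f"unknown scenario {self.scenario!r}; available: {sorted(SCENARIOS)}"
            )
        try:
            self.build_params()
        except (ValidationError, TypeError) as exc:
            raise ConfigValidationError(str(exc)) from exc
        if self.years is not None and self.years < 1:
            raise ConfigValidationError("years must be >= 1")
        if self.record_every < 1:
            raise ConfigValidationError("record_every must be >= 1")
        if self.grid not in ("reduced", "default"):
            raise ConfigValidationError("grid must be 'reduced' or 'default'")

    def build_params(self) -> ModelParams:
        base = get_scenario(self.scenario).params
        if not self.overrides:
            return base
        merged = base.to_dict()
        unknown = set(self.overrides) - set(merged)
        if unknown:
            raise ConfigValidationError(
                f"unknown override key(s): {sorted(unknown)}"
            )
        merged.update(self.overrides)
        try:
            return ModelParams.from_dict(merged)
        except ValidationError as exc:
            # re-raise with the config vocabulary ("T1+T2" etc. kept intact)
            raise ConfigValidationError(str(exc)) from exc

    def horizon(self) -> int:
        return self.years if self.years is not None else get_scenario(self.scenario).years

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["nu1_range"] = list(self.nu1_range)
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Raises :class:`ConfigFileError` for a missing/unreadable file,
    :class:`ConfigSyntaxError` for malformed YAML, and
    :class:`ConfigValidationError` for unknown keys or invariant violations
    (each message names the offending key).
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigFileError(f"cannot read config file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigSyntaxError(f"malformed YAML in {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigSyntaxError(f"config root must be a mapping, got {type(data)}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigValidationError(f"unknown config key(s): {sorted(unknown)}")
    if "nu1_range" in data:
        data["nu1_range"] = tuple(data["nu1_range"])
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigValidationError(str(exc)) from exc
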