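"""Named parameter sets and initial conditions for every standard setup.

All scenarios are deterministic and need no external input: the default
parameterization, the degenerate SI / SIR / SIS / disease-free limits, and
a desk-scale sweep grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .model import ModelParams, N_COMPARTMENTS, StateVector

__all__ = [
    "Scenario",
    "baseline",
    "limit_scenario",
    "reduced_grid",
    "default_grid",
    "SCENARIOS",
    "SIS_MU",
]

DEFAULT_YEARS = 2000

#: Finite stand-in for the mu -> infinity SIS limit: mean immune residence
#: 1/20 year, far below every other time scale in the model.
SIS_MU = 20.0


@dataclass(frozen=True)
class Scenario:
    name: str
    description: str
    params: ModelParams
    initial: StateVector
    years: int = DEFAULT_YEARS

    def __post_init__(self):
        if np.any(np.asarray(self.initial) < 0):
            raise ValidationError("initial state components must be non-negative")


def _uniform_initial(count: float = 100.0) -> np.ndarray:
    """The standard start: `count` individuals in each of the 10 classes."""
    return np.full(N_COMPARTMENTS, float(count))


def baseline() -> Scenario:
    """Default parameterization: delta_I = 4*delta_S, nu1 = 0.14, mu = 0 (SIR)."""
    params = ModelParams(
        delta_S=0.001, delta_R=0.001, delta_I=0.004, nu1=0.14, mu=0.0
    )
    return Scenario(
        name="baseline",
        description="default constants; migratory culling delta_I=4*delta_S, "
        "nu1=0.14, nu2=0.26, mu=0",
        params=params,
        initial=_uniform_initial(),
    )


def limit_scenario(kind: str) -> Scenario:
    """Degenerate limits of the SIRS structure.

    - ``SI``: no recovery (nu1 = nu2 = 0) -- infection is for life.
    - ``SIR``: no immunity loss (mu = 0) -- recovery is permanent.
    - ``SIS``: fast immunity loss (mu = 20) -- the resistant class is a
      negligible transient, approximating direct I -> S recovery.
    - ``disease_free``: default rates but no infected or resistant hosts
      at the start; the pathogen can never appear.
    """
    base = baseline()
    if kind == "SI":
        params = base.params.replace(nu1=0.0, nu2=0.0)
        return Scenario("SI", "no recovery: nu1=nu2=0", params, base.initial)
    if kind == "SIR":
        params = base.params.replace(mu=0.0)
        return Scenario("SIR", "permanent immunity: mu=0", params, base.initial)
    if kind == "SIS":
        params = base.params.replace(mu=SIS_MU)
        return Scenario(
            "SIS", f"fast immunity loss: mu={SIS_MU}", params, base.initial
        )
    if kind == "disease_free":
        initial = np.zeros(N_COMPARTMENTS)
        initial[0] = initial[5] = 100.0  # Sr, Sm only
        return Scenario(
            "disease_free", "susceptibles only; no pathogen", base.params, initial
        )
    raise ValidationError(
        f"unknown limit scenario {kind!r}; "
        "expected one of SI, SIR, SIS, disease_free"
    )


def default_grid():
    """Full sweep grids: mu in [0, 1] step 0.1, nu1 in [0, 0.5] step 0.05,
    delta_I in {1, 2, 4, 8} x delta_S."""
    mu_values = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    nu1_values = np.round(np.arange(0.0, 0.5 + 1e-9, 0.05), 10)
    delta_I_values = 0.001 * np.array([1.0, 2.0, 4.0, 8.0])
    return mu_values, nu1_values, delta_I_values


def reduced_grid():
    """Desk-scale 6x6 grid spanning the full ranges, delta_I in {1,4,8}*delta_S."""
    mu_values = np.round(np.linspace(0.0, 1.0, 6), 10)
    nu1_values = np.round(np.linspace(0.0, 0.5, 6), 10)
    delta_I_values = 0.001 * np.array([1.0, 4.0, 8.0])
    return mu_values, nu1_values, delta_I_values


SCENARIOS = {
    "baseline": baseline,
    "SI": lambda: limit_scenario("SI"),
    "SIR": lambda: limit_scenario("SIR"),
    "SIS": lambda: limit_scenario("SIS"),
    "disease_free": lambda: limit_scenario("disease_free"),
}


def get_scenario(name: str) -> Scenario:
    try:
        return SCENARIOS[name]()
    except KeyError:
        raise ValidationError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
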