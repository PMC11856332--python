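"""Annual-cycle simulator.

Each simulated year is the composition

    integrate shared-habitat season (length T1)
    -> migration mortality pulse
    -> integrate separate-habitat season (length T2)
    -> migration mortality pulse

iterated for the full horizon (2000 years by default).  The smooth
within-season dynamics are integrated with an adaptive explicit
Runge-Kutta scheme; the pulses are applied between integrations, so no
event detection is needed.  The model is fully deterministic.

Batched runs: a state of shape ``(10, K)`` paired with array-valued
``mu``/``nu1``/``nu2``/``delta_*`` parameters advances K independent
parameter sets in one integration, which is how the sweep module keeps
phase maps cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError, ValidationError
from .model import (
    ModelParams,
    N_COMPARTMENTS,
    STATE_FIELDS,
    StateVector,
    rhs_separate_habitats,
    rhs_shared_habitat,
)

__all__ = ["Trajectory", "integrate_interval", "step_one_year", "run_simulation"]

#: integrator defaults: the seasonal fields are smooth and non-stiff at the
#: default parameter scales, so a 4th/5th-order explicit pair suffices.
RTOL = 1e-8
ATOL = 1e-10

#: negative excursions larger than this are treated as solver failure
#: rather than round-off, and raise instead of being clamped.
CLAMP_TOL = 1e-8

_FIELDS = {"shared": rhs_shared_habitat, "separate": rhs_separate_habitats}


@dataclass
class Trajectory:
    """Yearly-sampled state history of one (possibly batched) simulation.

    ``states[j]`` is the state at the end of year ``years[j]`` (after the
    second migration pulse); ``years[0] == 0`` holds the initial condition.
    ``converged_year`` is set when an (optional) steady-state early stop
    fired, and None otherwise.
    """

    years: np.ndarray
    states: np.ndarray  # (n_samples, 10) or (n_samples, 10, K)
    params: ModelParams
    converged_year: Optional[int] = None

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.states = np.asarray(self.states, dtype=float)
        if len(self.years) != len(self.states):
            raise ValidationError("years and states must have equal length")

    @property
    def final_state(self) -> StateVector:
        return self.states[-1]

    def to_dataframe(self) -> pd.DataFrame:
        if self.states.ndim != 2:
            raise ValidationError("CSV export is defined for unbatched trajectories")
        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "year", self.years)
        return df

    def to_csv(self, path, params_path=None) -> None:
        """Write the trajectory table; optionally a sidecar parameter file."""
        self.to_dataframe().to_csv(path, index=False)
        if params_path is not None:
            self.params.to_yaml(params_path)

    @classmethod
    def from_csv(cls, path, params: ModelParams) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["year"].to_numpy(), df[list(STATE_FIELDS)].to_numpy(), params)


def _clamp(y: np.ndarray, context: str) -> np.ndarray:
    """Zero out integrator round-off negatives; fail loudly on real ones."""
    worst = y.min()
    if worst < -CLAMP_TOL:
        raise IntegrationError(
            f"state went negative ({worst:.3e}) during {context}; "
            "this exceeds round-off and indicates solver failure"
        )
    return np.maximum(y, 0.0)


def integrate_interval(
    state: StateVector,
    field: str,
    duration: float,
    params: ModelParams,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> StateVector:
    """Advance ``state`` by ``duration`` years under one seasonal field.

    ``field`` is ``"shared"`` or ``"separate"``.  Works on ``(10,)`` or
    batched ``(10, K)`` states.
    """
    if duration <= 0:
        raise ValidationError(f"duration must be positive, got {duration}")
    try:
        rhs = _FIELDS[field]
    except KeyError:
        raise ValidationError(f"field must be one of {sorted(_FIELDS)}, got {field!r}")
    y0 = np.asarray(state, dtype=float)
    shape = y0.shape

    def fun(t, y):
        return rhs(y.reshape(shape), params).ravel()

    sol = solve_ivp(
        fun, (0.0, duration), y0.ravel(), method="RK45", rtol=rtol, atol=atol
    )
    if not sol.success:
        raise IntegrationError(
            f"solver failed during {field} season: {sol.message}", params
        )
    return _clamp(sol.y[:, -1].reshape(shape), f"{field} season")


def step_one_year(
    state: StateVector,
    params: ModelParams,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> StateVector:
    """One annual cycle: shared season, pulse, separate season, pulse."""
    from .model import apply_migration_pulse

    y = integrate_interval(state, "shared", params.T1, params, rtol, atol)
    y = apply_migration_pulse(y, params)
    y = integrate_interval(y, "separate", params.T2, params, rtol, atol)
    return apply_migration_pulse(y, params)


def run_simulation(
    initial: StateVector,
    params: ModelParams,
    years: int,
    record_every: int = 1,
    early_stop_tol: Optional[float] = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Iterate the annual map for ``years`` cycles and record the history.

    Parameters
    ----------
    initial:
        Starting state, shape ``(10,)`` or ``(10, K)``.
    years:
        Number of annual cycles (>= 1).
    record_every:
        Sampling stride in years; year 0 and the final year are always kept.
    early_stop_tol:
        If given, stop once the year-over-year change satisfies
        ``max |y' - y| / (1 + |y|) < early_stop_tol`` (for batched runs, in
        every batch member); the stopping year is stored as
        ``converged_year``.  Leave as None for replication-grade runs: the
        full horizon is then always simulated.
    """
    if years < 1:
        raise ValidationError(f"years must be >= 1, got {years}")
    if record_every < 1:
        raise ValidationError(f"record_every must be >= 1, got {record_every}")
    y = np.asarray(initial, dtype=float)
    if y.shape[0] != N_COMPARTMENTS:
        raise ValidationError(f"state must have {N_COMPARTMENTS} compartments")
    if np.any(y < 0):
        raise ValidationError("initial state must be non-negative")

    recorded_years = [0]
    recorded = [y.copy()]
    converged_year = None
    for year in range(1, years + 1):
        y_next = step_one_year(y, params, rtol, atol)
        if year % record_every == 0 or year == years:
            recorded_years.append(year)
            recorded.append(y_next.copy())
        if early_stop_tol is not None:
            change = np.abs(y_next - y) / (1.0 + np.abs(y))
            if change.max() < early_stop_tol:
                converged_year = year
                if recorded_years[-1] != year:
                    recorded_years.append(year)
                    recorded.append(y_next.copy())
                y = y_next
                break
        y = y_next
    return Trajectory(
        np.array(recorded_years), np.stack(recorded), params, converged_year
    )
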