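"""Parameter sweeps: phase maps over (mu, nu1) and winner-transition boundaries.

A phase map runs the three-strain competition to its end state in every
cell of an immunity-loss x recovery-rate grid and colors the cell by the
winning strain.  Transition curves locate, per mu, the recovery rate nu1
at which the winner switches from strain 1 to 2 and from 2 to 3, by
bisection on the winner index.

Grid cells are independent by contract; internally all cells of a map (and
all active bisection brackets) advance together as one batched integration,
which is what keeps full sweeps tractable on one core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import ModelParams, N_COMPARTMENTS
from .outcomes import host_strategy_dominance, winning_strain
from .simulate import run_simulation

__all__ = ["PhaseMap", "TransitionCurve", "phase_map", "transition_boundaries"]

log = logging.getLogger(__name__)

DEFAULT_YEARS = 2000

#: nu2 tracks nu1 during sweeps with this migratory-recovery offset
#: unless the base parameters say otherwise.
_DEFAULT_INITIAL_PER_CLASS = 100.0


@dataclass
class PhaseMap:
    """Winner (1-3, or 0 for extinct) and migrant dominance per grid cell.

    ``winners[i, j]`` corresponds to ``nu1_values[i]`` and ``mu_values[j]``.
    """

    mu_values: np.ndarray
    nu1_values: np.ndarray
    delta_I: float
    winners: np.ndarray
    migrants_dominate: np.ndarray

    def __post_init__(self):
        expected = (len(self.nu1_values), len(self.mu_values))
        if self.winners.shape != expected:
            raise ValidationError(
                f"winners must have shape {expected}, got {self.winners.shape}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, nu1 in enumerate(self.nu1_values):
            for j, mu in enumerate(self.mu_values):
                w = int(self.winners[i, j])
                rows.append(
                    {
                        "mu": mu,
                        "nu1": nu1,
                        "delta_I": self.delta_I,
                        "winner": w if w else "extinct",
                        "migrants_dominate": bool(self.migrants_dominate[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path, params_path=None, params: ModelParams = None) -> None:
        self.to_dataframe().to_csv(path, index=False)
        if params_path is not None and params is not None:
            params.to_yaml(params_path)


@dataclass
class TransitionCurve:
    """Per-mu recovery-rate thresholds where the winning strain changes.

    NaN marks "no such transition inside the searched nu1 range".
    """

    delta_I: float
    mu_values: np.ndarray
    nu1_at_1to2: np.ndarray
    nu1_at_2to3: np.ndarray

    def __post_init__(self):
        both = np.isfinite(self.nu1_at_1to2) & np.isfinite(self.nu1_at_2to3)
        if np.any(self.nu1_at_1to2[both] > self.nu1_at_2to3[both] + 1e-12):
            raise ValidationError("1->2 threshold above 2->3 threshold")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mu": self.mu_values,
                "delta_I": self.delta_I,
                "nu1_at_1to2": self.nu1_at_1to2,
                "nu1_at_2to3": self.nu1_at_2to3,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _nu2_offset(base: ModelParams) -> float:
    return float(np.asarray(base.nu2) - np.asarray(base.nu1))


def _batch_outcomes(
    mu: np.ndarray,
    nu1: np.ndarray,
    delta_I: float,
    base: ModelParams,
    years: int,
    early_stop_tol: Optional[float],
):
    """Run the competition in every (mu, nu1) cell of a flat batch.

    Returns (winners, migrants_dominate, converged_year); nu2 follows nu1
    with the base parameters' migratory-recovery offset.
    """
    mu = np.asarray(mu, dtype=float)
    nu1 = np.asarray(nu1, dtype=float)
    params = base.replace(mu=mu, nu1=nu1, nu2=nu1 + _nu2_offset(base), delta_I=delta_I)
    initial = np.full((N_COMPARTMENTS, len(mu)), _DEFAULT_INITIAL_PER_CLASS)
    traj = run_simulation(
        initial, params, years=years, record_every=years, early_stop_tol=early_stop_tol
    )
    final = traj.final_state
    return (
        np.atleast_1d(winning_strain(final)),
        np.atleast_1d(host_strategy_dominance(final)),
        traj.converged_year,
    )


def phase_map(
    mu_values,
    nu1_values,
    delta_I: float,
    base: ModelParams = None,
    years: int = DEFAULT_YEARS,
    early_stop_tol: Optional[float] = None,
) -> PhaseMap:
    """Winning strain and migrant dominance over a (mu, nu1) grid.

    Every cell starts from the standard 100-per-class initial condition and
    uses ``nu2 = nu1 + 0.12`` (or the base parameters' own offset).
    """
    base = base if base is not None else ModelParams()
    mu_values = np.asarray(mu_values, dtype=float)
    nu1_values = np.asarray(nu1_values, dtype=float)
    for name, g in (("mu_values", mu_values), ("nu1_values", nu1_values)):
        if g.size == 0:
            raise ValidationError(f"{name} must be non-empty")
        if g.size > 1 and np.any(np.diff(g) <= 0):
            raise ValidationError(f"{name} must be strictly increasing")
    nn, mm = np.meshgrid(nu1_values, mu_values, indexing="ij")
    winners, dominate, _ = _batch_outcomes(
        mm.ravel(), nn.ravel(), delta_I, base, years, early_stop_tol
    )
    shape = (len(nu1_values), len(mu_values))
    return PhaseMap(
        mu_values=mu_values,
        nu1_values=nu1_values,
        delta_I=float(delta_I),
        winners=winners.reshape(shape),
        migrants_dominate=dominate.reshape(shape),
    )


def transition_boundaries(
    mu_values,
    delta_I: float,
    nu1_range=(0.0, 0.5),
    base: ModelParams = None,
    tol: float = 1e-3,
    years: int = DEFAULT_YEARS,
    early_stop_tol: Optional[float] = None,
    prescan_points: int = 6,
    winner_fn: Optional[Callable] = None,
) -> TransitionCurve:
    """Locate, per mu, the smallest nu1 where the winner reaches strain 2
    and strain 3, by bisection to within ``tol``.

    A coarse prescan over ``nu1_range`` verifies that the winner index is
    non-decreasing in nu1 (re-scanning three times denser, with a warning,
    if not) and brackets each transition; brackets across all mu values and
    both transitions are then bisected together in batched runs.

    ``winner_fn(mu_array, nu1_array) -> int array`` may be injected to
    replace the simulation-backed winner evaluation (used for cheap
    contract tests).
    """
    base = base if base is not None else ModelParams()
    mu_values = np.asarray(mu_values, dtype=float)
    lo_r, hi_r = float(nu1_range[0]), float(nu1_range[1])
    if not hi_r > lo_r:
        raise ValidationError("nu1_range must be a positive-length interval")
    if tol <= 0:
        raise ValidationError("tol must be positive")

    if winner_fn is None:

        def winner_fn(mu_arr, nu1_arr):
            w, _, _ = _batch_outcomes(
                mu_arr, nu1_arr, delta_I, base, years, early_stop_tol
            )
            return w

    def scan(points: int) -> np.ndarray:
        grid = np.linspace(lo_r, hi_r, points)
        mm, nn = np.meshgrid(mu_values, grid, indexing="ij")
        w = winner_fn(mm.ravel(), nn.ravel()).reshape(len(mu_values), points)
        return grid, w

    grid, winners = scan(prescan_points)
    monotone = np.all(np.diff(winners, axis=1) >= 0, axis=1)
    if not monotone.all():
        log.warning(
            "winner not monotone in nu1 for mu=%s; re-scanning densely",
            mu_values[~monotone],
        )
        grid, winners = scan(3 * prescan_points)

    n_mu = len(mu_values)
    levels = (2, 3)  # smallest nu1 with winner >= level
    lo = np.full((len(levels), n_mu), np.nan)
    hi = np.full((len(levels), n_mu), np.nan)
    for li, level in enumerate(levels):
        for j in range(n_mu):
            above = winners[j] >= level
            if not above.any() or above[0]:
                continue  # never crosses, or already crossed at range start
            k = int(np.argmax(above))
            lo[li, j] = grid[k - 1]
            hi[li, j] = grid[k]

    active = np.isfinite(lo)
    while True:
        widths = np.where(active, hi - lo, 0.0)
        work = active & (widths > tol)
        if not work.any():
            break
        li_idx, j_idx = np.nonzero(work)
        mids = 0.5 * (lo[work] + hi[work])
        w_mid = winner_fn(mu_values[j_idx], mids)
        for n, (li, j) in enumerate(zip(li_idx, j_idx)):
            if w_mid[n] >= levels[li]:
                hi[li, j] = mids[n]
            else:
                lo[li, j] = mids[n]

    threshold = 0.5 * (lo + hi)
    # the two bisections are independent; enforce the ordering invariant
    # (estimates can cross by up to tol when the transitions nearly coincide)
    both = np.isfinite(threshold[0]) & np.isfinite(threshold[1])
    threshold[0, both] = np.fmin(threshold[0, both], threshold[1, both])
    return TransitionCurve(
        delta_I=float(delta_I),
        mu_values=mu_values,
        nu1_at_1to2=threshold[0],
        nu1_at_2to3=threshold[1],
    )
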