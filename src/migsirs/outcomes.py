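"""Simulation outcome measures: winning strain and migrant/resident dominance.

The three pathogen strains compete from equal initial footholds; the
"winning" strategy is the strain whose pooled infected compartments
(residents + migrants) form the largest share of the final population.
Competitive exclusion usually drives the two losers to effectively zero.
Host-strategy dominance simply asks whether migrants or residents are more
numerous at the end of the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import ValidationError
from .model import StateVector, total_population
from .simulate import Trajectory

__all__ = [
    "EXTINCTION_THRESHOLD",
    "SimulationOutcome",
    "strain_totals",
    "winning_strain",
    "host_strategy_dominance",
    "summarize_outcome",
]

#: A strain whose final pooled total falls below this count is treated as
#: absent.  Continuous densities never reach exact zero, so "population
#: sizes that are ~0" needs a cutoff; 1e-6 individuals is far below any
#: biologically meaningful density at the model's scales.
EXTINCTION_THRESHOLD = 1e-6

#: Winner code for "no strain above threshold".
EXTINCT = 0

_IR = slice(1, 4)
_IM = slice(6, 9)
_MIGRANTS = slice(5, 10)
_RESIDENTS = slice(0, 5)


def strain_totals(state: StateVector) -> np.ndarray:
    """Pooled infected count per strain, ``Iri + Imi``; shape (3,) or (3, K)."""
    y = np.asarray(state, dtype=float)
    return y[_IR] + y[_IM]


def winning_strain(
    final: StateVector, threshold: float = EXTINCTION_THRESHOLD
) -> Union[int, np.ndarray]:
    """Index (1-3) of the most abundant strain, or 0 ("extinct") if none
    exceeds ``threshold``.  Ties break toward the less virulent strain.

    For a batched ``(10, K)`` state, returns an int array of shape (K,).
    """
    if threshold < 0:
        raise ValidationError("threshold must be non-negative")
    totals = strain_totals(final)
    # argmax takes the first maximum, which is the lower strain index
    winner = np.argmax(totals, axis=0) + 1
    winner = np.where(totals.max(axis=0) > threshold, winner, EXTINCT)
    return int(winner) if winner.ndim == 0 else winner


def host_strategy_dominance(final: StateVector) -> Union[bool, np.ndarray]:
    """True where migrants strictly outnumber residents (ties -> residents)."""
    y = np.asarray(final, dtype=float)
    migrants = y[_MIGRANTS].sum(axis=0)
    residents = y[_RESIDENTS].sum(axis=0)
    dominate = migrants > residents
    return bool(dominate) if np.ndim(dominate) == 0 else dominate


@dataclass(frozen=True)
class SimulationOutcome:
    """End-of-run summary of a single (unbatched) simulation."""

    winner: Union[int, str]  # 1, 2, 3 or "extinct"
    strain_totals: tuple  # (total1, total2, total3)
    migrant_total: float
    resident_total: float
    migrants_dominate: bool
    final_N: float

    def to_row(self, params) -> dict:
        """One flat CSV row keyed by the swept parameters."""
        return {
            "mu": float(np.asarray(params.mu)),
            "nu1": float(np.asarray(params.nu1)),
            "delta_I": float(np.asarray(params.delta_I)),
            "winner": self.winner,
            "strain1_total": self.strain_totals[0],
            "strain2_total": self.strain_totals[1],
            "strain3_total": self.strain_totals[2],
            "migrant_total": self.migrant_total,
            "resident_total": self.resident_total,
            "migrants_dominate": self.migrants_dominate,
        }


def summarize_outcome(
    traj: Trajectory, threshold: float = EXTINCTION_THRESHOLD
) -> SimulationOutcome:
    """Outcome measures evaluated on the final recorded state."""
    if len(traj.states) == 0:
        raise ValidationError("cannot summarize an empty trajectory")
    final = traj.final_state
    if final.ndim != 1:
        raise ValidationError("summarize_outcome expects an unbatched trajectory")
    totals = strain_totals(final)
    code = winning_strain(final, threshold)
    y = np.asarray(final)
    return SimulationOutcome(
        winner=code if code != EXTINCT else "extinct",
        strain_totals=tuple(float(t) for t in totals),
        migrant_total=float(y[_MIGRANTS].sum()),
        resident_total=float(y[_RESIDENTS].sum()),
        migrants_dominate=host_strategy_dominance(final),
        final_N=float(total_population(final)),
    )
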