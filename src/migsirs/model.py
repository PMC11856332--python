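"""Core model: parameters, state layout, seasonal vector fields, migration pulse.

The model tracks a partially migratory host population attacked by three
competing pathogen strains of increasing virulence.  Hosts are split into
residents (stay in Habitat 1 year-round) and migrants (spend the fraction
``T1`` of each year in Habitat 1 with the residents, and the fraction ``T2``
in Habitat 2 on their own).  Each host group has five compartments --
susceptible (S), infected with strain 1, 2 or 3 (I1..I3), and resistant (R)
-- for 10 compartments total.

Epidemiology is SIRS: susceptibles are infected at strain-specific
transmission rate ``beta_i``, infecteds recover into the resistant class at
a habitat-dependent rate (``nu1`` in Habitat 1, ``nu2 > nu1`` for migrants
in Habitat 2, i.e. "migratory recovery"), and resistant hosts lose immunity
back to susceptible at rate ``mu``.  ``mu = 0`` gives an SIR model; large
``mu`` approaches SIS.  Strain virulence ``alpha_i`` (disease-induced
mortality) buys transmission through a saturating trade-off curve
``beta(alpha)``, concave down so that each extra unit of virulence buys
less transmission than the last.

Reproduction happens only in the shared season and is density-dependent
through the factor ``(1 - gamma*N)`` with ``N`` the total population across
both host groups, giving a fecundity-based carrying capacity of
``1/gamma``.  Twice a year -- on departure from and return to Habitat 1 --
migrants pay a per-trip mortality toll: the S, I and R migrant classes are
scaled by ``1 - delta_S``, ``1 - delta_I`` and ``1 - delta_R``
("migratory culling" when ``delta_I`` exceeds the others).

All rates are per year; one simulated year has length 1, split into a
shared-habitat season of length ``T1`` and a separate-habitat season of
length ``T2`` with ``T1 + T2 = 1``.

States are plain ``numpy`` arrays of shape ``(10,)`` -- or ``(10, K)`` for
``K`` independent parameter sets run in a batch -- ordered as
``Sr, Ir1, Ir2, Ir3, Rr, Sm, Im1, Im2, Im3, Rm``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import yaml

from .errors import ValidationError

__all__ = [
    "STATE_FIELDS",
    "N_COMPARTMENTS",
    "TRADEOFF_FORMS",
    "ModelParams",
    "StateVector",
    "make_state",
    "state_to_dict",
    "transmission_rate",
    "total_population",
    "carrying_capacity",
    "rhs_shared_habitat",
    "rhs_separate_habitats",
    "apply_migration_pulse",
]

#: Compartment order used by every array in the package.
STATE_FIELDS = ("Sr", "Ir1", "Ir2", "Ir3", "Rr", "Sm", "Im1", "Im2", "Im3", "Rm")
N_COMPARTMENTS = len(STATE_FIELDS)

# index helpers (module-private; the slices cover the three strains)
_SR, _RR, _SM, _RM = 0, 4, 5, 9
_IR = slice(1, 4)
_IM = slice(6, 9)

TRADEOFF_FORMS = ("concave_sqrt", "ratio", "linear")

#: A model state: float array of shape (10,) or (10, K), all entries >= 0.
StateVector = np.ndarray

Scalar = Union[float, np.ndarray]


def _asarray(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class ModelParams:
    """All model constants.

    ``mu``, ``nu1``, ``nu2`` and the three ``delta`` costs may be scalars or
    1-D arrays of a common length ``K``; array-valued parameters let a whole
    sweep run as one batched integration.  Everything else is scalar.

    Parameters
    ----------
    T1, T2:
        Fractions of the year spent together / apart; must sum to 1.
    b:
        Density-independent birth rate (per year).
    d:
        Pathogen-independent mortality rate (per year).
    alpha:
        Strictly increasing disease-induced mortality rates of the three
        strains (per year).
    sigma:
        Disease-induced fecundity cost, added (signed) to ``b`` for
        infected parents.
    gamma:
        Density-dependence strength (per individual); carrying capacity is
        ``1/gamma``.
    delta_S, delta_I, delta_R:
        Per-migration-event mortality fractions in ``[0, 1)``.
    mu:
        Immunity-loss rate (per year); 0 gives SIR, large values approach SIS.
    nu1, nu2:
        Recovery rates in Habitat 1 and Habitat 2.  ``nu2=None`` applies the
        default rule ``nu2 = nu1 + 0.12`` (migratory recovery).
    cA, cB:
        Trade-off constants of the ``beta(alpha)`` curve.
    tradeoff_form:
        One of ``"concave_sqrt"`` (default), ``"ratio"``, ``"linear"``.
    """

    T1: float = 0.5
    T2: float = 0.5
    b: float = 2.0
    d: float = 0.14
    alpha: tuple = (0.01, 0.05, 0.1)
    sigma: float = -0.02
    gamma: float = 0.0001
    delta_S: Scalar = 0.001
    delta_I: Scalar = 0.004
    delta_R: Scalar = 0.001
    mu: Scalar = 0.0
    nu1: Scalar = 0.14
    nu2: Scalar = None
    cA: float = 0.005
    cB: float = 0.14
    tradeoff_form: str = "concave_sqrt"

    #: default migratory-recovery boost applied when nu2 is not given
    NU2_OFFSET = 0.12

    def __post_init__(self):
        if self.nu2 is None:
            object.__setattr__(self, "nu2", _asarray(self.nu1) + self.NU2_OFFSET)
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        self.validate()

    def validate(self) -> None:
        if abs(self.T1 + self.T2 - 1.0) > 1e-12:
            raise ValidationError(
                f"T1+T2 must equal 1, got T1={self.T1}, T2={self.T2}"
            )
        if not (0 < self.T1 < 1):
            raise ValidationError(f"T1 must lie in (0, 1), got {self.T1}")
        if len(self.alpha) != 3:
            raise ValidationError("alpha must hold exactly three strain virulences")
        if not (self.alpha[0] < self.alpha[1] < self.alpha[2]):
            raise ValidationError(f"alpha must be strictly increasing, got {self.alpha}")
        for name in ("b", "d", "cA", "cB", "gamma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.alpha[0] < 0:
            raise ValidationError("alpha rates must be non-negative")
        for name in ("mu", "nu1", "nu2"):
            if np.any(_asarray(getattr(self, name)) < 0):
                raise ValidationError(f"{name} must be non-negative")
        for name in ("delta_S", "delta_I", "delta_R"):
            v = _asarray(getattr(self, name))
            if np.any(v < 0) or np.any(v >= 1):
                raise ValidationError(f"{name} must lie in [0, 1)")
        if self.tradeoff_form not in TRADEOFF_FORMS:
            raise ValidationError(
                f"unknown tradeoff_form {self.tradeoff_form!r}; "
                f"expected one of {TRADEOFF_FORMS}"
            )

    # -- derived quantities -------------------------------------------------

    def beta(self) -> np.ndarray:
        """Transmission rates of the three strains, shape (3,)."""
        return transmission_rate(np.asarray(self.alpha), self)

    @property
    def batch_size(self) -> int:
        """Common length of array-valued parameters (1 when all scalar)."""
        k = 1
        for name in ("mu", "nu1", "nu2", "delta_S", "delta_I", "delta_R"):
            v = _asarray(getattr(self, name))
            if v.ndim > 0:
                if k not in (1, v.shape[0]) or v.ndim > 1:
                    raise ValidationError("array parameters must share one length")
                k = v.shape[0]
        return k

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields changed (re-validated)."""
        if "nu1" in changes and "nu2" not in changes:
            changes.setdefault("nu2", None)
        return dataclasses.replace(self, **changes)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, tuple):
                v = list(v)
            elif isinstance(v, np.floating):
                v = float(v)
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown parameter key(s): {sorted(unknown)}")
        clean = {
            k: tuple(v) if k == "alpha" else (np.asarray(v, float) if isinstance(v, list) else v)
            for k, v in data.items()
        }
        return cls(**clean)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_state(**counts) -> StateVector:
    """Build a state array from named compartment counts; others default to 0.

    >>> make_state(Sr=100.0, Im1=5.0)[0]
    100.0
    """
    unknown = set(counts) - set(STATE_FIELDS)
    if unknown:
        raise ValidationError(f"unknown compartment(s): {sorted(unknown)}")
    y = np.zeros(N_COMPARTMENTS)
    for name, v in counts.items():
        if v < 0:
            raise ValidationError(f"compartment {name} must be non-negative")
        y[STATE_FIELDS.index(name)] = float(v)
    return y


def state_to_dict(state: StateVector) -> dict:
    return {name: float(v) for name, v in zip(STATE_FIELDS, np.asarray(state))}


def transmission_rate(alpha_i, params: ModelParams):
    """Transmission rate ``beta_i`` bought by virulence ``alpha_i``.

    The default ``concave_sqrt`` form ``cA * sqrt(cB + alpha)`` is strictly
    increasing and concave down in ``alpha``: more virulent strains transmit
    faster, with diminishing returns.  The alternative forms ``ratio``
    (``cA / (cB + alpha)``, decreasing) and ``linear`` (``cA*cB + alpha``)
    are provided for sensitivity analysis only.
    """
    a = _asarray(alpha_i)
    if np.any(a < 0):
        raise ValidationError(f"alpha must be non-negative, got {alpha_i}")
    if params.cA < 0 or params.cB < 0:
        raise ValidationError("trade-off constants cA, cB must be non-negative")
    form = params.tradeoff_form
    if form == "concave_sqrt":
        return params.cA * np.sqrt(params.cB + a)
    if form == "ratio":
        return params.cA / (params.cB + a)
    if form == "linear":
        return params.cA * params.cB + a
    raise ValidationError(f"unknown tradeoff_form {form!r}")


def total_population(state: StateVector):
    """Total host count N across all 10 compartments (scalar or (K,))."""
    return _asarray(state).sum(axis=0)


def carrying_capacity(params: ModelParams) -> float:
    """Population size at which the density-dependent birth factor hits zero."""
    if params.gamma <= 0:
        raise ValidationError("carrying capacity requires gamma > 0")
    return 1.0 / params.gamma


def _cols(v: np.ndarray, batched: bool) -> np.ndarray:
    """Reshape a (3,) strain vector to broadcast against (3, K) pools."""
    return v[:, None] if batched else v


def rhs_shared_habitat(state: StateVector, params: ModelParams) -> np.ndarray:
    """Time derivatives during the shared season (migrants with residents).

    Both host groups mix: each susceptible class is exposed to the pooled
    infecteds ``Iri + Imi`` of every strain.  Births occur only in this
    season; residents and migrants each reproduce into their own susceptible
    class, throttled by the shared density factor ``(1 - gamma*N)``, with
    infected parents paying the fecundity cost ``sigma``.  Everyone recovers
    at the Habitat 1 rate ``nu1``.
    """
    y = _asarray(state)
    batched = y.ndim == 2
    beta = _cols(params.beta(), batched)
    alpha = _cols(np.asarray(params.alpha), batched)
    b, d, sig, gam = params.b, params.d, params.sigma, params.gamma
    mu, nu1 = params.mu, params.nu1

    Sr, Ir, Rr = y[_SR], y[_IR], y[_RR]
    Sm, Im, Rm = y[_SM], y[_IM], y[_RM]
    N = y.sum(axis=0)
    pool = Ir + Im
    new_r = beta * Sr * pool          # per-strain new resident infections
    new_m = beta * Sm * pool
    birth_factor = 1.0 - gam * N

    out = np.empty_like(y)
    out[_SR] = (-new_r.sum(axis=0) + mu * Rr
                + (b * (Sr + Rr) + (b + sig) * Ir.sum(axis=0)) * birth_factor
                - d * Sr)
    out[_IR] = new_r - (nu1 + d + alpha) * Ir
    out[_RR] = nu1 * Ir.sum(axis=0) - (mu + d) * Rr
    out[_SM] = (-new_m.sum(axis=0) + mu * Rm
                + (b * (Sm + Rm) + (b + sig) * Im.sum(axis=0)) * birth_factor
                - d * Sm)
    out[_IM] = new_m - (nu1 + d + alpha) * Im
    out[_RM] = nu1 * Im.sum(axis=0) - (mu + d) * Rm
    return out


def rhs_separate_habitats(state: StateVector, params: ModelParams) -> np.ndarray:
    """Time derivatives during the apart season (migrants in Habitat 2).

    Transmission is within-group only, there is no reproduction, and
    migrants enjoy the elevated Habitat 2 recovery rate ``nu2`` while
    residents keep recovering at ``nu1``.
    """
    y = _asarray(state)
    batched = y.ndim == 2
    beta = _cols(params.beta(), batched)
    alpha = _cols(np.asarray(params.alpha), batched)
    d, mu = params.d, params.mu
    nu1, nu2 = params.nu1, params.nu2

    Sr, Ir, Rr = y[_SR], y[_IR], y[_RR]
    Sm, Im, Rm = y[_SM], y[_IM], y[_RM]
    new_r = beta * Sr * Ir
    new_m = beta * Sm * Im

    out = np.empty_like(y)
    out[_SR] = -new_r.sum(axis=0) + mu * Rr - d * Sr
    out[_IR] = new_r - (nu1 + d + alpha) * Ir
    out[_RR] = nu1 * Ir.sum(axis=0) - (mu + d) * Rr
    out[_SM] = -new_m.sum(axis=0) + mu * Rm - d * Sm
    out[_IM] = new_m - (nu2 + d + alpha) * Im
    out[_RM] = nu2 * Im.sum(axis=0) - (mu + d) * Rm
    return out


def apply_migration_pulse(state: StateVector, params: ModelParams) -> StateVector:
    """Instantaneous per-trip migration mortality on the five migrant classes.

    Susceptible, infected and resistant migrants are scaled by
    ``1 - delta_S``, ``1 - delta_I`` and ``1 - delta_R``; residents are
    untouched.  Applied twice a year, on departure and on return.
    """
    y = _asarray(state).copy()
    y[_SM] *= 1.0 - _asarray(params.delta_S)
    y[_IM] *= 1.0 - _asarray(params.delta_I)
    y[_RM] *= 1.0 - _asarray(params.delta_R)
    return y
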