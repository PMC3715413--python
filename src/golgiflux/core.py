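"""Core domain types for the cisternal-maturation Golgi model.

The Golgi stack is represented as ``n_cisternae`` well-mixed compartments
indexed cis (1, youngest) to trans (N, oldest).  Every ``period`` time units
the stack shifts: each cisterna's index increments, the trans-most cisterna
dissolves, and a newborn cisterna with fixed initial concentrations is added
at the cis end.  Between shifts, vesicles continuously bud from every
cisterna, load cargo by competitive mass-action binding, and fuse with
targets in proportion to cognate v-SNARE x t-SNARE concentration products.

All concentrations are expressed in units of the newborn-cisterna
concentration (C0) and time in units of the maturation period, so presets
use ``C_init = 1`` and ``period = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np


class ConfigurationError(ValueError):
    """A species list or parameter set violates a model invariant."""


class Role(str, Enum):
    """Functional role of a transported molecule class.

    t-SNAREs act on the cisternal (target) side of fusion, v-SNAREs on the
    vesicular side; the ER v-SNARE mediates fusion of Golgi-derived vesicles
    with the ER.  PASSIVE_CARGO (Golgi enzymes) is transported and competes
    for vesicular binding sites but never contributes to fusion weights.
    """

    T_SNARE_ALPHA = "t_snare_alpha"
    V_SNARE_ALPHA = "v_snare_alpha"
    T_SNARE_BETA = "t_snare_beta"
    V_SNARE_BETA = "v_snare_beta"
    ER_V_SNARE = "er_v_snare"
    PASSIVE_CARGO = "passive_cargo"


#: cognate (v-SNARE role, t-SNARE role) pairs contributing to intra-Golgi fusion
COGNATE_PAIRS = (
    (Role.V_SNARE_ALPHA, Role.T_SNARE_ALPHA),
    (Role.V_SNARE_BETA, Role.T_SNARE_BETA),
)

T_ROLES = frozenset({Role.T_SNARE_ALPHA, Role.T_SNARE_BETA})
V_ROLES = frozenset({Role.V_SNARE_ALPHA, Role.V_SNARE_BETA, Role.ER_V_SNARE})


class Topology(str, Enum):
    LOCAL = "local"            # vesicles reach only the progenitor and its two neighbours
    UNRESTRICTED = "unrestricted"  # vesicles reach any cisterna (non-stacked Golgi)


class Boundary(str, Enum):
    OPEN = "open"      # vesicles may leave the Golgi by fusing with the ER
    CLOSED = "closed"  # vesicles are confined to the stack


class ErAccess(str, Enum):
    """Which donor cisternae may send vesicles to the ER (open boundary)."""

    FIRST_CISTERNA_ONLY = "first_cisterna_only"
    ALL_CISTERNAE = "all_cisternae"
    NONE = "none"


@dataclass(frozen=True)
class SpeciesSpec:
    """One transported molecule class (a SNARE or an enzyme).

    Parameters
    ----------
    name
        Short identifier, e.g. ``"alpha_t"`` or ``"enz_cis"``.
    role
        Fusion role; :class:`Role`.
    K
        Dissociation constant for vesicular binding sites, units of C0.
        Lower K = stronger competitor for vesicle incorporation.
    kappa
        First-order loss rate per maturation period (degradation,
        mis-targeting, inactivation -- everything except ER recycling,
        which the open boundary accounts for explicitly).
    C_init
        Concentration loaded into each newborn cisterna, units of C0.
    site_group
        Label of the vesicular binding-site pool this species competes in.
        Species sharing a label compete for the same sites; ``None`` gives
        the species a private pool (single-cargo loading ``n*C/(K+C)``).
    """

    name: str
    role: Role
    K: float
    kappa: float = 0.0
    C_init: float = 1.0
    site_group: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("species name must be non-empty")
        if not self.K > 0:
            raise ConfigurationError(f"species {self.name!r}: K must be > 0, got {self.K}")
        if self.kappa < 0:
            raise ConfigurationError(f"species {self.name!r}: kappa must be >= 0, got {self.kappa}")
        if self.C_init < 0:
            raise ConfigurationError(f"species {self.name!r}: C_init must be >= 0, got {self.C_init}")


@dataclass(frozen=True)
class ModelParameters:
    """Stack geometry, transport intensity, boundary mode and integrator knobs.

    ``omega`` is the single lumped vesicular transport coefficient.  The
    underlying budding rate, fusion rate constant, compartment area and
    vesicle/cisterna dilution factor only ever enter the steady-state flux
    as a product (compartment areas are constant in the model), so they are
    not separately identifiable and are absorbed into one dimensionless
    constant multiplying every normalized vesicular flux term.
    """

    n_cisternae: int = 8
    period: float = 1.0
    omega: float = 5.0
    n_sites: float = 1.0
    T_ER: float = 0.7
    topology: Topology = Topology.LOCAL
    boundary: Boundary = Boundary.OPEN
    er_access: ErAccess = ErAccess.ALL_CISTERNAE
    linear_loading: bool = False
    dt: float = 1e-3
    tol: float = 1e-8
    max_periods: int = 500

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)


@dataclass
class GolgiState:
    """Instantaneous state of the stack between shift events.

    ``C`` holds cisternal concentrations, species x cisterna, cis to trans;
    the youngest cisterna has column index 0 (cisterna number one).
    ``active_n`` < ``C.shape[1]`` only during de-novo growth, when the stack
    is still filling up; inactive columns are zero and never touched.
    """

    C: np.ndarray
    t_in_period: float = 0.0
    n_shifts: int = 0
    er_accumulated: np.ndarray = field(default=None)  # type: ignore[assignment]
    decayed_accumulated: np.ndarray = field(default=None)  # type: ignore[assignment]
    clamped_mass: float = 0.0
    active_n: int = 0

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n_species = self.C.shape[0]
        if self.er_accumulated is None:
            self.er_accumulated = np.zeros(n_species)
        if self.decayed_accumulated is None:
            self.decayed_accumulated = np.zeros(n_species)
        if self.active_n == 0:
            self.active_n = self.C.shape[1]
        if np.any(self.C < 0):
            raise ValueError("cisternal concentrations must be nonnegative")

    def copy(self) -> "GolgiState":
        return GolgiState(
            C=self.C.copy(),
            t_in_period=self.t_in_period,
            n_shifts=self.n_shifts,
            er_accumulated=self.er_accumulated.copy(),
            decayed_accumulated=self.decayed_accumulated.copy(),
            clamped_mass=self.clamped_mass,
            active_n=self.active_n,
        )


@dataclass
class MassBalance:
    """Per-species budget of the final simulated period.

    Over one full period (shift to shift) the newborn input must equal the
    flushed trans-cisterna content plus ER delivery plus first-order decay
    plus the change in total stack content; ``defect`` is the residual of
    that budget and should vanish to integrator accuracy.
    """

    input: np.ndarray
    flushed: np.ndarray
    er_delivered: np.ndarray
    decayed: np.ndarray
    delta_stack: np.ndarray

    @property
    def defect(self) -> np.ndarray:
        return self.input - self.flushed - self.er_delivered - self.decayed - self.delta_stack


@dataclass
class SteadyStateResult:
    """Converged (or capped) periodic steady state of a scenario run.

    ``profiles`` is the species x cisterna concentration matrix sampled
    immediately before the cisternal shift event -- the model's plotted
    observable.  ``er_fraction`` is the fraction of each species'
    per-period input that is recycled to the ER per period at steady state.
    """

    species: tuple[SpeciesSpec, ...]
    params: ModelParameters
    profiles: np.ndarray
    converged: bool
    n_periods_used: int
    residual: float
    er_fraction: np.ndarray
    mass_balance: MassBalance
    flushed: np.ndarray
    fitted_exponent: Optional[dict] = None
    scenario: Optional[str] = None

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def profile(self, name: str) -> np.ndarray:
        """Pre-shift concentration profile of one species, cis to trans."""
        return self.profiles[self._index(name)]

    def _index(self, name: str) -> int:
        for i, s in enumerate(self.species):
            if s.name == name:
                return i
        raise KeyError(f"unknown species {name!r}; have {self.species_names}")

    def to_frame(self):
        """Tidy profile table: scenario-free species/cisterna/concentration."""
        import pandas as pd

        records = []
        for i, s in enumerate(self.species):
            prof = self.profiles[i]
            peak = prof.max()
            for j in range(prof.size):
                records.append(
                    {
                        "species": s.name,
                        "cisterna": j + 1,
                        "concentration": prof[j],
                        "normalized_concentration": prof[j] / peak if peak > 0 else 0.0,
                    }
                )
        return pd.DataFrame.from_records(records)

    def summary(self) -> str:
        """Human-readable per-species summary table."""
        from .report import summarize

        return summarize(self).to_text()


def _pair_roles_present(species: Sequence[SpeciesSpec]) -> set[Role]:
    return {s.role for s in species}


def validate(species: Sequence[SpeciesSpec], params: ModelParameters) -> None:
    """Enforce every configuration invariant; raise ConfigurationError on violation."""
    names = [s.name for s in species]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate species names: {dupes}")
    if not species:
        raise ConfigurationError("at least one species is required")

    p = params
    if p.n_cisternae < 2:
        raise ConfigurationError(f"n_cisternae must be >= 2, got {p.n_cisternae}")
    if not p.period > 0:
        raise ConfigurationError(f"period must be > 0, got {p.period}")
    if p.omega < 0:
        raise ConfigurationError(f"omega must be >= 0, got {p.omega}")
    if not p.n_sites > 0:
        raise ConfigurationError(f"n_sites must be > 0, got {p.n_sites}")
    if p.T_ER < 0:
        raise ConfigurationError(f"T_ER must be >= 0, got {p.T_ER}")
    if not p.dt > 0:
        raise ConfigurationError(f"dt must be > 0, got {p.dt}")
    if not p.dt < p.period / 100:
        raise ConfigurationError(
            f"dt must be < period/100 for a usable Euler step, got dt={p.dt}, period={p.period}"
        )
    if not p.tol > 0:
        raise ConfigurationError(f"tol must be > 0, got {p.tol}")
    if p.max_periods < 1:
        raise ConfigurationError(f"max_periods must be >= 1, got {p.max_periods}")

    if p.boundary is Boundary.CLOSED and p.er_access is not ErAccess.NONE:
        raise ConfigurationError(
            "boundary=CLOSED requires er_access=NONE (no vesicle may leave the stack)"
        )

    roles = _pair_roles_present(species)
    if p.omega > 0:
        if not roles & T_ROLES or not roles & V_ROLES:
            raise ConfigurationError(
                "omega > 0 requires at least one t-SNARE and one v-SNARE species "
                "to carry any vesicular transport"
            )
        for v_role, t_role in COGNATE_PAIRS:
            if (v_role in roles) != (t_role in roles):
                raise ConfigurationError(
                    f"cognate pair incomplete: found only one of {v_role.value}/{t_role.value}"
                )
    if p.er_access is not ErAccess.NONE and p.boundary is Boundary.OPEN:
        if Role.ER_V_SNARE not in roles and p.omega > 0:
            raise ConfigurationError(
                "an open boundary with ER access needs an er_v_snare species to "
                "mediate Golgi-to-ER fusion"
            )
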