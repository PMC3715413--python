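"""Vesicular flux assembly, Euler stepping, shift events, steady-state runs.

Vesicle populations are not tracked explicitly: at steady state every
budded vesicle fuses with one of its allowed targets, so the per-donor
cargo efflux equals the loaded vesicular concentration distributed over
targets by normalized fusion weights.  The weight of target j for a donor
is proportional to the sum over cognate SNARE pairs of (vesicular v-SNARE)
x (target cisternal t-SNARE); the ER target weight is (vesicular ER
v-SNARE) x (fixed ER t-SNARE concentration).

Boundary handling in the LOCAL topology: a donor's missing neighbour slot
(cis of cisterna 1 when no ER is reachable, trans of cisterna N always)
reflects back onto the donor itself.  Every donor then distributes its
vesicle budget over a full set of slots, and a loss-free closed stack has
an exactly flat steady state — vesicular transport alone can enhance a
concentration difference between cisternae but never create one.
"""

from __future__ import annotations

import logging
import math
from typing import Literal, Optional, Sequence

import numpy as np

from .core import (
    Boundary,
    COGNATE_PAIRS,
    ErAccess,
    GolgiState,
    MassBalance,
    ModelParameters,
    Role,
    SpeciesSpec,
    SteadyStateResult,
    Topology,
    validate,
)
from .loading import site_group_ids, vesicle_concentrations

logger = logging.getLogger(__name__)

__all__ = [
    "fusion_weights",
    "flux_derivatives",
    "euler_step",
    "maturation_shift",
    "run_to_steady_state",
    "initial_state",
]


class _Kinetics:
    """Precomputed per-configuration arrays for the inner integration loop."""

    def __init__(self, species: Sequence[SpeciesSpec], params: ModelParameters):
        self.species = tuple(species)
        self.params = params
        self.K = np.array([s.K for s in species])
        self.kappa = np.array([s.kappa for s in species])
        self.C_init = np.array([s.C_init for s in species])
        self.group_ids = site_group_ids(species)
        roles = [s.role for s in species]
        self.pair_indices = [
            (roles.index(v), roles.index(t))
            for v, t in COGNATE_PAIRS
            if v in roles and t in roles
        ]
        self.er_index = roles.index(Role.ER_V_SNARE) if Role.ER_V_SNARE in roles else None
        self.er_open = (
            params.boundary is Boundary.OPEN
            and params.er_access is not ErAccess.NONE
            and self.er_index is not None
        )

    def vesicles(self, C: np.ndarray) -> np.ndarray:
        return vesicle_concentrations(
            C, self.K, self.params.n_sites, self.group_ids, linear=self.params.linear_loading
        )

    def weight_matrix(self, C: np.ndarray, V: np.ndarray) -> np.ndarray:
        """Normalized fusion weights, donors x (cisternae + ER column)."""
        n = C.shape[1]
        p = self.params
        aff = np.zeros((n, n + 1))
        for vi, ti in self.pair_indices:
            aff[:, :n] += np.outer(V[vi], C[ti])
        er_aff = V[self.er_index] * p.T_ER if self.er_open else None

        if p.topology is Topology.UNRESTRICTED:
            if er_aff is not None:
                if p.er_access is ErAccess.ALL_CISTERNAE:
                    aff[:, n] = er_aff
                else:  # FIRST_CISTERNA_ONLY
                    aff[0, n] = er_aff[0]
        else:  # LOCAL: band |donor - target| <= 1 plus boundary slots
            band = np.zeros((n, n))
            idx = np.arange(n)
            band[idx, idx] = 1.0
            if n > 1:
                band[idx[:-1], idx[:-1] + 1] = 1.0
                band[idx[1:], idx[1:] - 1] = 1.0
            aff[:, :n] *= band
            self_aff = np.diagonal(aff[:, :n]).copy()
            # trans slot of the last donor has no recipient -> reflects to self
            aff[n - 1, n - 1] += self_aff[n - 1]
            if er_aff is not None:
                # cis slot of donor 0 is the ER
                aff[0, n] = er_aff[0]
                if p.er_access is ErAccess.ALL_CISTERNAE and n > 1:
                    # expansive ER reaches every donor: an extra slot each
                    aff[1:, n] = er_aff[1:]
            else:
                # closed cis end: donor 0's cis slot reflects to self
                aff[0, 0] += self_aff[0]

        denom = aff.sum(axis=1)
        W = np.zeros_like(aff)
        positive = denom > 0
        W[positive] = aff[positive] / denom[positive, None]
        return W

    def derivatives(self, C: np.ndarray):
        """(dC/dt, ER delivery rate per species) for the active stack."""
        n = C.shape[1]
        V = self.vesicles(C)
        W = self.weight_matrix(C, V)
        W0 = W.copy()
        np.fill_diagonal(W0[:, :n], 0.0)
        out_frac = W0.sum(axis=1)
        inflow = V @ W0
        omega = self.params.omega
        dC = -self.kappa[:, None] * C + omega * (inflow[:, :n] - V * out_frac[None, :])
        er_rate = omega * inflow[:, n]
        return dC, er_rate


def _kinetics(species, params) -> _Kinetics:
    return _Kinetics(species, params)


def fusion_weights(
    donor: int,
    state: GolgiState,
    params: ModelParameters,
    species: Sequence[SpeciesSpec],
) -> dict:
    """Fusion-weight row of one donor cisterna (1-based index).

    Returns a mapping from target labels (1-based cisterna numbers, plus
    ``"ER"`` when reachable) to normalized weights.  Weights sum to one
    whenever any target has positive affinity; with all-zero affinities
    (e.g. no v-SNARE in the vesicle) transport is silently inactive and
    every weight is zero.
    """
    kin = _Kinetics(species, params)
    n = state.active_n
    if not 1 <= donor <= n:
        raise IndexError(f"donor {donor} outside active stack 1..{n}")
    C = state.C[:, :n]
    V = kin.vesicles(C)
    W = kin.weight_matrix(C, V)
    row = W[donor - 1]
    if params.topology is Topology.UNRESTRICTED:
        targets = range(n)
    else:
        targets = range(max(donor - 2, 0), min(donor + 1, n))
    out = {j + 1: float(row[j]) for j in targets}
    if kin.er_open and row[n] > 0:
        out["ER"] = float(row[n])
    return out


def flux_derivatives(
    state: GolgiState, params: ModelParameters, species: Sequence[SpeciesSpec]
) -> np.ndarray:
    """Net rate matrix dC/dt (species x cisterna) at the current state."""
    kin = _Kinetics(species, params)
    dC, _ = kin.derivatives(state.C[:, : state.active_n])
    full = np.zeros_like(state.C)
    full[:, : state.active_n] = dC
    return full


def euler_step(
    state: GolgiState,
    params: ModelParameters,
    species: Sequence[SpeciesSpec],
    dt: Optional[float] = None,
) -> GolgiState:
    """One explicit Euler update of the state (returns a new state).

    Negative concentrations produced by overshoot are clamped to zero and
    the clamped mass recorded; persistent clamping indicates a too-large dt.
    """
    if dt is None:
        dt = params.dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    kin = _Kinetics(species, params)
    new = state.copy()
    _advance(kin, new, dt)
    return new


def _advance(kin: _Kinetics, state: GolgiState, dt: float) -> None:
    """In-place Euler update used by the run loop."""
    n = state.active_n
    C = state.C[:, :n]
    dC, er_rate = kin.derivatives(C)
    state.decayed_accumulated += dt * (kin.kappa[:, None] * C).sum(axis=1)
    state.er_accumulated += dt * er_rate
    C += dt * dC
    neg = C < 0
    if neg.any():
        clamped = -C[neg].sum()
        state.clamped_mass += clamped
        if clamped > 1e-12:
            logger.warning("clamped %.3e of negative concentration overshoot", clamped)
        C[neg] = 0.0
    state.t_in_period += dt


def maturation_shift(
    state: GolgiState, species: Sequence[SpeciesSpec], n_cisternae: Optional[int] = None
) -> np.ndarray:
    """Perform one cisternal shift in place; return the flushed contents.

    Every cisterna's index increments by one; the trans-most cisterna is
    removed and its contents returned as flushed output (zero while the
    stack is still growing de novo); a newborn cisterna with ``C_init``
    concentrations appears at the cis end.
    """
    if n_cisternae is None:
        n_cisternae = state.C.shape[1]
    C_init = np.array([s.C_init for s in species])
    n = state.active_n
    if n < n_cisternae:
        flushed = np.zeros(len(species))
        state.C[:, 1 : n + 1] = state.C[:, :n]
        state.active_n = n + 1
    else:
        flushed = state.C[:, n - 1].copy()
        state.C[:, 1:n] = state.C[:, : n - 1]
    state.C[:, 0] = C_init
    state.n_shifts += 1
    state.t_in_period = 0.0
    return flushed


def initial_state(
    species: Sequence[SpeciesSpec],
    params: ModelParameters,
    start: Literal["full", "denovo"] = "full",
) -> GolgiState:
    """Fresh state: a full stack of newborn-identical cisternae, or a
    single cisterna from which the stack grows de novo."""
    C_init = np.array([s.C_init for s in species])
    C = np.zeros((len(species), params.n_cisternae))
    if start == "full":
        C[:] = C_init[:, None]
        active = params.n_cisternae
    elif start == "denovo":
        C[:, 0] = C_init
        active = 1
    else:
        raise ValueError(f"start must be 'full' or 'denovo', got {start!r}")
    return GolgiState(C=C, active_n=active)


def run_to_steady_state(
    species: Sequence[SpeciesSpec],
    params: ModelParameters,
    start: Literal["full", "denovo"] = "full",
    sample_phase: Optional[float] = None,
) -> SteadyStateResult:
    """Integrate period by period until the pre-shift snapshot repeats.

    Convergence is detected in sup-norm between successive pre-shift
    snapshots (the paper's plotted observable); non-convergence within
    ``max_periods`` flags the result rather than raising.  ``sample_phase``
    optionally reports the profile at a mid-period phase in [0, period)
    instead of the pre-shift instant (diagnostics only; convergence is
    always judged pre-shift).
    """
    validate(species, params)
    kin = _Kinetics(species, params)
    p = params
    steps = max(int(round(p.period / p.dt)), 101)
    dt = p.period / steps
    sample_step = None
    if sample_phase is not None:
        if not 0 <= sample_phase < p.period:
            raise ValueError("sample_phase must lie in [0, period)")
        sample_step = int(round(sample_phase / dt))

    state = initial_state(species, params, start=start)
    prev_snapshot = None
    snapshot = state.C.copy()
    phase_snapshot = state.C.copy()
    residual = math.inf
    converged = False
    n_periods = 0
    balance = None
    er_fraction = np.zeros(len(species))

    for period_index in range(p.max_periods):
        er_before = state.er_accumulated.copy()
        decayed_before = state.decayed_accumulated.copy()
        stack_before = state.C[:, : state.active_n].sum(axis=1)
        for k in range(steps):
            if sample_step is not None and k == sample_step:
                phase_snapshot = state.C.copy()
            _advance(kin, state, dt)
        snapshot = state.C.copy()
        n_periods = period_index + 1

        full_stack = state.active_n == p.n_cisternae
        flushed = maturation_shift(state, species, p.n_cisternae)
        er_period = state.er_accumulated - er_before
        balance = MassBalance(
            input=kin.C_init.copy(),
            flushed=flushed,
            er_delivered=er_period,
            decayed=state.decayed_accumulated - decayed_before,
            delta_stack=state.C[:, : state.active_n].sum(axis=1) - stack_before,
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            er_fraction = np.where(kin.C_init > 0, er_period / kin.C_init, 0.0)

        if full_stack and prev_snapshot is not None:
            residual = float(np.max(np.abs(snapshot - prev_snapshot)))
            logger.debug("period %d residual %.3e", n_periods, residual)
            if residual <= p.tol:
                converged = True
                break
        if full_stack:
            prev_snapshot = snapshot

    if not converged:
        logger.warning(
            "steady state not reached after %d periods (residual %.3e > tol %.1e)",
            n_periods,
            residual,
            p.tol,
        )
    if state.clamped_mass > 1e-9:
        logger.warning(
            "total clamped negative overshoot %.3e; consider a smaller dt", state.clamped_mass
        )

    profiles = phase_snapshot if sample_step is not None else snapshot
    return SteadyStateResult(
        species=tuple(species),
        params=params,
        profiles=profiles,
        converged=converged,
        n_periods_used=n_periods,
        residual=residual,
        er_fraction=np.clip(er_fraction, 0.0, 1.0),
        mass_balance=balance,
        flushed=flushed,
    )
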