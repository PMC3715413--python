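"""Asymptotic steady-state SNARE gradient: analytic exponent and profile fits.

Far from both ends of a (hypothetically long) stack, cisternal SNARE
concentrations are small, vesicle loading is linear in the donor
concentration, and the pre-shift steady-state profile decays exponentially
with the cisterna number, C_i ∝ a^i.  Substituting the exponential ansatz
into the transport equation with normalized nearest-neighbour fusion
weights, every interior cisterna decays as exp(-lambda*t) with

    lambda = kappa + (omega * n_sites / K) * (1 - a)^2 / (1 + a + a^2)

and the shift-periodicity condition C_{i+1}(pre-shift) = C_i(pre-shift)
* exp(-lambda*T) closes the system into a transcendental relation for the
per-cisterna factor ``a``:

    ln a = -(kappa*T) - (omega*n_sites*T/K) * (1 - a)^2 / (1 + a + a^2)

The two dimensionless groups are ``decay_group = kappa*T`` (SNARE loss per
period) and ``transport_group = omega*n_sites*T/K`` (linearized vesicular
transport intensity per period).  Limits: with zero loss a = 1 for any
transport intensity (vesicular exchange alone cannot create a gradient);
with zero transport a = exp(-decay_group), the pure conveyor-decay factor;
transport strictly steepens any loss-seeded gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExponentSolution",
    "steady_state_relation",
    "solve_exponent",
    "small_loss_expansion",
    "fit_exponent",
]

_BISECTION_TOL = 1e-10
_A_FLOOR = 1e-12


@dataclass(frozen=True)
class ExponentSolution:
    """Root of the steady-state exponent relation.

    ``a`` is the per-cisterna decay factor of the pre-shift profile
    (profile ∝ a^i, 0 < a <= 1); ``residual`` is the absolute value of the
    transcendental relation at the root.
    """

    a: float
    decay_group: float
    transport_group: float
    residual: float

    @property
    def params_used(self) -> dict:
        return {"decay_group": self.decay_group, "transport_group": self.transport_group}


def steady_state_relation(a: float, decay_group: float, transport_group: float) -> float:
    """The transcendental relation whose root is the gradient exponent.

    Returns ln(a) + decay_group + transport_group*(1-a)^2/(1+a+a^2); the
    steady-state factor is the zero of this expression on (0, 1].
    """
    a = np.asarray(a, dtype=float)
    return np.log(a) + decay_group + transport_group * (1.0 - a) ** 2 / (1.0 + a + a * a)


def solve_exponent(decay_group: float, transport_group: float) -> ExponentSolution:
    """Solve for the per-cisterna decay factor ``a`` by bracketed bisection.

    The root closest to 1 is returned: it is the branch that continuously
    deforms from the no-loss fixed point a = 1 as the loss rate grows, i.e.
    the one the maturing stack actually relaxes onto.  Zero loss returns
    a = 1 exactly for any transport intensity.
    """
    if decay_group < 0 or transport_group < 0:
        raise ValueError("decay_group and transport_group must be nonnegative")
    if decay_group == 0:
        return ExponentSolution(1.0, decay_group, transport_group, 0.0)

    f = lambda a: float(steady_state_relation(a, decay_group, transport_group))
    # f(1) = decay_group > 0; scan downward for the first sign change
    grid = np.linspace(1.0, _A_FLOOR, 4001)
    hi = 1.0
    lo = None
    for a in grid[1:]:
        if f(float(a)) < 0:
            lo = float(a)
            break
        hi = float(a)
    if lo is None:
        raise RuntimeError(
            "no sign change of the steady-state relation on (0, 1]: "
            f"decay_group={decay_group}, transport_group={transport_group}, "
            f"f(1e-12)={f(_A_FLOOR):.3e}"
        )
    while hi - lo > _BISECTION_TOL:
        mid = 0.5 * (hi + lo)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    a_root = 0.5 * (hi + lo)
    return ExponentSolution(a_root, decay_group, transport_group, abs(f(a_root)))


def small_loss_expansion(transport_group: float, decay_group: float) -> float:
    """Second-order small-loss expansion of the gradient exponent.

    a ≈ 1 - decay_group + (1/2 - transport_group/3) * decay_group**2.
    At zero loss this is exactly 1, independent of the vesicular transport
    intensity; the transport only enters at second order in the loss,
    steepening the gradient once transport_group > 3/2.
    """
    k = decay_group
    w = transport_group
    return 1.0 - k + (0.5 - w / 3.0) * k * k


def fit_exponent(profile, interior: slice | tuple[int, int]) -> tuple[float, float]:
    """Log-linear fit of a per-cisterna decay factor on an interior range.

    Parameters
    ----------
    profile
        Per-cisterna concentrations, cis to trans (1-based cisterna i maps
        to index i-1).
    interior
        Index range (slice, or 0-based (start, stop) tuple) away from both
        stack ends, where boundary effects are negligible.

    Returns
    -------
    (a, r_squared)
        The fitted per-cisterna factor exp(slope of log C vs i) and the
        coefficient of determination of the log-linear fit.
    """
    prof = np.asarray(profile, dtype=float)
    if isinstance(interior, tuple):
        interior = slice(*interior)
    y = prof[interior]
    if y.size < 3:
        raise ValueError("interior range must contain at least three cisternae")
    if np.any(y <= 0):
        raise ValueError("profile must be strictly positive on the interior range")
    x = np.arange(prof.size, dtype=float)[interior]
    logy = np.log(y)
    slope, intercept = np.polyfit(x, logy, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((logy - fitted) ** 2))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(np.exp(slope)), r2
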