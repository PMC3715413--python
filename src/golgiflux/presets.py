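"""Built-in scenario presets.

Each preset is a fully validated (species list, parameters) pair mirroring
one of the model's canonical setups: the single-SNARE-pair gradient study,
the enzyme-competition stack with open or closed ER boundary, the full
two-pair mammalian Golgi, its unrestricted-fusion (non-stacked, yeast-like)
variant, and a long stack for asymptotic gradient analysis.

Concentrations are in units of the newborn-cisterna concentration and time
in units of the maturation period, so every preset has ``C_init = 1`` and
``period = 1``.  Dissociation constants of the mammalian scenario
(ER v-SNARE 0.2; alpha t/v 0.4; beta t 1; beta v 5; cis/medial/trans
enzymes 1.4/2.5/5) and the ER t-SNARE level 0.7 are the published set;
loss rates and the lumped transport coefficient omega are package defaults
chosen once to place each scenario in its smooth, convergent transport
regime (see docs/methods.md) and are marked as defaults in config output.
"""

from __future__ import annotations

from .core import (
    Boundary,
    ConfigurationError,
    ErAccess,
    ModelParameters,
    Role,
    SpeciesSpec,
    Topology,
    validate,
)

__all__ = ["SCENARIOS", "build_scenario", "DEFAULT_KEYS"]

# Published dissociation constants (units of C0) and the ER t-SNARE level
K_ER_V = 0.2
K_ALPHA_T = 0.4
K_ALPHA_V = 0.4
K_BETA_T = 1.0
K_BETA_V = 5.0
K_ENZ_CIS = 1.4
K_ENZ_MED = 2.5
K_ENZ_TRANS = 5.0
T_ER = 0.7

# Package defaults (loss rates, lumped transport coefficient omega, site
# concentration).  Only the product omega*n_sites matters dynamically, so
# n_sites is kept at 1 and omega carries the transport intensity.
N_SITES_DEFAULT = 1.0
KAPPA_SINGLE = 0.2     # seed loss of the single-pair scenarios
OMEGA_SINGLE = 2.0
KAPPA_ENZ_SEED = 0.3   # seed loss of the enzyme-competition scenarios
OMEGA_ENZ_OPEN = 3.6
OMEGA_ENZ_CLOSED = 1.0
OMEGA_FULL = 10.0
KAPPA_BETA_T = 0.1     # small decay of the beta t-SNARE in the full model
OMEGA_YEAST = 8.0
KAPPA_YEAST = 0.3      # both t-SNAREs decay in the unrestricted scenario
KAPPA_LONG = 0.1
OMEGA_LONG = 1.0

#: parameter/species keys whose preset values are package defaults rather
#: than published constants (flagged in serialized config output)
DEFAULT_KEYS = ("omega", "n_sites", "kappa")


def _single_pair(kappa: float, K: float = 1.0) -> list[SpeciesSpec]:
    return [
        SpeciesSpec("alpha_t", Role.T_SNARE_ALPHA, K=K, kappa=kappa),
        SpeciesSpec("alpha_v", Role.V_SNARE_ALPHA, K=K, kappa=kappa),
    ]


def _enzymes(site_group: str = "enzymes") -> list[SpeciesSpec]:
    return [
        SpeciesSpec("enz_cis", Role.PASSIVE_CARGO, K=K_ENZ_CIS, site_group=site_group),
        SpeciesSpec("enz_med", Role.PASSIVE_CARGO, K=K_ENZ_MED, site_group=site_group),
        SpeciesSpec("enz_trans", Role.PASSIVE_CARGO, K=K_ENZ_TRANS, site_group=site_group),
    ]


def _scenario_single_snare():
    """One cognate SNARE pair in a closed stack: loss plus vesicular
    transport establish the cis-to-trans gradient."""
    params = ModelParameters(
        omega=OMEGA_SINGLE,
        n_sites=N_SITES_DEFAULT,
        boundary=Boundary.CLOSED,
        er_access=ErAccess.NONE,
    )
    return _single_pair(KAPPA_SINGLE), params


def _scenario_single_snare_loss_only():
    """Loss mechanism alone (omega = 0): the pure conveyor-decay gradient
    exp(-kappa*(i-1))."""
    species, params = _scenario_single_snare()
    return species, params.replace(omega=0.0)


def _scenario_single_snare_transport_only():
    """Vesicular transport alone (all kappa = 0): no gradient forms."""
    _, params = _scenario_single_snare()
    return _single_pair(0.0), params


def _scenario_enzymes(boundary: Boundary):
    """Three enzyme classes competing for vesicular sites, riding the
    single-pair SNARE gradient.

    The SNAREs evolve autonomously (private site pools) while the enzymes
    compete with each other for one shared pool; with the open boundary,
    vesicles from the first cisterna may fuse with the ER.  The closed
    variant uses a weaker transport coefficient: confining all vesicles to
    the stack strengthens the fusion self-enhancement, and the scenario is
    kept inside the smooth regime below the clumping instability.
    """
    species = _single_pair(KAPPA_ENZ_SEED, K=K_ALPHA_T) + [
        SpeciesSpec("er_v", Role.ER_V_SNARE, K=K_ER_V),
        *_enzymes(),
    ]
    open_b = boundary is Boundary.OPEN
    params = ModelParameters(
        omega=OMEGA_ENZ_OPEN if open_b else OMEGA_ENZ_CLOSED,
        n_sites=N_SITES_DEFAULT,
        T_ER=T_ER,
        boundary=boundary,
        er_access=ErAccess.FIRST_CISTERNA_ONLY if open_b else ErAccess.NONE,
    )
    return species, params


def _scenario_full_mammalian():
    """Two cognate SNARE pairs, ER v-SNARE and three enzyme classes, all
    competing for one shared pool of vesicular sites; every decay rate is
    zero except a small loss of the beta t-SNARE, whose ER recycling is
    poor; vesicles from any cisterna may fuse with the ER."""
    shared = "all"
    species = [
        SpeciesSpec("er_v", Role.ER_V_SNARE, K=K_ER_V, site_group=shared),
        SpeciesSpec("alpha_t", Role.T_SNARE_ALPHA, K=K_ALPHA_T, site_group=shared),
        SpeciesSpec("alpha_v", Role.V_SNARE_ALPHA, K=K_ALPHA_V, site_group=shared),
        SpeciesSpec("beta_t", Role.T_SNARE_BETA, K=K_BETA_T, kappa=KAPPA_BETA_T, site_group=shared),
        SpeciesSpec("beta_v", Role.V_SNARE_BETA, K=K_BETA_V, site_group=shared),
        *_enzymes(site_group=shared),
    ]
    params = ModelParameters(
        omega=OMEGA_FULL,
        n_sites=N_SITES_DEFAULT,
        T_ER=T_ER,
        boundary=Boundary.OPEN,
        er_access=ErAccess.ALL_CISTERNAE,
    )
    return species, params


def _scenario_unrestricted_yeast():
    """Full model without the nearest-neighbour fusion restriction
    (non-stacked Golgi): vesicles reach any cisterna and the ER.  Both
    t-SNAREs carry the seed decay term, and the transport coefficient is
    slightly reduced to stay within the convergent regime of the
    unrestricted fusion dynamics."""
    species, params = _scenario_full_mammalian()
    species = [
        s
        if s.role not in (Role.T_SNARE_ALPHA, Role.T_SNARE_BETA)
        else SpeciesSpec(
            s.name, s.role, K=s.K, kappa=KAPPA_YEAST, C_init=s.C_init, site_group=s.site_group
        )
        for s in species
    ]
    return species, params.replace(
        topology=Topology.UNRESTRICTED, omega=OMEGA_YEAST, max_periods=800
    )


def _scenario_long_stack():
    """Non-biologically long stack (N = 30) in the linear-loading regime,
    for validating the exponential interior gradient against the analytic
    root of the steady-state relation."""
    params = ModelParameters(
        n_cisternae=30,
        omega=OMEGA_LONG,
        n_sites=N_SITES_DEFAULT,
        boundary=Boundary.CLOSED,
        er_access=ErAccess.NONE,
        linear_loading=True,
    )
    return _single_pair(KAPPA_LONG), params


SCENARIOS = {
    "single_snare": _scenario_single_snare,
    "single_snare_loss_only": _scenario_single_snare_loss_only,
    "single_snare_transport_only": _scenario_single_snare_transport_only,
    "enzymes_open": lambda: _scenario_enzymes(Boundary.OPEN),
    "enzymes_closed": lambda: _scenario_enzymes(Boundary.CLOSED),
    "full_mammalian": _scenario_full_mammalian,
    "unrestricted_yeast": _scenario_unrestricted_yeast,
    "long_stack": _scenario_long_stack,
}


def build_scenario(name: str) -> tuple[list[SpeciesSpec], ModelParameters]:
    """Return the validated (species, parameters) pair of a named preset."""
    try:
        factory = SCENARIOS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {name!r}; valid presets: {', '.join(sorted(SCENARIOS))}"
        ) from None
    species, params = factory()
    validate(species, params)
    return species, params
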