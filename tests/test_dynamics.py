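"""Fusion weights, flux assembly, Euler stepping and shift events."""

import numpy as np
import pytest

from golgiflux import (
    Boundary,
    ErAccess,
    GolgiState,
    ModelParameters,
    Role,
    SpeciesSpec,
    build_scenario,
    euler_step,
    flux_derivatives,
    fusion_weights,
    initial_state,
    maturation_shift,
    run_to_steady_state,
)
from golgiflux.dynamics import _Kinetics


def _pair(kappa=0.0, K=1.0):
    return [
        SpeciesSpec("t", Role.T_SNARE_ALPHA, K=K, kappa=kappa),
        SpeciesSpec("v", Role.V_SNARE_ALPHA, K=K, kappa=kappa),
    ]


def _closed_params(**kw):
    kw.setdefault("boundary", Boundary.CLOSED)
    kw.setdefault("er_access", ErAccess.NONE)
    return ModelParameters(**kw)


class TestFusionWeights:
    def test_interior_donor_weights_proportional_to_t_snare(self):
        species = _pair()
        params = _closed_params(n_cisternae=3, omega=1.0)
        state = GolgiState(C=np.array([[0.9, 0.6, 0.3], [1.0, 1.0, 1.0]]))
        w = fusion_weights(2, state, params, species)
        assert w[1] == pytest.approx(0.5)
        assert w[2] == pytest.approx(1 / 3)
        assert w[3] == pytest.approx(1 / 6)

    def test_flat_stack_gives_uniform_interior_weights(self):
        species = _pair()
        params = _closed_params(n_cisternae=5, omega=1.0)
        state = initial_state(species, params)
        w = fusion_weights(3, state, params, species)
        assert w[2] == w[3] == w[4] == pytest.approx(1 / 3)

    def test_degenerate_second_pair_matches_pure_alpha(self):
        rng = np.random.default_rng(7)
        C = rng.uniform(0.2, 1.0, (2, 4))
        species_a = _pair()
        # two-pair configuration whose beta members are absent from the stack
        species_ab = species_a + [
            SpeciesSpec("bt", Role.T_SNARE_BETA, K=1.0, C_init=0.0),
            SpeciesSpec("bv", Role.V_SNARE_BETA, K=1.0, C_init=0.0),
        ]
        params = _closed_params(n_cisternae=4, omega=1.0)
        state_a = GolgiState(C=C.copy())
        state_ab = GolgiState(C=np.vstack([C, np.zeros((2, 4))]))
        for donor in range(1, 5):
            wa = fusion_weights(donor, state_a, params, species_a)
            wab = fusion_weights(donor, state_ab, params, species_ab)
            assert wa == pytest.approx(wab)

    def test_all_zero_affinity_silences_transport(self):
        species = _pair()
        params = _closed_params(n_cisternae=3, omega=1.0)
        state = GolgiState(C=np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]))
        w = fusion_weights(2, state, params, species)
        assert all(val == 0 for val in w.values())


class TestFluxDerivatives:
    def test_transport_off_reduces_to_pure_decay(self):
        species = _pair(kappa=0.25)
        params = _closed_params(omega=0.0)
        state = initial_state(species, params)
        state.C *= np.array([[0.9], [0.4]])
        dC = flux_derivatives(state, params, species)
        np.testing.assert_allclose(dC, -0.25 * state.C, rtol=1e-14)

    def test_closed_stack_conserves_total_between_shifts(self):
        species = _pair(kappa=0.0)
        params = _closed_params(omega=2.0)
        rng = np.random.default_rng(11)
        state = GolgiState(C=rng.uniform(0.05, 1.5, (2, 8)))
        dC = flux_derivatives(state, params, species)
        np.testing.assert_allclose(dC.sum(axis=1), 0.0, atol=1e-13)

    def test_flat_profile_has_zero_derivative_everywhere(self):
        # oracle: direct evaluation of in/out sums at a uniform stack;
        # transport can only enhance differences, never create them
        species = _pair(kappa=0.0)
        params = _closed_params(omega=3.0)
        state = initial_state(species, params)
        dC = flux_derivatives(state, params, species)
        np.testing.assert_allclose(dC, 0.0, atol=1e-14)

    def test_er_delivery_counts_against_stack_total(self):
        species = _pair(kappa=0.0) + [SpeciesSpec("er_v", Role.ER_V_SNARE, K=0.5)]
        params = ModelParameters(
            omega=2.0, boundary=Boundary.OPEN, er_access=ErAccess.ALL_CISTERNAE
        )
        state = initial_state(species, params)
        kin = _Kinetics(species, params)
        dC, er_rate = kin.derivatives(state.C)
        np.testing.assert_allclose(dC.sum(axis=1), -er_rate, atol=1e-13)
        assert er_rate.sum() > 0


class TestEulerStep:
    def test_single_decay_step(self):
        species = _pair(kappa=0.2)
        params = _closed_params(omega=0.0)
        state = initial_state(species, params)
        new = euler_step(state, params, species, dt=1e-3)
        np.testing.assert_allclose(new.C, 0.9998, rtol=1e-14)
        assert new.t_in_period == pytest.approx(1e-3)

    def test_overshoot_clamped_to_zero(self):
        species = _pair(kappa=2000.0)
        params = _closed_params(omega=0.0)
        state = initial_state(species, params)
        new = euler_step(state, params, species, dt=1e-3)
        assert np.all(new.C == 0.0)
        assert new.clamped_mass > 0

    def test_halved_steps_richardson_order(self):
        species = _pair(kappa=0.3)
        params = _closed_params(omega=1.5)
        rng = np.random.default_rng(3)
        base = GolgiState(C=rng.uniform(0.1, 1.0, (2, 8)))

        def err(dt):
            one = euler_step(base, params, species, dt=dt)
            half = euler_step(
                euler_step(base, params, species, dt=dt / 2), params, species, dt=dt / 2
            )
            return np.max(np.abs(one.C - half.C))

        e1, e2 = err(2e-3), err(1e-3)
        assert e2 == pytest.approx(e1 / 4, rel=0.15)  # O(dt^2) local error


class TestMaturationShift:
    def test_shift_semantics(self):
        species = [SpeciesSpec("x", Role.PASSIVE_CARGO, K=1.0, C_init=0.7)]
        state = GolgiState(C=np.array([[1.0, 2.0, 3.0]]))
        flushed = maturation_shift(state, species)
        np.testing.assert_allclose(state.C, [[0.7, 1.0, 2.0]])
        np.testing.assert_allclose(flushed, [3.0])
        assert state.n_shifts == 1
        assert state.t_in_period == 0.0

    def test_pure_conveyor_reaches_uniform_stack(self):
        species = _pair(kappa=0.0)
        params = _closed_params(omega=0.0, n_cisternae=5)
        state = initial_state(species, params)
        state.C *= np.linspace(2.0, 0.5, 5)[None, :]
        for _ in range(5):
            maturation_shift(state, species)
        np.testing.assert_allclose(state.C, 1.0)

    def test_denovo_growth_fills_stack_before_flushing(self):
        species = _pair(kappa=0.0)
        params = _closed_params(omega=0.0, n_cisternae=4)
        state = initial_state(species, params, start="denovo")
        assert state.active_n == 1
        for expected in [2, 3, 4]:
            flushed = maturation_shift(state, species, params.n_cisternae)
            assert state.active_n == expected
            assert np.all(flushed == 0)
        flushed = maturation_shift(state, species, params.n_cisternae)
        assert state.active_n == 4
        assert np.all(flushed == 1.0)


class TestSteadyState:
    def test_zero_loss_profile_is_flat(self):
        result = run_to_steady_state(*build_scenario("single_snare_transport_only"))
        assert result.converged
        prof = result.profile("alpha_t")
        np.testing.assert_allclose(prof[1:] / prof[:-1], 1.0, atol=1e-12)

    def test_snare_gradient_monotone_and_steeper_than_decay_alone(self):
        res_full = run_to_steady_state(*build_scenario("single_snare"))
        res_loss = run_to_steady_state(*build_scenario("single_snare_loss_only"))
        assert res_full.converged and res_loss.converged
        p_full, p_loss = res_full.profile("alpha_t"), res_loss.profile("alpha_t")
        assert np.all(np.diff(p_full) < 0)
        # vesicular transport enhances the loss-seeded gradient
        assert p_full[-1] / p_full[0] < p_loss[-1] / p_loss[0]

    def test_nonconvergence_is_flagged_not_raised(self):
        species, params = build_scenario("single_snare")
        result = run_to_steady_state(species, params.replace(max_periods=3))
        assert not result.converged
        assert result.n_periods_used == 3

    def test_sample_phase_differs_from_pre_shift(self):
        species, params = build_scenario("single_snare_loss_only")
        pre = run_to_steady_state(species, params)
        mid = run_to_steady_state(species, params, sample_phase=0.5)
        assert mid.converged
        # mid-period snapshot has decayed for half a period less
        ratio = mid.profile("alpha_t")[1:] / pre.profile("alpha_t")[1:]
        np.testing.assert_allclose(ratio, np.exp(0.2 * 0.5), rtol=1e-3)
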