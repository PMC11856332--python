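"""Core model arithmetic: trade-off curve, derivative fields, migration pulse."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from migsirs import (
    ModelParams,
    ValidationError,
    apply_migration_pulse,
    carrying_capacity,
    make_state,
    rhs_separate_habitats,
    rhs_shared_habitat,
    total_population,
    transmission_rate,
)

import oracles


class TestTransmissionRate:
    def test_default_form_hand_value(self, default_params):
        # cA * sqrt(cB + alpha) at alpha = 0.01
        assert transmission_rate(0.01, default_params) == pytest.approx(
            0.005 * np.sqrt(0.15), rel=1e-12
        )

    def test_zero_scaling_constant_gives_zero(self, default_params):
        p = default_params.replace(cA=0.0)
        assert transmission_rate(0.3, p) == 0.0

    def test_more_virulent_strain_transmits_faster(self, default_params):
        b = default_params.beta()
        assert b[2] > b[1] > b[0] > 0

    @pytest.mark.parametrize(
        "form,expected",
        [
            ("concave_sqrt", 0.005 * np.sqrt(0.15)),
            ("ratio", 0.005 / 0.15),
            ("linear", 0.005 * 0.14 + 0.01),
        ],
    )
    def test_all_forms(self, form, expected):
        p = ModelParams(tradeoff_form=form)
        assert transmission_rate(0.01, p) == pytest.approx(expected, rel=1e-12)

    def test_negative_virulence_rejected(self, default_params):
        with pytest.raises(ValidationError):
            transmission_rate(-0.1, default_params)

    def test_negative_constants_rejected(self):
        with pytest.raises(ValidationError):
            ModelParams(cA=-1.0)

    def test_default_form_increasing_and_concave(self, default_params):
        """beta(alpha) must rise with diminishing returns on a dense grid."""
        a = np.linspace(0.0, 1.0, 201)
        b = transmission_rate(a, default_params)
        assert np.all(np.diff(b) > 0)
        assert np.all(np.diff(b, 2) < 0)


class TestParams:
    def test_season_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="T1"):
            ModelParams(T1=0.6, T2=0.5)

    def test_virulence_must_increase_across_strains(self):
        with pytest.raises(ValidationError):
            ModelParams(alpha=(0.1, 0.05, 0.01))

    def test_migration_cost_must_be_a_fraction(self):
        with pytest.raises(ValidationError):
            ModelParams(delta_I=1.0)

    def test_default_migratory_recovery_offset(self):
        assert float(ModelParams(nu1=0.14).nu2) == pytest.approx(0.26)

    def test_yaml_round_trip(self, default_params, tmp_path):
        path = tmp_path / "params.yaml"
        default_params.to_yaml(path)
        loaded = ModelParams.from_yaml(path)
        assert loaded == default_params

    def test_unknown_key_rejected(self):
        with pytest.raises(ValidationError, match="bogus"):
            ModelParams.from_dict({"bogus": 1.0})

    def test_carrying_capacity_from_density_dependence(self, default_params):
        assert carrying_capacity(default_params) == pytest.approx(10000.0)


class TestTotalPopulation:
    def test_uniform_initial_condition(self, uniform_state):
        assert total_population(uniform_state) == 1000.0

    @pytest.mark.parametrize(
        "state,expected",
        [(np.zeros(10), 0.0), (make_state(Sr=9999.5), 9999.5)],
    )
    def test_edge_sums(self, state, expected):
        assert total_population(state) == expected


class TestDerivativeFields:
    def test_zero_state_is_fixed(self, default_params):
        z = np.zeros(10)
        assert np.all(rhs_shared_habitat(z, default_params) == 0)
        assert np.all(rhs_separate_habitats(z, default_params) == 0)

    def test_shared_susceptible_growth(self, default_params):
        # Sr=100 alone: births 2*100*(1-0.01) minus deaths 0.14*100
        d = rhs_shared_habitat(make_state(Sr=100.0), default_params)
        assert d[0] == pytest.approx(184.0, rel=1e-12)
        assert np.all(d[1:] == 0)

    def test_shared_immunity_loss_flow(self, default_params):
        p = default_params.replace(mu=0.5)
        d = rhs_shared_habitat(make_state(Rr=100.0), p)
        assert d[0] == pytest.approx(248.0, rel=1e-12)  # 0.5*100 + 2*100*0.99
        assert d[4] == pytest.approx(-64.0, rel=1e-12)  # -(0.5+0.14)*100

    def test_separate_season_has_no_births(self, default_params):
        d = rhs_separate_habitats(make_state(Sr=100.0), default_params)
        assert d[0] == pytest.approx(-14.0, rel=1e-12)

    def test_separate_migrant_recovery_uses_habitat2_rate(self, default_params):
        # Im1=100, nu2=0.26, alpha1=0.01: outflow (0.26+0.14+0.01)*100
        d = rhs_separate_habitats(make_state(Im1=100.0), default_params)
        assert d[6] == pytest.approx(-41.0, rel=1e-12)
        assert d[9] == pytest.approx(26.0, rel=1e-12)

    def test_disease_free_subspace_invariant(self, default_params):
        state = make_state(Sr=500.0, Sm=300.0)
        for rhs in (rhs_shared_habitat, rhs_separate_habitats):
            d = rhs(state, default_params)
            assert np.all(d[1:5] == 0) and np.all(d[6:] == 0)

    @pytest.mark.parametrize("mu", [0.0, 0.3, 20.0])
    def test_matches_scalar_transcription_oracle(
        self, random_states, default_params, mu
    ):
        """Vectorized fields agree with an independent scalar transcription
        of the seasonal equations at 100 random states."""
        p = default_params.replace(mu=mu)
        for y in random_states:
            got = rhs_shared_habitat(y, p)
            want = np.array(oracles.naive_rhs_shared(y, p))
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)
            got = rhs_separate_habitats(y, p)
            want = np.array(oracles.naive_rhs_separate(y, p))
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_batched_matches_unbatched(self, random_states, default_params):
        batch = random_states[:8].T  # (10, 8)
        got = rhs_shared_habitat(batch, default_params)
        for k in range(8):
            np.testing.assert_allclose(
                got[:, k], rhs_shared_habitat(batch[:, k], default_params), rtol=1e-12
            )


class TestMigrationPulse:
    def test_zero_cost_is_identity(self, uniform_state, default_params):
        p = default_params.replace(delta_S=0.0, delta_I=0.0, delta_R=0.0)
        np.testing.assert_array_equal(
            apply_migration_pulse(uniform_state, p), uniform_state
        )

    def test_costs_hit_the_right_classes(self, default_params):
        y = apply_migration_pulse(make_state(Sm=100.0, Sr=100.0), default_params)
        assert y[5] == pytest.approx(99.9)
        assert y[0] == 100.0  # residents untouched

    def test_infected_migrant_culling(self, default_params):
        y = apply_migration_pulse(make_state(Im1=200.0), default_params)
        assert y[6] == pytest.approx(199.2)  # delta_I = 4 * delta_S = 0.004

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1e4), min_size=10, max_size=10))
    def test_never_increases_and_preserves_residents(self, values):
        y = np.array(values)
        out = apply_migration_pulse(y, ModelParams())
        assert np.all(out <= y + 1e-12)
        np.testing.assert_array_equal(out[:5], y[:5])
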