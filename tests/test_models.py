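"""The 7-state loss process and its model families."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

import trifrac as tf
from trifrac.models import (
    TRANSITION_NAMES,
    free_param_names,
    loss_flux,
    model_from_vector,
    relabel,
    state_permutation,
)

from conftest import ARB_RATES, arb_model, all_free_params

rates_strategy = st.lists(
    st.floats(0.05, 5.0, allow_nan=False), min_size=8, max_size=8
)


def _arb(values) -> tf.LossModel:
    return tf.build_model(
        "arb", dict(zip([f"rho_{n}" for n in TRANSITION_NAMES[1:]], values))
    )


class TestFamilies:
    def test_null_materialisation(self):
        m = tf.build_model("null", {"sigma": 0.5})
        assert m.rho[:3] == (1.0, 1.0, 1.0)
        assert m.rho[3:] == (0.5,) * 6

    def test_neutral_1d_equals_null(self):
        null = tf.build_model("null", {"sigma": 0.7})
        one = tf.build_model("1d", {"sigma": 0.7, "f_T": 1.0, "f_D": 1.0})
        assert null.rho == one.rho

    def test_arb_materialises_input(self):
        m = arb_model()
        assert m.rho[0] == 1.0
        assert m.rho[1] == ARB_RATES["rho_T>D_LF.MF"]

    def test_family_nesting_chain(self):
        """Every family instance is representable in the next richer family
        with an identical rate matrix."""
        m1 = tf.build_model("1d", {"sigma": 0.9, "f_T": 0.5, "f_D": 0.7})
        m3 = tf.build_model(
            "3g", {"sigma": 0.9, "f_T": 0.5, "f_D": 0.7, "g_T": 1.0, "g_D": 1.0}
        )
        assert m1.rho == m3.rho
        arb = tf.build_model(
            "arb", {f"rho_{n}": r for n, r in zip(TRANSITION_NAMES[1:], m3.rho[1:])}
        )
        assert np.allclose(tf.rate_matrix(m3), tf.rate_matrix(arb))

    def test_free_parameter_ledger(self):
        counts = [
            tf.count_free_parameters(tf.build_model(f, all_free_params(f)))
            for f in ("null", "1d", "3g", "arb")
        ]
        assert counts == [1, 3, 5, 8]
        arr = tf.build_model(
            "arb", all_free_params("arb"), arrival=tf.Arrival("MF", 0.2)
        )
        assert tf.count_free_parameters(arr) - counts[3] == 2

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            tf.build_model("null", {"sigma": -0.1})
        with pytest.raises(ValueError):
            tf.build_model("null", {"sigma": 1.0}, root_params=all_free_params("arb"))
        with pytest.raises(ValueError):
            tf.Arrival("XX", 0.1)
        with pytest.raises(ValueError):
            tf.build_model("1d", {"sigma": 1.0})  # missing f_T, f_D


class TestTransitionMatrix:
    def test_u_zero_is_identity(self):
        assert np.allclose(tf.transition_matrix(arb_model(), 0.0), np.eye(7))

    @pytest.mark.parametrize("u", [0.05, 0.3, 1.0, 3.0])
    def test_null_t_to_t_closed_form(self, u):
        m = tf.build_model("null", {"sigma": 0.6})
        P = tf.transition_matrix(m, u)
        assert P[0, 0] == pytest.approx(np.exp(-3 * u), abs=1e-10)

    def test_matches_series_expansion(self):
        """Truncated-series matrix exponential as an independent oracle."""
        m = arb_model()
        Q = tf.rate_matrix(m)
        u = 0.4
        series = np.eye(7)
        term = np.eye(7)
        for k in range(1, 60):
            term = term @ (Q * u) / k
            series = series + term
        assert np.allclose(tf.transition_matrix(m, u), series, atol=1e-12)

    def test_rows_stochastic_and_absorbing(self):
        P = tf.transition_matrix(arb_model(), 50.0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert P[:, 4:].sum(axis=1)[0] >= 1 - 1e-6  # everything ends single-copy
        assert np.allclose(P[4:, 4:], np.eye(3))

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            tf.transition_matrix(arb_model(), -0.1)

    @settings(max_examples=25, deadline=None)
    @given(rates_strategy, st.floats(0.01, 2.0), st.floats(0.01, 2.0))
    def test_chapman_kolmogorov(self, rates, u1, u2):
        m = _arb(rates)
        P1, P2 = tf.transition_matrix(m, u1), tf.transition_matrix(m, u2)
        P12 = tf.transition_matrix(m, u1 + u2)
        assert np.allclose(P1 @ P2, P12, atol=1e-10)


class TestRootDistribution:
    def test_non_arrival_point_mass_on_T(self):
        assert np.allclose(tf.root_distribution(arb_model()), np.eye(7)[0])

    def test_zero_length_phase_collapses(self):
        m = tf.build_model("null", {"sigma": 1.0}, arrival=tf.Arrival("LF", 0.0))
        assert np.allclose(tf.root_distribution(m), np.eye(7)[0])

    def test_three_state_founder_chain_oracle(self):
        """MF-last arrival: founders LF, IF evolve in a 3-state chain for
        tau, then map onto {T, D_LF.MF, D_IF.MF}."""
        tau, kappa = 0.2, 1.0
        m = tf.build_model("null", {"sigma": 1.0}, arrival=tf.Arrival("MF", tau, kappa))
        # 3-state generator over (D_LF.IF, S_LF, S_IF): both loss rates sigma=1
        G = np.array([[-2.0, 1.0, 1.0], [0, 0, 0], [0, 0, 0]]) * kappa
        p3 = expm(G * tau)[0]
        pi = tf.root_distribution(m)
        assert pi[0] == pytest.approx(p3[0], abs=1e-12)  # D_LF.IF -> T
        assert pi[2] == pytest.approx(p3[1], abs=1e-12)  # S_LF -> D_LF.MF
        assert pi[3] == pytest.approx(p3[2], abs=1e-12)  # S_IF -> D_IF.MF
        assert pi.sum() == pytest.approx(1.0)

    def test_asymmetric_phase_rates(self):
        m = arb_model(arrival=tf.Arrival("MF", 0.5, 2.0))
        r_lf = ARB_RATES["rho_D_LF.IF>S_LF"] * 2.0
        r_if = ARB_RATES["rho_D_LF.IF>S_IF"] * 2.0
        stay = np.exp(-(r_lf + r_if) * 0.5)
        pi = tf.root_distribution(m)
        assert pi[0] == pytest.approx(stay, abs=1e-12)
        assert pi[2] / pi[3] == pytest.approx(r_lf / r_if, rel=1e-9)


class TestRelabeling:
    @settings(max_examples=20, deadline=None)
    @given(rates_strategy, st.permutations([0, 1, 2]))
    def test_relabel_preserves_spectrum_and_flux(self, rates, perm):
        m = _arb(rates)
        m2 = relabel(m, tuple(perm))
        flux = loss_flux(m.rho)
        flux2 = loss_flux(m2.rho)
        for old in range(3):
            assert flux2[perm[old]] == pytest.approx(flux[old])
        # Q is the same matrix under the induced state permutation
        sp = state_permutation(tuple(perm))
        Q, Q2 = tf.rate_matrix(m), tf.rate_matrix(m2)
        assert np.allclose(Q2[np.ix_(sp, sp)], Q)

    def test_vector_round_trip(self):
        names = free_param_names("arb", arrival=True)
        vec = list(ARB_RATES.values()) + [0.3, 1.5]
        m = model_from_vector("arb", vec, arrival_last="MF")
        assert m.arrival.tau == 0.3
        assert m.rho[1:] == tuple(ARB_RATES.values())
        assert len(names) == len(vec)


def test_rates_tsv_and_dict_round_trip(tmp_path):
    from trifrac.models import model_from_dict, model_to_dict, write_rates_tsv

    m = arb_model(arrival=tf.Arrival("MF", 0.25, 1.4))
    m2 = model_from_dict(model_to_dict(m))
    assert m2.rho == m.rho and m2.arrival == m.arrival
    path = tmp_path / "rates.tsv"
    write_rates_tsv(m, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "parameter\tvalue"
    assert any(line.startswith("tau\t0.25") for line in lines)
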