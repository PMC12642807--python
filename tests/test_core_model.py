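"""Exact encoding of the exchange fluxes, system RHS, and regime algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import symbiovade as sv
from symbiovade.core_model import swap_state

from conftest import draw_model_params, draw_reduced_params, draw_state


def eval_fluxes_by_hand(state, p):
    """Independent term-by-term evaluation of the four net flux functions."""
    p_n, m_n, p_i, m_i = state
    D_a = (p_n + p_i) / p.d + m_n + m_i
    D_b = p_n + p_i + p.d * (m_n + m_i)
    F_pn = (p.q_hpn * p_n * (p.alpha_nn * m_n + p.alpha_in * m_i) / D_a
            - p.q_cpn * p_n * (p.beta_nn * m_n + p.beta_ni * m_i) / D_b)
    F_mn = (p.q_cmn * m_n * (p.beta_nn * p_n + p.beta_in * p_i) / D_b
            - p.q_hmn * m_n * (p.alpha_nn * p_n + p.alpha_ni * p_i) / D_a)
    F_pi = (p.q_hpi * p_i * (p.alpha_ii * m_i + p.alpha_ni * m_n) / D_a
            - p.q_cpi * p_i * (p.beta_ii * m_i + p.beta_in * m_n) / D_b)
    F_mi = (p.q_cmi * m_i * (p.beta_ii * p_i + p.beta_ni * p_n) / D_b
            - p.q_hmi * m_i * (p.alpha_ii * p_i + p.alpha_in * p_n) / D_a)
    return np.array([F_pn, F_mn, F_pi, F_mi])


class TestExchangeFluxes:
    def test_all_zero_state_gives_zero_fluxes(self, defaults):
        fl = sv.exchange_fluxes((0, 0, 0, 0), defaults)
        assert fl.net.tolist() == [0, 0, 0, 0]
        assert not fl.kernel_alpha.any() and not fl.kernel_beta.any()

    def test_unit_example(self):
        ones = {k: 1.0 for k in ModelParamsExchangeFields}
        p = sv.ModelParams(**ones, d=1.0)
        fl = sv.exchange_fluxes((1, 1, 0, 0), p)
        assert fl.gain_p_n == pytest.approx(0.5, abs=1e-15)

    def test_aggregate_equals_independent_evaluation(self, rng):
        for _ in range(200):
            p = draw_model_params(rng)
            state = draw_state(rng)
            fl = sv.exchange_fluxes(state, p)
            np.testing.assert_allclose(fl.net, eval_fluxes_by_hand(state, p), rtol=1e-12)

    def test_aggregate_is_q_times_kernel_sum(self, rng):
        for _ in range(100):
            p = draw_model_params(rng)
            fl = sv.exchange_fluxes(draw_state(rng), p)
            ka, kb = fl.kernel_alpha, fl.kernel_beta
            assert fl.gain_p_n == pytest.approx(p.q_hpn * (ka[0, 0] + ka[1, 0]), rel=1e-13)
            assert fl.cost_p_i == pytest.approx(p.q_cpi * (kb[1, 0] + kb[1, 1]), rel=1e-13)
            assert fl.gain_m_i == pytest.approx(p.q_cmi * (kb[0, 1] + kb[1, 1]), rel=1e-13)
            assert fl.cost_m_n == pytest.approx(p.q_hmn * (ka[0, 0] + ka[0, 1]), rel=1e-13)

    def test_per_pair_conservation(self, rng):
        """What host j pays along beta_jk (per unit cost efficiency) is what
        symbiont k receives (per unit benefit efficiency), pair by pair."""
        q_cp = {"n": "q_cpn", "i": "q_cpi"}
        q_cm = {"n": "q_cmn", "i": "q_cmi"}
        q_hp = {"n": "q_hpn", "i": "q_hpi"}
        q_hm = {"n": "q_hmn", "i": "q_hmi"}
        idx = {"n": 0, "i": 1}
        for _ in range(200):
            p = draw_model_params(rng)
            state = draw_state(rng)
            p_n, m_n, p_i, m_i = state
            D_b = p_n + p_i + p.d * (m_n + m_i)
            D_a = (p_n + p_i) / p.d + m_n + m_i
            hosts = {"n": p_n, "i": p_i}
            syms = {"n": m_n, "i": m_i}
            for j in "ni":
                for k in "ni":
                    beta_jk = getattr(p, f"beta_{j}{k}")
                    alpha_jk = getattr(p, f"alpha_{j}{k}")
                    # host-j cost and symbiont-k gain attributable to beta_jk
                    cost = getattr(p, q_cp[j]) * hosts[j] * beta_jk * syms[k] / D_b
                    gain = getattr(p, q_cm[k]) * syms[k] * beta_jk * hosts[j] / D_b
                    assert cost / getattr(p, q_cp[j]) == pytest.approx(
                        gain / getattr(p, q_cm[k]), rel=1e-12)
                    # and the mirror identity for the alpha_jk kernel
                    sgain = getattr(p, q_hp[k]) * hosts[k] * alpha_jk * syms[j] / D_a
                    scost = getattr(p, q_hm[j]) * syms[j] * alpha_jk * hosts[k] / D_a
                    assert sgain / getattr(p, q_hp[k]) == pytest.approx(
                        scost / getattr(p, q_hm[j]), rel=1e-12)
                    # both match the FluxSet kernels
                    fl = sv.exchange_fluxes(state, p)
                    assert fl.kernel_beta[idx[j], idx[k]] == pytest.approx(
                        beta_jk * hosts[j] * syms[k] / D_b, rel=1e-12)
                    assert fl.kernel_alpha[idx[j], idx[k]] == pytest.approx(
                        alpha_jk * syms[j] * hosts[k] / D_a, rel=1e-12)

    def test_subscript_convention_alpha_in(self, rng):
        """Zeroing alpha_in removes the invasive-symbiont->native-host supply
        from the native host's gain and the invasive symbiont's cost, and
        nothing else."""
        p = draw_model_params(rng)
        p0 = p.replace(alpha_in=0.0)
        state = draw_state(rng)
        fl, fl0 = sv.exchange_fluxes(state, p), sv.exchange_fluxes(state, p0)
        assert fl.gain_p_n > fl0.gain_p_n
        assert fl.cost_m_i > fl0.cost_m_i
        for name in ("cost_p_n", "gain_m_n", "cost_m_n", "gain_p_i", "cost_p_i", "gain_m_i"):
            assert getattr(fl, name) == getattr(fl0, name)

    def test_negative_state_rejected(self, defaults):
        with pytest.raises(ValueError, match="nonnegative"):
            sv.exchange_fluxes((1, -0.1, 0, 0), defaults)

    def test_saturation_bound_on_gains(self, rng):
        """Each gain flux is capped by q x (largest coefficient) x receiver
        biomass: supply cannot exceed what the receiving pool can absorb."""
        for _ in range(100):
            p = draw_model_params(rng)
            p_n, m_n, p_i, m_i = state = draw_state(rng)
            fl = sv.exchange_fluxes(state, p)
            a_max = max(p.alpha_nn, p.alpha_ni, p.alpha_in, p.alpha_ii)
            b_max = max(p.beta_nn, p.beta_ni, p.beta_in, p.beta_ii)
            assert fl.gain_p_n <= p.q_hpn * a_max * p_n * (1 + 1e-12)
            assert fl.gain_p_i <= p.q_hpi * a_max * p_i * (1 + 1e-12)
            assert fl.gain_m_n <= p.q_cmn * b_max * m_n * (1 + 1e-12)
            assert fl.gain_m_i <= p.q_cmi * b_max * m_i * (1 + 1e-12)


class TestFullRhs:
    def test_extinction_is_equilibrium(self, defaults):
        np.testing.assert_array_equal(sv.full_rhs((0, 0, 0, 0), defaults), np.zeros(4))

    def test_lone_host_logistic_term(self):
        p = sv.ModelParams(r_pn=1.0, mu_pn=0.5)
        np.testing.assert_allclose(sv.full_rhs((1, 0, 0, 0), p), [0.5, 0, 0, 0], atol=1e-15)

    def test_compositional_assembly(self, rng):
        """RHS is exactly growth + net flux - competition - self-limitation."""
        for _ in range(100):
            p = draw_model_params(rng)
            s = draw_state(rng)
            fl = sv.exchange_fluxes(s, p)
            expected = fl.net + np.array(
                [
                    p.r_pn * s[0] - p.c_p_in * s[0] * s[2] - p.mu_pn * s[0] ** 2,
                    -p.c_m_in * s[1] * s[3] - p.mu_mn * s[1] ** 2,
                    p.r_pi * s[2] - p.c_p_ni * s[0] * s[2] - p.mu_pi * s[2] ** 2,
                    -p.c_m_ni * s[1] * s[3] - p.mu_mi * s[3] ** 2,
                ]
            )
            np.testing.assert_allclose(sv.full_rhs(s, p), expected, rtol=1e-12, atol=1e-15)


class TestReducedSystem:
    def test_origin_is_equilibrium(self):
        rp = draw_reduced_params(np.random.default_rng(0))
        np.testing.assert_array_equal(sv.reduced_rhs((0, 0), rp), np.zeros(2))

    def test_direct_arithmetic_example(self):
        # p=m=1, d=1, Q_p=0.1: dp/dt = 1 + 0.5*0.1 - 1 = 0.05
        rp = sv.ReducedParams(r_p=1, q_hp=1, q_cp=1, q_cm=1, q_hm=1,
                              alpha=0.6, beta=0.5, mu_p=1, mu_m=1, d=1)
        assert sv.compute_Q(rp).Q_p == pytest.approx(0.1)
        assert sv.reduced_rhs((1, 1), rp)[0] == pytest.approx(0.05)

    def test_restriction_equivalence_identity_at_unit_d(self, rng):
        for _ in range(50):
            p = draw_model_params(rng, d=1.0)
            rp = sv.reduced_from_full(p, "native")
            state = draw_state(rng, 2)
            full = sv.full_rhs((state[0], state[1], 0, 0), p)
            np.testing.assert_allclose(
                sv.reduced_rhs(state, rp), full[:2], rtol=1e-12, atol=1e-15)
            assert rp.alpha == p.alpha_nn and rp.beta == p.beta_nn

    @pytest.mark.parametrize("community", ["native", "invasive"])
    def test_restriction_equivalence_any_d(self, rng, community):
        """The reduced system equals the full system restricted to one pair
        for every biomass-adjustment factor (via the d-rescaled mapping)."""
        sl = slice(0, 2) if community == "native" else slice(2, 4)
        for _ in range(50):
            p = draw_model_params(rng)
            rp = sv.reduced_from_full(p, community)
            s2 = draw_state(rng, 2)
            full_state = np.zeros(4)
            full_state[sl] = s2
            np.testing.assert_allclose(
                sv.reduced_rhs(s2, rp), sv.full_rhs(full_state, p)[sl],
                rtol=1e-12, atol=1e-15)

    def test_small_invader_percapita_rate_tends_to_d_Qm(self, rng):
        """As m -> 0 at fixed p, the symbiont's per-capita growth approaches
        d*Q_m (the interaction term behaves as d*m)."""
        for _ in range(20):
            rp = draw_reduced_params(rng, d=float(rng.uniform(0.5, 2.0)))
            Q_m = sv.compute_Q(rp).Q_m
            if abs(Q_m) < 1e-3:
                continue
            pstar = 1.3
            m = 1e-8 * pstar
            rate = sv.reduced_rhs((pstar, m), rp)[1] / m
            assert rate == pytest.approx(rp.d * Q_m, rel=1e-4)


class TestRegimeAlgebra:
    @pytest.mark.parametrize(
        "q, expected",
        [
            ((0.1, 0.2), sv.InteractionRegime.MUTUALISTIC),
            ((-0.1, 0.2), sv.InteractionRegime.PARASITIC_FOR_HOST),
            ((0.1, -0.2), sv.InteractionRegime.PARASITIC_FOR_SYMBIONT),
            ((0.0, 0.2), sv.InteractionRegime.COMMENSAL_HOST),
            ((0.1, 0.0), sv.InteractionRegime.COMMENSAL_SYMBIONT),
            ((0.0, 0.0), sv.InteractionRegime.NEUTRAL),
            ((1e-14, -1e-14), sv.InteractionRegime.NEUTRAL),
            ((-0.1, -0.2), sv.InteractionRegime.INVALID_EXCHANGE),
        ],
    )
    def test_sign_table(self, q, expected):
        assert sv.classify_regime(sv.QPair(*q)) is expected

    def test_compute_Q_examples(self):
        rp = sv.ReducedParams(r_p=1, q_hp=2, q_cp=1, q_cm=1, q_hm=1,
                              alpha=0.4, beta=0.3, mu_p=1, mu_m=1, d=2)
        assert sv.compute_Q(rp).Q_p == pytest.approx(0.1)
        rp0 = sv.ReducedParams(r_p=1, q_hp=2, q_cp=1, q_cm=1, q_hm=1,
                               alpha=0.0, beta=0.0, mu_p=1, mu_m=1, d=2)
        assert sv.compute_Q(rp0) == (0.0, 0.0)
        rp_b = sv.ReducedParams(r_p=1, q_hp=1, q_cp=1, q_cm=1, q_hm=1,
                                alpha=0.5, beta=0.5, mu_p=1, mu_m=1, d=1)
        assert sv.compute_Q(rp_b) == (0.0, 0.0)

    @given(Q_p=st.floats(-5, 5), Q_m=st.floats(-5, 5))
    @settings(max_examples=200, derandomize=True)
    def test_classification_is_pure_sign_function(self, Q_p, Q_m):
        regime = sv.classify_regime(sv.QPair(Q_p, Q_m))
        regime2 = sv.classify_regime(sv.QPair(2 * Q_p, 2 * Q_m))
        if min(abs(Q_p), abs(Q_m)) > 1e-12:  # away from the tolerance band
            assert regime is regime2

    def test_cross_pair_examples(self):
        ones = {k: 1.0 for k in ModelParamsExchangeFields}
        p = sv.ModelParams(**{**ones, "alpha_in": 1.0, "beta_ni": 0.1,
                              "alpha_ni": 0.0, "beta_in": 0.0}, d=1.0)
        assert sv.cross_pair_regimes(p).pn_mi is sv.InteractionRegime.PARASITIC_FOR_SYMBIONT
        assert sv.scenario_id(p) == "7"

        p2 = sv.ModelParams(**{**ones, "alpha_in": 0.0, "beta_ni": 0.0,
                               "alpha_ni": 0.0, "beta_in": 0.0})
        assert sv.cross_pair_regimes(p2).pn_mi is sv.InteractionRegime.NEUTRAL

        p3 = sv.ModelParams(q_hpn=2, q_cpn=1, q_cmi=2, q_hmi=1, d=1,
                            alpha_in=1.0, beta_ni=1.0)
        assert sv.cross_pair_regimes(p3).pn_mi is sv.InteractionRegime.MUTUALISTIC

    def test_regimes_match_bruteforce_inequalities(self, rng):
        """classify_regime(compute_Q) agrees with direct sign evaluation of
        the two boundary inequalities on random draws."""
        for _ in range(2000):
            p = draw_model_params(rng)
            cross = sv.cross_pair_regimes(p)
            # (p_n, m_i) edge
            Qp = p.q_hpn * p.alpha_in / p.d - p.q_cpn * p.beta_ni
            Qm = p.q_cmi * p.beta_ni - p.q_hmi * p.alpha_in / p.d
            if Qp > 1e-12 and Qm > 1e-12:
                assert cross.pn_mi is sv.InteractionRegime.MUTUALISTIC
            elif Qp < -1e-12 and Qm > 1e-12:
                assert cross.pn_mi is sv.InteractionRegime.PARASITIC_FOR_HOST
            elif Qp > 1e-12 and Qm < -1e-12:
                assert cross.pn_mi is sv.InteractionRegime.PARASITIC_FOR_SYMBIONT
            # (p_i, m_n) edge
            Qp = p.q_hpi * p.alpha_ni / p.d - p.q_cpi * p.beta_in
            Qm = p.q_cmn * p.beta_in - p.q_hmn * p.alpha_ni / p.d
            if Qp > 1e-12 and Qm > 1e-12:
                assert cross.pi_mn is sv.InteractionRegime.MUTUALISTIC
            elif Qp < -1e-12 and Qm > 1e-12:
                assert cross.pi_mn is sv.InteractionRegime.PARASITIC_FOR_HOST
            elif Qp > 1e-12 and Qm < -1e-12:
                assert cross.pi_mn is sv.InteractionRegime.PARASITIC_FOR_SYMBIONT


class TestScenarioId:
    def test_no_shared_partners_is_scenario_1(self, defaults):
        assert sv.scenario_id(defaults) == "1"

    def test_single_active_edges(self, defaults):
        # (p_i, m_n) mutualistic only -> scenario 2
        p = defaults.replace(alpha_ni=1.0, beta_in=1.0)
        assert sv.scenario_id(p) == "2"
        # (p_n, m_i) mutualistic only -> scenario 3
        p = defaults.replace(alpha_in=1.0, beta_ni=1.0)
        assert sv.scenario_id(p) == "3"

    def test_combined_label(self, defaults):
        # pi_mn mutualistic AND pn_mi parasitic for the (native) host
        p = defaults.replace(alpha_ni=1.0, beta_in=1.0, alpha_in=0.1, beta_ni=1.5)
        assert sv.scenario_id(p) == "(2,6)"


class TestParamsValidation:
    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError, match="mu_pn"):
            sv.ModelParams(mu_pn=-1.0)

    def test_zero_d_rejected(self):
        with pytest.raises(ValueError, match="d"):
            sv.ModelParams(d=0.0)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            sv.ModelParams.from_dict({"r_pn": 1.0, "bogus": 2.0})

    def test_swap_is_involution_and_mirrors_regimes(self, rng):
        p = draw_model_params(rng)
        assert sv.swap_communities(sv.swap_communities(p)) == p
        cross, cross_sw = sv.cross_pair_regimes(p), sv.cross_pair_regimes(sv.swap_communities(p))
        assert cross.pn_mi is cross_sw.pi_mn and cross.pi_mn is cross_sw.pn_mi

    def test_swap_state_roundtrip(self):
        np.testing.assert_array_equal(swap_state(swap_state((1, 2, 3, 4))), [1, 2, 3, 4])


# exchange-coefficient and conversion-efficiency field names used by the
# all-ones fixtures above
ModelParamsExchangeFields = (
    "alpha_nn", "alpha_ni", "alpha_in", "alpha_ii",
    "beta_nn", "beta_ni", "beta_in", "beta_ii",
    "q_hpn", "q_cpn", "q_hpi", "q_cpi", "q_cmn", "q_hmn", "q_cmi", "q_hmi",
)
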