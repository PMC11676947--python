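import numpy as np
import pytest

from thalmf.transfer import (COEFF_NAMES, TFCoefficients, TransferFunctionModel,
                             conductance_moments, default_rate_grid,
                             effective_threshold, fit_transfer_function,
                             membrane_moments, sample_single_cell_rates,
                             stationary_adaptation, transfer_rate)


class TestConductanceMoments:
    def test_zero_rates_leave_only_the_leak(self, ic_tc, tc_awake):
        muGe, muGi, sGe, sGi, muG = conductance_moments(0.0, 0.0, ic_tc)
        assert muGe == muGi == sGe == sGi == 0.0
        assert muG == tc_awake.gL

    def test_mean_conductance_spot_value(self, ic_tc):
        # nu K tau Q = 10 * 25 * 0.005 * 1 = 1.25 nS
        muGe, _, _, _, muG = conductance_moments(10.0, 0.0, ic_tc)
        assert muGe == pytest.approx(1.25)
        assert muG == pytest.approx(11.25)

    def test_conductance_sd_spot_value(self, ic_tc):
        # Q sqrt(nu K tau / 2) = sqrt(0.625) ~ 0.79 nS
        _, _, sGe, _, _ = conductance_moments(10.0, 0.0, ic_tc)
        assert sGe == pytest.approx(np.sqrt(0.625), rel=1e-12)

    def test_negative_rates_rejected(self, ic_tc):
        with pytest.raises(ValueError):
            conductance_moments(-1.0, 0.0, ic_tc)


class TestMembraneMoments:
    def test_rest_without_input(self, ic_tc, tc_awake):
        m = membrane_moments(0.0, 0.0, 0.0, ic_tc)
        assert float(m.muV) == pytest.approx(tc_awake.EL)
        assert float(m.sigmaV) == 0.0
        # degenerate-limit convention: tau_m + max(tau_e, tau_i)
        assert float(m.tauV) == pytest.approx(tc_awake.tau_m + 5.0)

    def test_mean_potential_spot_value(self, ic_tc):
        # (muGe*Ee + gL*EL) / muG = (0 - 650) / 11.25 ~ -57.78 mV
        m = membrane_moments(10.0, 0.0, 0.0, ic_tc)
        assert float(m.muV) == pytest.approx(-650.0 / 11.25, rel=1e-9)

    def test_adaptation_current_hyperpolarizes(self, ic_tc):
        m0 = membrane_moments(10.0, 0.0, 0.0, ic_tc)
        m1 = membrane_moments(10.0, 0.0, 50.0, ic_tc)
        assert float(m1.muV) < float(m0.muV)

    def test_muv_is_a_convex_combination_of_reversals(self, ic_tc, tc_awake):
        for ne, ni in [(5.0, 5.0), (50.0, 20.0), (200.0, 40.0)]:
            m = membrane_moments(ne, ni, 0.0, ic_tc)
            assert tc_awake.Ei <= float(m.muV) <= tc_awake.Ee

    def test_tauv_single_weak_input_limit(self, ic_tc, tc_awake):
        """As nu_e -> 0 with one synaptic class, tauV -> tau_m + tau_e."""
        m = membrane_moments(1e-9, 0.0, 0.0, ic_tc)
        assert float(m.tauV) == pytest.approx(tc_awake.tau_m + tc_awake.tau_e,
                                              rel=1e-4)

    def test_static_conductances_shift_and_shunt(self, ic_tc):
        m0 = membrane_moments(10.0, 0.0, 0.0, ic_tc)
        m1 = membrane_moments(10.0, 0.0, 0.0, ic_tc, static_gi=10.0)
        assert float(m1.muV) < float(m0.muV)      # pulled toward Ei
        assert float(m1.muG) > float(m0.muG)      # shunted
        assert float(m1.sigmaV) < float(m0.sigmaV)


class TestEffectiveThreshold:
    def test_constant_polynomial(self, ic_tc):
        coeffs = TFCoefficients(P=np.r_[-45.0, np.zeros(9)])
        m = membrane_moments(50.0, 10.0, 0.0, ic_tc)
        assert float(effective_threshold(m, coeffs)) == pytest.approx(-45.0)

    def test_value_at_normalization_center_is_p0(self, tf_tc):
        class M:   # moments exactly at the center of the normalized regime
            muV, sigmaV, tauVN = -60.0, 4.0, 0.5
        assert float(effective_threshold(M, tf_tc)) == pytest.approx(tf_tc.P[0])

    def test_matches_independent_polynomial_evaluation(self, tf_tc):
        """Hand-computed 10-term sum over the saturating normalized features."""
        muV, sigmaV, tauVN = -50.0, 10.0, 1.5
        clip = tf_tc.norm.get("clip", 3.0)
        xm = clip * np.tanh(((muV + 60.0) / 10.0) / clip)
        xs = clip * np.tanh(((sigmaV - 4.0) / 6.0) / clip)
        xt = clip * np.tanh(((tauVN - 0.5) / 1.0) / clip)
        P = tf_tc.P
        expected = (P[0] + P[1] * xm + P[2] * xs + P[3] * xt
                    + P[4] * xm**2 + P[5] * xm * xs + P[6] * xm * xt
                    + P[7] * xs**2 + P[8] * xs * xt + P[9] * xt**2)

        class M:
            pass
        M.muV, M.sigmaV, M.tauVN = muV, sigmaV, tauVN
        assert float(effective_threshold(M, tf_tc)) == pytest.approx(expected,
                                                                     rel=1e-12)

    def test_requires_ten_finite_amplitudes(self):
        with pytest.raises(ValueError):
            TFCoefficients(P=np.zeros(9))
        with pytest.raises(ValueError):
            TFCoefficients(P=np.r_[np.nan, np.zeros(9)])


class TestTransferRate:
    def test_rate_at_threshold_is_half_maximum(self, ic_tc):
        m = membrane_moments(20.0, 5.0, 0.0, ic_tc)
        coeffs = TFCoefficients(P=np.r_[float(m.muV), np.zeros(9)])
        rate = transfer_rate(20.0, 5.0, 0.0, coeffs, ic_tc)
        assert rate == pytest.approx(1.0 / (2 * float(m.tauV) * 1e-3), rel=1e-9)

    def test_bounded_by_inverse_tauv(self, tf_tc, ic_tc):
        for ne in np.geomspace(1.0, 400.0, 12):
            for ni in (0.0, 10.0, 40.0):
                m = membrane_moments(ne, ni, 0.0, ic_tc)
                rate = transfer_rate(ne, ni, 0.0, tf_tc, ic_tc)
                assert 0.0 <= rate <= 1.0 / (float(m.tauV) * 1e-3) + 1e-9

    def test_zero_sigma_gives_step_response(self, ic_tc, tc_awake):
        # no input -> sigmaV = 0: rate is a step at the threshold
        below = TFCoefficients(P=np.r_[-70.0, np.zeros(9)])   # thr below EL
        m = membrane_moments(0.0, 0.0, 0.0, ic_tc)
        assert transfer_rate(0.0, 0.0, 0.0, below, ic_tc) == pytest.approx(
            1.0 / (float(m.tauV) * 1e-3))
        above = TFCoefficients(P=np.r_[-60.0, np.zeros(9)])   # thr above EL
        assert transfer_rate(0.0, 0.0, 0.0, above, ic_tc) == 0.0

    @pytest.mark.parametrize("cell", ["TC", "RE"])
    def test_monotone_in_excitation_and_inhibition(self, cell, ic_tc, ic_re):
        """Grid-checked monotonicity across the fluctuation-driven regime
        (output below ~60 Hz; the fit is not trusted at very high rates)."""
        coeffs = TFCoefficients.reference(cell)
        ic = ic_tc if cell == "TC" else ic_re
        ne_grid = np.geomspace(2.0, 300.0, 10)
        for ni in (0.0, 10.0, 30.0):
            rates = np.asarray(transfer_rate(ne_grid, ni, 0.0, coeffs, ic))
            assert np.all(np.diff(rates) >= -1e-9)
        ne_vals = (20.0, 40.0) if cell == "TC" else (10.0, 30.0)
        for ne in ne_vals:
            rates = np.asarray(
                transfer_rate(ne, np.asarray([0.0, 10.0, 30.0, 60.0]), 0.0,
                              coeffs, ic))
            assert np.all(np.diff(rates) <= 1e-9)


def test_stationary_adaptation_closed_form_when_a_is_zero(ic_tc, tc_awake):
    # a = 0 (awake TC): w* = tau_w[s] * b * nu exactly
    w = stationary_adaptation(10.0, 20.0, 0.0, ic_tc)
    # the damped fixed-point iteration stops at its 0.01 pA tolerance
    assert w == pytest.approx(tc_awake.tau_w * 1e-3 * tc_awake.b * 10.0,
                              abs=0.02)


def test_stationary_adaptation_self_consistent_with_subthreshold_term(ic_re,
                                                                      re_awake):
    w = stationary_adaptation(5.0, 50.0, 10.0, ic_re)
    muV = float(membrane_moments(50.0, 10.0, w, ic_re).muV)
    expected = re_awake.tau_w * 1e-3 * re_awake.b * 5.0 + re_awake.a * (muV - re_awake.EL)
    assert w == pytest.approx(expected, abs=0.05)


class TestSampling:
    def test_zero_excitation_rows_are_silent(self, tc_awake, ic_tc):
        tab = sample_single_cell_rates(tc_awake, ic_tc, [(0.0, 0.0), (0.0, 10.0)],
                                       duration=500.0, reps=3, seed=1)
        assert np.all(tab["rate"] == 0.0)

    def test_rates_increase_with_excitation(self, tc_awake, ic_tc):
        grid = [(ne, 0.0) for ne in (10.0, 30.0, 60.0, 120.0)]
        tab = sample_single_cell_rates(tc_awake, ic_tc, grid, duration=2000.0,
                                       reps=8, seed=2)
        r = tab["rate"].to_numpy()
        tol = 2 * tab["sem"].to_numpy()
        assert np.all(np.diff(r) >= -(tol[:-1] + tol[1:]))

    def test_standard_error_follows_sqrt_law(self, tc_awake, ic_tc):
        small = sample_single_cell_rates(tc_awake, ic_tc, [(60.0, 0.0)],
                                         duration=1000.0, reps=8, seed=3)
        large = sample_single_cell_rates(tc_awake, ic_tc, [(60.0, 0.0)],
                                         duration=1000.0, reps=32, seed=3)
        ratio = small["sem"].iloc[0] / large["sem"].iloc[0]
        assert 1.2 < ratio < 3.4     # sqrt(4) = 2 within Monte-Carlo slack

    def test_empty_grid_rejected(self, tc_awake, ic_tc):
        with pytest.raises(ValueError):
            sample_single_cell_rates(tc_awake, ic_tc, [], duration=100.0, reps=1)


class TestFit:
    def _synthetic_table(self, coeffs, params, ic):
        """Noise-free rates generated by the transfer function itself
        (adaptation disabled so the stationary w is exactly zero)."""
        import pandas as pd
        grid = default_rate_grid(n_e=12)
        ne = np.asarray([g[0] for g in grid])
        ni = np.asarray([g[1] for g in grid])
        rate = np.asarray(transfer_rate(ne, ni, 0.0, coeffs, ic))
        return pd.DataFrame({"nu_e": ne, "nu_i": ni, "rate": rate})

    def test_recovers_known_coefficients(self, tf_tc, tc_awake, ic_tc):
        p = tc_awake.with_overrides(a=0.0, b=0.0)
        from thalmf.transfer import InputConnectivity
        ic = InputConnectivity(K_e=ic_tc.K_e, K_i=ic_tc.K_i, params=p)
        tab = self._synthetic_table(tf_tc, p, ic)
        res = fit_transfer_function(tab, p, ic)
        rel = np.linalg.norm(res.coeffs.P - tf_tc.P) / np.linalg.norm(tf_tc.P)
        assert rel < 0.01
        assert res.rmse < 0.5

    def test_constant_threshold_cell_yields_p0_only(self, tc_awake, ic_tc):
        p = tc_awake.with_overrides(a=0.0, b=0.0)
        from thalmf.transfer import InputConnectivity
        ic = InputConnectivity(K_e=ic_tc.K_e, K_i=ic_tc.K_i, params=p)
        const = TFCoefficients(P=np.r_[-48.0, np.zeros(9)])
        tab = self._synthetic_table(const, p, ic)
        res = fit_transfer_function(tab, p, ic)
        assert res.coeffs.P[0] == pytest.approx(-48.0, abs=0.05)
        assert np.all(np.abs(res.coeffs.P[1:]) < 0.1)

    def test_insufficient_active_points_rejected(self, tc_awake, ic_tc):
        import pandas as pd
        tab = pd.DataFrame({"nu_e": [1.0] * 40, "nu_i": [0.0] * 40,
                            "rate": [0.0] * 40})
        with pytest.raises(ValueError):
            TransferFunctionModel(tab, tc_awake, ic_tc).fit()

    def test_summary_reports_all_amplitudes(self, tf_tc, tc_awake, ic_tc):
        p = tc_awake.with_overrides(a=0.0, b=0.0)
        from thalmf.transfer import InputConnectivity
        ic = InputConnectivity(K_e=ic_tc.K_e, K_i=ic_tc.K_i, params=p)
        res = fit_transfer_function(self._synthetic_table(tf_tc, p, ic), p, ic)
        text = res.summary()
        for name in COEFF_NAMES:
            assert name in text
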