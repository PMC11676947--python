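import numpy as np
import pytest

from thalmf.meanfield import (MFConfig, MFState, NoisyConductances,
                              integrate_mf, mf_derivatives,
                              ou_conductance_noise, stationary_state)
from thalmf.stimuli import OUNoiseSpec
from thalmf.transfer import transfer_rate


@pytest.fixture(scope="module")
def awake_cfg():
    return MFConfig.from_state("awake")


@pytest.fixture(scope="module")
def awake_fp(awake_cfg):
    """Stationary point at the standard in-vivo-like drive P = 4 Hz."""
    return stationary_state((4.0, 0.0), awake_cfg, check_stability=False)


class TestDerivatives:
    def test_vanish_at_the_fixed_point(self, awake_cfg, awake_fp):
        dx = mf_derivatives(awake_fp.state, (4.0, 0.0), awake_cfg)
        assert np.max(np.abs(dx)) < 1e-6

    def test_negative_drives_rejected(self, awake_cfg):
        with pytest.raises(ValueError):
            mf_derivatives(MFState(), (-1.0, 0.0), awake_cfg)

    def test_finite_size_term_vanishes_for_large_networks(self, awake_cfg,
                                                          awake_fp):
        """A_mm ~ 1/N: the covariance source at the fixed point scales away."""
        from dataclasses import replace
        x = awake_fp.state.to_vector().copy()
        x[2:5] = 0.0   # strip covariances: dc/dt = A + (F-nu)^2 terms only
        small = mf_derivatives(x, (4.0, 0.0), awake_cfg)
        big_cfg = replace(awake_cfg, N_e=10**9, N_i=10**9)
        big = mf_derivatives(x, (4.0, 0.0), big_cfg)
        # the A-driven source dominates at N = 500 and scales away ~1/N
        # (a small residual from the covariance-corrected rate offset stays)
        assert abs(big[2]) < abs(small[2]) * 1e-2
        assert abs(big[4]) < abs(small[4]) * 1e-2

    def test_first_order_rates_match_bisection_oracle(self, awake_cfg):
        """With adaptation frozen (a=b=0) the first-order fixed point solves
        nu = F(nu); an independent nested bisection finds the same root."""
        from dataclasses import replace
        pe = awake_cfg.params_e.with_overrides(a=0.0, b=0.0)
        pi = awake_cfg.params_i.with_overrides(a=0.0, b=0.0)
        from thalmf.transfer import InputConnectivity
        cfg = replace(awake_cfg, params_e=pe, params_i=pi,
                      ic_e=InputConnectivity(K_e=25.0, K_i=25.0, params=pe),
                      ic_i=InputConnectivity(K_e=25.0, K_i=150.0, params=pi))
        P = 4.0
        exc_e = cfg.K_P_e * P / 25.0

        def g(nu_i):
            # TC has no recurrent excitation: nu_e* responds instantly
            nu_e = float(transfer_rate(exc_e, nu_i, 0.0, cfg.coeffs_e, cfg.ic_e))
            exc_i = nu_e + cfg.K_P_i * P / 25.0
            return float(transfer_rate(exc_i, nu_i, 0.0, cfg.coeffs_i, cfg.ic_i)) - nu_i

        lo, hi = 0.0, 200.0
        assert g(lo) > 0 > g(hi)
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if g(mid) > 0:
                lo = mid
            else:
                hi = mid
        nu_i_star = 0.5 * (lo + hi)
        nu_e_star = float(transfer_rate(exc_e, nu_i_star, 0.0, cfg.coeffs_e,
                                        cfg.ic_e))
        traj = integrate_mf(MFState(nu_e=1.0, nu_i=1.0), (P, 0.0), cfg, 3000.0,
                            second_order=False)
        assert traj["nu_i"].iloc[-1] == pytest.approx(nu_i_star, abs=1e-3)
        assert traj["nu_e"].iloc[-1] == pytest.approx(nu_e_star, abs=1e-3)
        # frozen adaptation stays frozen
        assert traj["w_e"].iloc[-1] == 0.0
        assert traj["w_i"].iloc[-1] == 0.0


class TestIntegration:
    def test_zero_drive_zero_state_stays_zero(self, awake_cfg):
        traj = integrate_mf(MFState(), (0.0, 0.0), awake_cfg, 500.0)
        assert np.all(traj[["nu_e", "nu_i", "c_ee", "c_ii"]].to_numpy() == 0.0)

    def test_awake_trajectory_settles_with_re_dominant(self, awake_cfg):
        traj = integrate_mf(MFState(nu_e=1.0, nu_i=1.0), (4.0, 0.0),
                            awake_cfg, 2500.0, second_order=False)
        tail = traj.iloc[-100:]
        assert tail["nu_i"].mean() > tail["nu_e"].mean()
        assert tail["nu_i"].std() < 0.01   # converged

    def test_covariance_clips_rare_near_equilibrium(self, awake_cfg, awake_fp):
        traj = integrate_mf(awake_fp.state, (4.0, 0.0), awake_cfg, 2000.0)
        assert traj.attrs["clip_fraction"] < 1e-3

    def test_rates_and_diagonals_never_negative(self, awake_cfg):
        traj = integrate_mf(MFState(nu_e=5.0, nu_i=1.0), (2.0, 10.0),
                            awake_cfg, 1000.0)
        assert (traj[["nu_e", "nu_i", "c_ee", "c_ii"]].to_numpy() >= 0).all()


class TestStationary:
    def test_silent_without_drive(self, awake_cfg):
        st = stationary_state((0.0, 0.0), awake_cfg, check_stability=False)
        assert st.state.nu_e == pytest.approx(0.0, abs=1e-6)
        assert st.state.nu_i == pytest.approx(0.0, abs=1e-6)

    def test_root_and_integration_agree(self, awake_cfg, awake_fp):
        traj = integrate_mf(awake_fp.state, (4.0, 0.0), awake_cfg, 3000.0)
        end = traj.iloc[-1]
        assert end["nu_e"] == pytest.approx(awake_fp.state.nu_e, abs=1e-4)
        assert end["nu_i"] == pytest.approx(awake_fp.state.nu_i, abs=1e-4)

    def test_reports_standard_deviations(self, awake_fp):
        assert awake_fp.sd_i > awake_fp.sd_e >= 0.0

    def test_drive_regimes_are_ordered(self, awake_cfg):
        """Silent, then TC-controlled, then inhibited as P grows."""
        prev = None
        rates = {}
        for P in (0.0, 1.0, 4.0):
            st = stationary_state((P, 0.0), awake_cfg, init=prev,
                                  check_stability=False)
            prev = st.state
            rates[P] = st.state
        assert rates[0.0].nu_i == pytest.approx(0.0, abs=1e-6)
        assert rates[1.0].nu_e > rates[1.0].nu_i * 0.1   # TC participates
        assert rates[4.0].nu_i > 10 * rates[4.0].nu_e    # deeply inhibited


class TestOUConductanceNoise:
    def test_zero_sd_is_constant_at_the_mean(self):
        spec = OUNoiseSpec(mean=4.0, sd=0.0, tau_corr=20.0,
                           target="conductance_e")
        nc = ou_conductance_noise(spec, 1000.0, T=5.0, seed=0)
        assert np.allclose(nc.ge, 4.0)

    def test_block_average_preserves_the_mean(self):
        """For a path that never clips, bin-averaging is mean-preserving."""
        spec = OUNoiseSpec(mean=50.0, sd=2.0, tau_corr=20.0,
                           target="conductance_e")
        from thalmf.stimuli import sample_ou
        rng_seed = 42
        raw = sample_ou(spec, 10000.0, 0.1, seed=np.random.default_rng(rng_seed).integers(2**31))
        nc = ou_conductance_noise(spec, 10000.0, T=5.0, seed=rng_seed, dt=0.1)
        assert nc.ge.mean() == pytest.approx(raw.mean(), rel=1e-12)

    def test_long_path_moments_match_ou_law(self):
        spec = OUNoiseSpec(mean=30.0, sd=3.0, tau_corr=20.0,
                           target="conductance_e")
        nc = ou_conductance_noise(spec, 300000.0, T=5.0, seed=1)
        n_eff = nc.ge.size * 5.0 / (2 * spec.tau_corr)
        assert abs(nc.ge.mean() - 30.0) < 3 * spec.sd / np.sqrt(n_eff)
        # block-averaging over T=5 ms removes little variance at tau=20 ms
        assert 0.7 * spec.sd < nc.ge.std() < 1.05 * spec.sd

    def test_negative_values_clipped(self):
        spec = OUNoiseSpec(mean=0.5, sd=3.0, tau_corr=20.0,
                           target="conductance_e")
        nc = ou_conductance_noise(spec, 5000.0, T=5.0, seed=2)
        assert np.all(nc.ge >= 0.0)

    def test_noise_raises_membrane_fluctuation(self, awake_cfg):
        """Conductance noise must widen the recorded TC membrane wander."""
        base = integrate_mf(MFState(nu_e=1, nu_i=1), (1.0, 0.0), awake_cfg,
                            1500.0, record_moments=True)
        nc = ou_conductance_noise(
            OUNoiseSpec(mean=8.0, sd=8.0, tau_corr=20.0, target="conductance_e"),
            1500.0, T=5.0, seed=3, populations=("e",))
        noisy = integrate_mf(MFState(nu_e=1, nu_i=1), (1.0, 0.0), awake_cfg,
                             1500.0, noise=nc, record_moments=True)
        fluct = lambda tr: np.sqrt(np.mean(tr["sigmaV_e"] ** 2) + np.var(tr["muV_e"]))
        assert fluct(noisy) > fluct(base) + 1.0


def test_config_requires_fine_integration_step(awake_cfg):
    from dataclasses import replace
    with pytest.raises(ValueError):
        replace(awake_cfg, dt=1.0)   # dt must stay <= T/10
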