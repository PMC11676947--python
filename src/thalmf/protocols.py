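"""The responsiveness experiment battery.

Each protocol runs against the mean-field backend and, where meaningful, the
spiking network, always through the same stimulus descriptions, and returns a
ResponseCurve or SpindleReport with enough metadata to regenerate it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import periodogram

from .cell import run_poisson_batch
from .meanfield import (MFConfig, MFState, NoisyConductances, integrate_mf,
                        ou_conductance_noise, stationary_state)
from .network import (build_connectivity, bin_population_rate, simulate_network)
from .params import CellParams, cell_preset, network_defaults
from .stimuli import OUNoiseSpec, StimulusSpec
from .transfer import (InputConnectivity, TFCoefficients, membrane_moments,
                       stationary_adaptation, transfer_rate)

__all__ = [
    "ResponseCurve",
    "SpindleReport",
    "peak_response_curve",
    "response_gain",
    "noise_gain_scan",
    "conductance_response_scan",
    "isi_response_probability",
    "autocorrelation_time",
    "firing_adaptation_metric",
    "spindle_run",
    "bifurcation_scan",
    "spindle_mf_config",
]

logger = logging.getLogger(__name__)


@dataclass
class ResponseCurve:
    """x/response pairs with Monte-Carlo sd and run metadata."""

    x: np.ndarray
    response: np.ndarray
    sd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.x.shape:
                raise ValueError("sd must match x in length")
        if self.x.shape != self.response.shape:
            raise ValueError("x and response must match in length")

    def to_frame(self) -> pd.DataFrame:
        d = {"x": self.x, "response": self.response}
        if self.sd is not None:
            d["sd"] = self.sd
        return pd.DataFrame(d)


@dataclass
class SpindleReport:
    """Outcome of a spindle (self-sustained oscillation) run."""

    dominant_frequency: float      # Hz
    peak_prominence: float         # ratio of spectral peak to background
    limit_cycle: bool
    amplitude: float               # Hz, half peak-to-trough of nu_e

    def __post_init__(self) -> None:
        if self.limit_cycle and not self.dominant_frequency > 0:
            raise ValueError("limit cycle requires a positive frequency")


# ---------------------------------------------------------------------------
# stimulus-shape responsiveness (split-Gaussian slope scan)

def peak_response_curve(
    state: str,
    sigma_l_list,
    backend: str = "mean_field",
    P_const: float = 1.0,
    amplitude: float = 10.0,
    sigma_r: float = 200.0,
    seed: int = 0,
) -> ResponseCurve:
    """Relative peak response vs stimulus slope (left width of a
    split-Gaussian, right width fixed at 0.2 s, peak amplitude 10 Hz).

    The response is the maximum TC rate above the pre-stimulus baseline
    inside [t0 - 3 sigma_l, t0 + 3 sigma_r], divided by the stimulus
    amplitude.
    """
    ratios = []
    if amplitude == 0:
        return ResponseCurve(x=np.asarray(sigma_l_list),
                             response=np.zeros(len(list(sigma_l_list))),
                             meta={"state": state, "backend": backend,
                                   "P": P_const, "amplitude": 0.0})
    if backend == "mean_field":
        cfg = MFConfig.from_state(state)
        base = stationary_state((P_const, 0.0), cfg, check_stability=False)
        for sig_l in sigma_l_list:
            t0 = 500.0 + 4.0 * sig_l
            dur = t0 + 3.5 * sigma_r
            stim = StimulusSpec(kind="split_gaussian", A=amplitude, t0=t0,
                                sigma_l=sig_l, sigma_r=sigma_r)
            traj = integrate_mf(base.state, (P_const, stim), cfg, dur)
            pre = traj[traj["t"] < t0 - 3 * sig_l]["nu_e"].mean()
            win = traj[(traj["t"] >= t0 - 3 * sig_l) & (traj["t"] <= t0 + 3 * sigma_r)]
            ratios.append((win["nu_e"].max() - pre) / amplitude)
    elif backend == "network":
        net = network_defaults(state=state, seed=seed)
        conn = build_connectivity(net)
        for k, sig_l in enumerate(sigma_l_list):
            t0 = 1000.0 + 4.0 * sig_l
            dur = t0 + 3.5 * sigma_r
            stim = StimulusSpec(kind="split_gaussian", A=amplitude, t0=t0,
                                sigma_l=sig_l, sigma_r=sigma_r)
            raster, _ = simulate_network(conn, net, P_const, stim, dur,
                                         seed=seed + 17 * k + 1)
            t, r = bin_population_rate(raster, "TC", T_bin=5.0, t_start=500.0)
            pre = r[t < t0 - 3 * sig_l].mean()
            win = r[(t >= t0 - 3 * sig_l) & (t <= t0 + 3 * sigma_r)]
            ratios.append((win.max() - pre) / amplitude)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return ResponseCurve(
        x=np.asarray(sigma_l_list), response=np.asarray(ratios),
        meta={"state": state, "backend": backend, "P": P_const,
              "amplitude": amplitude, "sigma_r": sigma_r, "seed": seed},
    )


# ---------------------------------------------------------------------------
# stationary gain protocols

def _gated_response(cfg: MFConfig, P_const: float, amp: float,
                    noise: NoisyConductances | None, init: MFState,
                    pulse: float = 1600.0, lead: float = 600.0):
    """TC response to one gated (rectangular) sensory pulse: steady-state
    window = last 50% of the pulse; also returns run-averaged muV/sigmaV."""
    stim = StimulusSpec(kind="rectangular", A=amp, t0=lead, width=pulse)
    traj = integrate_mf(init, (P_const, stim), cfg, lead + pulse,
                        noise=noise, record_moments=True)
    base = traj[traj["t"] < lead]["nu_e"].mean()
    win = traj[traj["t"] >= lead + 0.5 * pulse]
    resp = win["nu_e"].mean() - base
    # run-level membrane fluctuation: within-bin shotnoise variance plus the
    # across-bin wander of muV driven by the noise
    sigv = float(np.sqrt(np.mean(traj["sigmaV_e"] ** 2) + np.var(traj["muV_e"])))
    return resp, sigv


def response_gain(
    state: str,
    P_const: float,
    S_amplitudes,
    backend: str = "mean_field",
    noise: NoisyConductances | None = None,
    cfg: MFConfig | None = None,
    seed: int = 0,
    gated: bool = False,
) -> dict:
    """Gain = least-squares slope of stationary TC rate vs sensory amplitude.

    Without noise the stationary states are solved directly (or, with
    ``gated=True``, probed with the same gated rectangular pulses used for
    the noisy case); with noise each amplitude is probed with a gated pulse
    and the steady-state window of the noisy trajectory is averaged.
    Returns gain (Hz per Hz), R^2, the response values, and the run-averaged
    membrane fluctuation.
    """
    amps = np.asarray(list(S_amplitudes), dtype=float)
    if amps.size < 2:
        raise ValueError("need at least two amplitudes for a slope")
    if backend != "mean_field":
        raise ValueError("response_gain is a mean-field protocol")
    cfg = cfg or MFConfig.from_state(state)
    responses = []
    sigmas = []
    if noise is None and gated:
        base = stationary_state((P_const, 0.0), cfg, check_stability=False)
        for amp in amps:
            resp, sigv = _gated_response(cfg, P_const, float(amp), None, base.state)
            responses.append(resp)
            sigmas.append(sigv)
    elif noise is None:
        prev = None
        osc_flagged = False
        for amp in amps:
            st = stationary_state((P_const, float(amp)), cfg, init=prev,
                                  check_stability=False)
            if not st.converged:
                osc_flagged = True
            prev = st.state
            responses.append(st.state.nu_e)
            m = membrane_moments(
                *_tc_inputs(cfg, st.state, P_const, float(amp)),
                st.state.w_e, cfg.ic_e)
            sigmas.append(float(m.sigmaV))
        if osc_flagged:
            raise RuntimeError(
                "non-stationary (oscillatory) regime: use the spindle protocol")
    else:
        base = stationary_state((P_const, 0.0), cfg,
                                noise=(float(np.mean(noise.ge)),
                                       float(np.mean(noise.gi))),
                                noise_pops=noise.populations,
                                check_stability=False)
        for amp in amps:
            resp, sigv = _gated_response(cfg, P_const, float(amp), noise, base.state)
            responses.append(resp)
            sigmas.append(sigv)
    responses = np.asarray(responses)
    slope, intercept = np.polyfit(amps, responses, 1)
    pred = slope * amps + intercept
    ss_res = float(np.sum((responses - pred) ** 2))
    ss_tot = float(np.sum((responses - responses.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"gain": float(slope), "r2": r2, "amplitudes": amps,
            "responses": responses, "sigmaV": float(np.mean(sigmas)),
            "state": state, "P": P_const}


def _tc_inputs(cfg: MFConfig, state: MFState, P: float, S: float):
    from .meanfield import _population_inputs
    (xe, xi), _ = _population_inputs(state.to_vector(), P, S, cfg)
    return xe, xi


def noise_gain_scan(
    state: str,
    noise_levels,
    backend: str = "mean_field",
    P_const: float = 1.0,
    S_amplitudes=(0.0, 5.0, 10.0),
    tau_noise: float = 20.0,
    duration_hint: float = 2300.0,
    seed: int = 0,
    n_reps: int = 1,
) -> dict:
    """Gain under gated 10 Hz sensory stimuli vs membrane fluctuation.

    Each noise level is an OU conductance amplitude (mean = sd = level, nS)
    applied as piecewise-static excitatory and inhibitory conductances to
    the TC population (the population-level analog of a dynamic-clamp
    conductance injection into the responding cells).  Gains are estimated
    from gated rectangular pulses at every level (including zero noise) and
    averaged over ``n_reps`` independent noise realizations.  Returns the
    gain-vs-sigmaV curve and the linear slope in gain per mV.
    """
    levels = list(noise_levels)
    if len(levels) < 3:
        raise ValueError("need at least 3 noise levels for the linear fit")
    cfg = MFConfig.from_state(state)
    gains, sigs = [], []
    for j, lvl in enumerate(levels):
        g_reps, s_reps = [], []
        for r in range(n_reps if lvl > 0 else 1):
            if lvl == 0:
                res = response_gain(state, P_const, S_amplitudes, cfg=cfg,
                                    gated=True)
            else:
                spec = OUNoiseSpec(mean=float(lvl), sd=float(lvl),
                                   tau_corr=tau_noise, target="conductance_e")
                noise = ou_conductance_noise(spec, duration_hint, T=cfg.T,
                                             seed=seed + 101 * j + 7919 * r,
                                             populations=("e",))
                res = response_gain(state, P_const, S_amplitudes, cfg=cfg,
                                    noise=noise)
            g_reps.append(res["gain"])
            s_reps.append(res["sigmaV"])
        gains.append(float(np.mean(g_reps)))
        sigs.append(float(np.mean(s_reps)))
    gains = np.asarray(gains)
    sigs = np.asarray(sigs)
    slope, intercept = np.polyfit(sigs, gains, 1)
    curve = ResponseCurve(x=sigs, response=gains,
                          meta={"state": state, "levels": levels, "P": P_const,
                                "tau_noise": tau_noise, "seed": seed})
    return {"curve": curve, "slope": float(slope), "intercept": float(intercept)}


def cortical_turning_point(
    state: str = "awake",
    P_grid=None,
    cfg: MFConfig | None = None,
) -> dict:
    """Cortical-drive amplitude ending the inhibited regime.

    Scans stationary fixed points over constant P and returns the P at the
    saturation knee of the RE rate curve (most negative second derivative of
    nu_i vs P, quadratically interpolated), which coincides with the sharp
    upturn of the TC response.
    """
    P_grid = np.asarray(P_grid if P_grid is not None else np.arange(0.0, 41.0, 2.0))
    cfg = cfg or MFConfig.from_state(state)
    nu_e, nu_i = [], []
    prev = None
    for P in P_grid:
        st = stationary_state((float(P), 0.0), cfg, init=prev,
                              check_stability=False)
        prev = st.state
        nu_e.append(st.state.nu_e)
        nu_i.append(st.state.nu_i)
    nu_e = np.asarray(nu_e)
    nu_i = np.asarray(nu_i)
    d2 = np.gradient(np.gradient(nu_i, P_grid), P_grid)
    k = int(np.argmin(d2))
    # quadratic interpolation around the knee
    if 0 < k < len(P_grid) - 1:
        denom = d2[k - 1] - 2 * d2[k] + d2[k + 1]
        shift = 0.5 * (d2[k - 1] - d2[k + 1]) / denom if denom != 0 else 0.0
        P_turn = float(P_grid[k] + shift * (P_grid[1] - P_grid[0]))
    else:
        P_turn = float(P_grid[k])
    return {"P_turn": P_turn, "P": P_grid, "nu_e": nu_e, "nu_i": nu_i}


# ---------------------------------------------------------------------------
# conductance-response (dynamic-clamp-like) protocols

def _sigmoid(q, base, amp, shift, width):
    return base + amp / (1.0 + np.exp(-(q - shift) / width))


def fit_sigmoid(x, y):
    """4-parameter logistic fit; returns params dict incl. the maximum slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.allclose(y, y[0]):
        raise ValueError("degenerate (flat) response; sigmoid fit skipped")
    p0 = [float(y.min()), float(y.max() - y.min()),
          float(x[np.argmin(np.abs(y - 0.5 * (y.min() + y.max())))]),
          float((x.max() - x.min()) / 8 or 1.0)]
    popt, _ = curve_fit(_sigmoid, x, y, p0=p0, maxfev=20000)
    base, amp, shift, width = popt
    return {"base": base, "amp": amp, "shift": shift, "width": width,
            "max_slope": amp / (4.0 * width)}


def conductance_response_scan(
    Qe_list,
    noise: OUNoiseSpec | None = None,
    backend: str = "mean_field",
    input_rate: float = 10.0,
    state: str = "awake",
    reps: int = 20,
    duration: float = 5000.0,
    seed: int = 0,
) -> dict:
    """Response vs excitatory quantal strength of a common Poisson drive.

    single_cell backend: output spikes per input spike for one TC cell driven
    by one Poisson train (the dynamic-clamp experiment).  mean_field /
    network backends: stationary TC population rate with the shared drive
    delivered to every cell.  A 4-parameter sigmoid is fitted; returns the
    curve, the fit, its maximum slope and shift.
    """
    Qe_list = np.asarray(list(Qe_list), dtype=float)
    if np.any(np.diff(Qe_list) <= 0):
        raise ValueError("Qe_list must be strictly increasing")
    sd = None
    if backend == "single_cell":
        params = cell_preset(f"TC_{state}")
        resp, spread = [], []
        for k, q in enumerate(Qe_list):
            out = run_poisson_batch(
                params, np.full(reps, input_rate), np.zeros(reps), duration,
                seed=seed + 31 * k, Qe=float(q), ou_current=noise)
            per_in = out["counts"] / (input_rate * duration * 1e-3)
            resp.append(per_in.mean())
            spread.append(per_in.std(ddof=1) if reps > 1 else 0.0)
        resp = np.asarray(resp)
        sd = np.asarray(spread)
    elif backend == "mean_field":
        cfg = MFConfig.from_state(state)
        resp = []
        prev = None
        for q in Qe_list:
            cfg_q = replace(cfg, common_drive=(input_rate, float(q)))
            st = stationary_state((0.0, 0.0), cfg_q, init=prev,
                                  check_stability=False)
            prev = st.state
            resp.append(st.state.nu_e)
        resp = np.asarray(resp)
    elif backend == "network":
        net = network_defaults(state=state, seed=seed)
        conn = build_connectivity(net)
        resp = []
        for k, q in enumerate(Qe_list):
            raster, _ = simulate_network(
                conn, net, 0.0, 0.0, duration, seed=seed + 7 * k,
                common_drive=(input_rate, float(q)), ou_noise=noise)
            _, r = bin_population_rate(raster, "TC", T_bin=5.0, t_start=500.0)
            resp.append(r.mean())
        resp = np.asarray(resp)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    curve = ResponseCurve(x=Qe_list, response=resp, sd=sd,
                          meta={"backend": backend, "state": state,
                                "input_rate": input_rate, "seed": seed})
    try:
        fit = fit_sigmoid(Qe_list, resp)
    except (ValueError, RuntimeError) as err:
        logger.warning("sigmoid fit skipped: %s", err)
        fit = None
    return {"curve": curve, "fit": fit}


def isi_response_probability(
    params: CellParams,
    EL_override: float,
    Qe: float,
    input_rate: float = 10.0,
    noise: OUNoiseSpec | None = None,
    duration: float = 20000.0,
    reps: int = 10,
    seed: int = 0,
    bin_width: float = 50.0,
    isi_max: float = 550.0,
    response_window: float = 50.0,
) -> pd.DataFrame:
    """P(output spike | preceding input ISI) for a single driven TC cell.

    Each input spike is labelled responded if an output spike falls within
    ``response_window`` ms (or before the next input spike, whichever is
    sooner); the label is histogrammed against the ISI from the previous
    input spike, normalized per bin by occupancy.  Bins with fewer than 10
    events are flagged wide-uncertainty rather than dropped.
    """
    p = params.with_overrides(EL=EL_override, label=f"{params.label}@{EL_override}mV")
    out = run_poisson_batch(
        p, np.full(reps, input_rate), np.zeros(reps), duration, seed=seed,
        Qe=Qe, ou_current=noise, record_spikes=True, record_input_spikes=True)
    edges = np.arange(0.0, isi_max + bin_width, bin_width)
    hits = np.zeros(len(edges) - 1)
    occ = np.zeros(len(edges) - 1)
    for inp, outp in zip(out["input_spikes"], out["spikes"]):
        if inp.size < 2:
            continue
        isis = np.diff(inp)
        for i in range(1, inp.size):
            isi = isis[i - 1]
            if isi >= isi_max:
                continue
            t_i = inp[i]
            t_next = inp[i + 1] if i + 1 < inp.size else np.inf
            window_end = min(t_i + response_window, t_next)
            k = int(isi // bin_width)
            occ[k] += 1
            if np.any((outp > t_i) & (outp <= window_end)):
                hits[k] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(occ > 0, hits / np.maximum(occ, 1), np.nan)
    return pd.DataFrame({
        "isi_lo": edges[:-1], "isi_hi": edges[1:],
        "probability": prob, "n_events": occ.astype(int),
        "wide_uncertainty": occ < 10,
    })


# ---------------------------------------------------------------------------
# diagnostics

def autocorrelation_time(rate_trace, dt_fine: float = 1.0) -> float:
    """1/e decay time (ms) of the normalized autocovariance of a rate trace.

    Returns nan (with a log notice) for a constant trace, where the
    autocorrelation is undefined.
    """
    x = np.asarray(rate_trace, dtype=float)
    x = x - x.mean()
    var = np.mean(x**2)
    if var == 0:
        logger.warning("autocorrelation undefined for a constant trace")
        return float("nan")
    n = x.size
    ac = np.correlate(x, x, mode="full")[n - 1:] / (var * n)
    below = np.flatnonzero(ac < 1.0 / np.e)
    if below.size == 0:
        return float(n * dt_fine)
    k = below[0]
    if k == 0:
        return float(dt_fine)
    # linear interpolation between the straddling lags
    a0, a1 = ac[k - 1], ac[k]
    frac = (a0 - 1.0 / np.e) / (a0 - a1)
    return float((k - 1 + frac) * dt_fine)


def firing_adaptation_metric(
    params: CellParams,
    tf: TFCoefficients,
    ic: InputConnectivity,
    polarization: float = 0.0,
    noise_sd: float = 0.0,
    nu_in: float = 10.0,
    nu_i_in: float = 0.0,
    n_noise: int = 20,
    seed: int = 0,
) -> float:
    """Firing-adaptation index F_adapt = 1 - F(w=w*) / F(w=0) in [0, 1].

    The relative drop of the transfer-function rate once adaptation has
    equilibrated, evaluated at input rate ``nu_in`` with the resting
    potential offset by ``polarization`` mV.  With ``noise_sd`` > 0 the index
    is averaged over static conductance draws |N(noise_sd, noise_sd)| on both
    synaptic channels.  Returns nan when the unadapted rate is zero.
    """
    p = params.with_overrides(EL=params.EL + polarization)
    ic_p = InputConnectivity(K_e=ic.K_e, K_i=ic.K_i, params=p)
    rng = np.random.default_rng(seed)
    draws = max(1, n_noise) if noise_sd > 0 else 1
    vals = []
    for _ in range(draws):
        ge = gi = 0.0
        if noise_sd > 0:
            ge = abs(rng.normal(noise_sd, noise_sd))
            gi = abs(rng.normal(noise_sd, noise_sd))
        f0 = float(transfer_rate(nu_in, nu_i_in, 0.0, tf, ic_p,
                                 static_ge=ge, static_gi=gi))
        if f0 <= 0:
            vals.append(np.nan)
            continue
        # equilibrate: rate and stationary adaptation solved jointly
        rate = f0
        for _ in range(200):
            w = stationary_adaptation(rate, nu_in, nu_i_in, ic_p)
            new = float(transfer_rate(nu_in, nu_i_in, w, tf, ic_p,
                                      static_ge=ge, static_gi=gi))
            if abs(new - rate) < 1e-4:
                rate = new
                break
            rate = 0.5 * rate + 0.5 * new
        vals.append(1.0 - rate / f0)
    out = float(np.nanmean(vals))
    if np.isnan(out):
        logger.warning("firing_adaptation_metric undefined: F(w=0) = 0")
    return out


# ---------------------------------------------------------------------------
# spindle oscillations

def spindle_mf_config(coeffs_e: TFCoefficients | None = None,
                      coeffs_i: TFCoefficients | None = None,
                      **overrides) -> MFConfig:
    """Mean-field configuration for the spindle state.

    Uses the package's own re-fitted transfer-function coefficients for the
    modified reset potentials when available (shipped with the package data);
    falls back on the reference awake-fit coefficients otherwise.
    """
    if coeffs_e is None or coeffs_i is None:
        try:
            from .fixtures import load_spindle_coefficients
            ce, ci = load_spindle_coefficients()
        except (FileNotFoundError, ImportError):
            logger.warning("spindle TF refit unavailable; using reference fit")
            ce, ci = TFCoefficients.reference("TC"), TFCoefficients.reference("RE")
        coeffs_e = coeffs_e or ce
        coeffs_i = coeffs_i or ci
    return MFConfig.from_state("spindle", coeffs_e=coeffs_e, coeffs_i=coeffs_i,
                               **overrides)


def _oscillation_metrics(t: np.ndarray, x: np.ndarray, fs: float):
    """Dominant frequency, spectral prominence and sustained-amplitude check
    on the last half of a rate trace."""
    half = x[x.size // 2:]
    third = x.size // 3
    amp_mid = 0.5 * (np.percentile(x[third:2 * third], 97.5)
                     - np.percentile(x[third:2 * third], 2.5))
    amp_late = 0.5 * (np.percentile(x[2 * third:], 97.5)
                      - np.percentile(x[2 * third:], 2.5))
    detr = half - half.mean()
    freq, pxx = periodogram(detr, fs=fs)
    if np.all(pxx == 0):
        return 0.0, 0.0, False, 0.0
    k = int(np.argmax(pxx))
    fdom = float(freq[k])
    prominence = float(pxx[k] / max(np.median(pxx[pxx > 0]), 1e-30))
    sustained = (amp_late > 1.0) and (amp_late > 0.6 * amp_mid) and fdom > 0
    return fdom, prominence, bool(sustained), float(amp_late)


def spindle_run(
    backend: str = "mean_field",
    duration: float = 5000.0,
    kick: StimulusSpec | None = None,
    cfg: MFConfig | None = None,
    seed: int = 0,
    state: str = "spindle",
):
    """Kick the spindle-state circuit and test for a self-sustained
    oscillation after stimulus offset; returns (SpindleReport, trace)."""
    kick = kick or StimulusSpec(kind="rectangular", A=20.0, t0=100.0, width=200.0)
    if backend == "mean_field":
        if cfg is None:
            cfg = (spindle_mf_config() if state == "spindle"
                   else MFConfig.from_state(state))
        traj = integrate_mf(MFState(), (0.0, kick), cfg, duration)
        t = traj["t"].to_numpy()
        x = traj["nu_e"].to_numpy()
        fs = 1000.0 / (t[1] - t[0])
    elif backend == "network":
        net = network_defaults(state=state, seed=seed)
        conn = build_connectivity(net)
        raster, _ = simulate_network(conn, net, 0.0, kick, duration, seed=seed + 1)
        t, x = bin_population_rate(raster, "TC", T_bin=5.0)
        fs = 1000.0 / 5.0
    else:
        raise ValueError(f"unknown backend {backend!r}")
    post = t > (kick.t0 + kick.width)
    fdom, prom, sustained, amp = _oscillation_metrics(t[post], x[post], fs)
    report = SpindleReport(dominant_frequency=fdom if sustained else max(fdom, 0.0),
                           peak_prominence=prom, limit_cycle=sustained,
                           amplitude=amp)
    return report, (t, x)


def bifurcation_scan(
    gamma_grid,
    backend: str = "mean_field",
    duration: float = 4000.0,
    seed: int = 0,
    amplitude_floor: float = 1.0,
) -> dict:
    """Oscillation amplitude vs connectivity scale gamma in [1, 10].

    gamma linearly scales every intra-thalamic connection probability from
    1/10 of the reference values (gamma=1, the small-network regime) to the
    reference values (gamma=10), while quantal strengths are scaled by
    10/gamma so the total mean synaptic conductance K*Q stays fixed.  The
    Hopf point is the first gamma whose post-kick amplitude exceeds the
    detection floor.
    """
    gamma_grid = np.asarray(list(gamma_grid), dtype=float)
    amps = []
    kick = StimulusSpec(kind="rectangular", A=20.0, t0=100.0, width=200.0)
    for k, g in enumerate(gamma_grid):
        scale_p = g / 10.0
        scale_q = 10.0 / g
        if backend == "mean_field":
            base = spindle_mf_config()
            pe = base.params_e.with_overrides(Qe=base.params_e.Qe * scale_q,
                                              Qi=base.params_e.Qi * scale_q)
            pi = base.params_i.with_overrides(Qe=base.params_i.Qe * scale_q,
                                              Qi=base.params_i.Qi * scale_q)
            cfg = replace(
                base, params_e=pe, params_i=pi,
                ic_e=InputConnectivity(K_e=base.ic_e.K_e * scale_p,
                                       K_i=base.ic_e.K_i * scale_p, params=pe),
                ic_i=InputConnectivity(K_e=base.ic_i.K_e * scale_p,
                                       K_i=base.ic_i.K_i * scale_p, params=pi),
            )
            report, _ = spindle_run("mean_field", duration, kick, cfg=cfg)
        else:
            net = network_defaults(state="spindle", seed=seed + k)
            p = dict(net.p)
            for key in ("TC_RE", "RE_TC", "RE_RE"):
                p[key] = p[key] * scale_p
            net = replace(net, p=p)
            # scale intra-thalamic quantal sizes via the drive-override table
            q = dict(net.Q_drive)
            pe = cell_preset("TC_spindle")
            pi = cell_preset("RE_spindle")
            q.update({"TC_RE": pi.Qe * scale_q, "RE_TC": pe.Qi * scale_q,
                      "RE_RE": pi.Qi * scale_q})
            net = replace(net, Q_drive=q)
            conn = build_connectivity(net)
            raster, _ = simulate_network(conn, net, 0.0, kick, duration,
                                         seed=seed + 100 + k)
            t, x = bin_population_rate(raster, "TC", T_bin=5.0)
            post = t > (kick.t0 + kick.width)
            _, _, _, amp = _oscillation_metrics(t[post], x[post], 200.0)
            amps.append(amp)
            continue
        amps.append(report.amplitude if report.limit_cycle else
                    min(report.amplitude, amplitude_floor * 0.5))
    amps = np.asarray(amps)
    above = np.flatnonzero(amps > amplitude_floor)
    hopf = float(gamma_grid[above[0]]) if above.size else float("nan")
    return {"gamma": gamma_grid, "amplitude": amps, "hopf_gamma": hopf,
            "backend": backend}
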