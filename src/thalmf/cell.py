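"""Single AdEx neuron with conductance-based synapses.

The adaptive exponential integrate-and-fire neuron is the elementary unit of
both the spiking network and the single-cell simulations that feed the
transfer-function fit:

    cm dv/dt   = gL (EL - v) + gL Delta exp((v - Vt)/Delta) - w + I_syn + I_ext
    tau_w dw/dt = a (v - EL) - w            (w += b at each spike)
    I_syn      = Ge (Ee - v) + Gi (Ei - v)

with synaptic conductances that jump by Q per presynaptic spike and decay
exponentially.  Integration is forward Euler (default dt = 0.1 ms); the
exponential term is evaluated at min(v, V_spike) to avoid overflow during the
spike upswing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .params import CellParams, classification_defaults
from .stimuli import OUNoiseSpec, StimulusSpec, drive_rate, sample_ou

__all__ = [
    "CellState",
    "SpikeTrain",
    "TraceRecord",
    "adex_step",
    "simulate_cell",
    "run_poisson_batch",
    "classify_firing",
]


@dataclass
class CellState:
    """Dynamic variables of one AdEx cell."""

    v: float                      # membrane potential, mV
    w: float = 0.0                # adaptation current, pA
    Ge: float = 0.0               # excitatory conductance, nS
    Gi: float = 0.0               # inhibitory conductance, nS
    refrac_remaining: float = 0.0  # ms

    def __post_init__(self) -> None:
        if self.Ge < 0 or self.Gi < 0:
            raise ValueError("conductances must be non-negative")
        if self.refrac_remaining < 0:
            raise ValueError("refrac_remaining must be non-negative")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) over a simulation of given duration."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size and (np.any(np.diff(times) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if times.size and (times[0] < 0 or times[-1] > self.duration):
            raise ValueError("spike times must lie in [0, duration]")

    def __len__(self) -> int:
        return self.times.size

    def rate(self) -> float:
        """Mean firing rate in Hz."""
        return 1000.0 * len(self) / self.duration


@dataclass
class TraceRecord:
    """Uniformly sampled membrane trace plus the spike train."""

    t: np.ndarray          # ms
    v: np.ndarray          # mV
    w: np.ndarray          # pA
    spikes: SpikeTrain
    dt: float = field(default=0.1)

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.v) == len(self.w)):
            raise ValueError("trace grids must have equal length")

    def to_columns(self) -> np.ndarray:
        return np.column_stack([self.t, self.v, self.w])


def _check_finite(v: np.ndarray, w: np.ndarray, t: float) -> None:
    for name, arr in (("v", v), ("w", w)):
        bad = ~np.isfinite(np.atleast_1d(arr))
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise FloatingPointError(
                f"non-finite {name} in cell {idx} at t={t:.2f} ms"
            )


def adex_step(
    state: CellState,
    params: CellParams,
    I_ext: float,
    incoming_exc_spikes: int,
    incoming_inh_spikes: int,
    dt: float,
):
    """One forward-Euler step; returns (new_state, spiked).

    Conductances decay exactly and receive quantal increments, the synaptic
    current is evaluated at the pre-step membrane potential, and during the
    refractory period v is clamped at V_reset while w and the conductances
    keep evolving.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params
    ge = state.Ge * np.exp(-dt / p.tau_e) + p.Qe * incoming_exc_spikes
    gi = state.Gi * np.exp(-dt / p.tau_i) + p.Qi * incoming_inh_spikes
    v, w = state.v, state.w
    i_syn = ge * (p.Ee - v) + gi * (p.Ei - v)

    w_new = w + dt * (p.a * (v - p.EL) - w) / p.tau_w
    spiked = False
    if state.refrac_remaining > 0:
        v_new = p.V_reset
        refrac = max(state.refrac_remaining - dt, 0.0)
    else:
        v_exp = min(v, p.V_spike)  # clip the exponential to avoid overflow
        dv = (
            p.gL * (p.EL - v)
            + p.gL * p.Delta * np.exp((v_exp - p.Vt) / p.Delta)
            - w
            + i_syn
            + I_ext
        ) / p.cm
        v_new = v + dt * dv
        refrac = 0.0
        if v_new > p.V_spike:
            spiked = True
            v_new = p.V_reset
            w_new = w_new + p.b
            refrac = p.t_refrac
    _check_finite(np.asarray(v_new), np.asarray(w_new), t=0.0)
    return (
        CellState(v=float(v_new), w=float(w_new), Ge=float(ge), Gi=float(gi),
                  refrac_remaining=float(refrac)),
        spiked,
    )


def _iext_array(I_ext, t_grid: np.ndarray):
    """Normalize an external-current argument to per-step values (pA)."""
    if I_ext is None:
        return np.zeros_like(t_grid)
    if isinstance(I_ext, StimulusSpec):
        return np.asarray(drive_rate(I_ext, t_grid), dtype=float)
    arr = np.asarray(I_ext, dtype=float)
    if arr.ndim == 0:
        return np.full_like(t_grid, float(arr))
    if arr.shape != t_grid.shape:
        raise ValueError("explicit I_ext array must have one value per step")
    return arr


def run_poisson_batch(
    params: CellParams,
    nu_e,
    nu_i,
    duration: float,
    dt: float = 0.1,
    seed=None,
    I_ext=None,
    ou_current: OUNoiseSpec | None = None,
    Qe: float | None = None,
    record_spikes: bool = False,
    record_input_spikes: bool = False,
    record_trace: bool = False,
    init_v=None,
) -> dict:
    """Simulate a batch of independent AdEx cells under Poisson bombardment.

    ``nu_e`` / ``nu_i`` are the *total* excitatory / inhibitory input rates in
    Hz per cell (already multiplied by the in-degree).  All cells share
    ``params``; ``Qe`` optionally overrides the excitatory quantal increment
    (conductance-response scans).  Returns a dict with ``counts`` (spikes per
    cell) and, on request, output/input spike time lists and the trace of
    cell 0.
    """
    nu_e = np.atleast_1d(np.asarray(nu_e, dtype=float))
    nu_i = np.atleast_1d(np.asarray(nu_i, dtype=float))
    n = max(nu_e.size, nu_i.size)
    nu_e = np.broadcast_to(nu_e, (n,)).copy()
    nu_i = np.broadcast_to(nu_i, (n,)).copy()
    if np.any(nu_e < 0) or np.any(nu_i < 0):
        raise ValueError("input rates must be non-negative")

    p = params
    qe = p.Qe if Qe is None else float(Qe)
    rng = np.random.default_rng(seed)
    nsteps = int(round(duration / dt))
    t_grid = np.arange(nsteps) * dt

    v = np.full(n, p.EL) if init_v is None else np.broadcast_to(init_v, (n,)).astype(float).copy()
    w = np.zeros(n)
    ge = np.zeros(n)
    gi = np.zeros(n)
    refrac = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)

    dec_e = np.exp(-dt / p.tau_e)
    dec_i = np.exp(-dt / p.tau_i)
    lam_e = nu_e * dt * 1e-3
    lam_i = nu_i * dt * 1e-3
    iext = _iext_array(I_ext, t_grid)
    ou = None
    if ou_current is not None:
        if ou_current.target != "current":
            raise ValueError("single-cell OU noise must target 'current'")
        # independent OU current per cell
        ou = np.stack([
            sample_ou(ou_current, duration, dt, seed=rng.integers(2**31))
            for _ in range(n)
        ])

    out_spikes: list[list[float]] = [[] for _ in range(n)] if record_spikes else []
    in_spikes: list[list[float]] = [[] for _ in range(n)] if record_input_spikes else []
    trace_v = np.empty(nsteps) if record_trace else None
    trace_w = np.empty(nsteps) if record_trace else None

    for k in range(nsteps):
        ke = rng.poisson(lam_e)
        ki = rng.poisson(lam_i)
        if record_input_spikes:
            for idx in np.flatnonzero(ke):
                in_spikes[idx].extend([t_grid[k]] * int(ke[idx]))
        ge = ge * dec_e + qe * ke
        gi = gi * dec_i + p.Qi * ki
        i_syn = ge * (p.Ee - v) + gi * (p.Ei - v)
        i_tot = i_syn + iext[k]
        if ou is not None:
            i_tot = i_tot + ou[:, k]

        w_new = w + dt * (p.a * (v - p.EL) - w) / p.tau_w
        in_refrac = refrac > 0
        v_exp = np.minimum(v, p.V_spike)
        dv = (
            p.gL * (p.EL - v)
            + p.gL * p.Delta * np.exp((v_exp - p.Vt) / p.Delta)
            - w
            + i_tot
        ) / p.cm
        v_new = np.where(in_refrac, p.V_reset, v + dt * dv)
        refrac = np.maximum(refrac - dt, 0.0)

        spiking = (v_new > p.V_spike) & ~in_refrac
        if spiking.any():
            v_new[spiking] = p.V_reset
            w_new[spiking] += p.b
            refrac[spiking] = p.t_refrac
            counts[spiking] += 1
            if record_spikes:
                tk = t_grid[k] + dt
                for idx in np.flatnonzero(spiking):
                    out_spikes[idx].append(tk)
        v, w = v_new, w_new
        if record_trace:
            trace_v[k] = v[0]
            trace_w[k] = w[0]
        if k % 2000 == 0:
            _check_finite(v, w, t_grid[k])

    out = {"counts": counts, "t": t_grid, "duration": duration}
    if record_spikes:
        out["spikes"] = [np.asarray(s) for s in out_spikes]
    if record_input_spikes:
        out["input_spikes"] = [np.asarray(s) for s in in_spikes]
    if record_trace:
        out["v"] = trace_v
        out["w"] = trace_w
    return out


def simulate_cell(
    params: CellParams,
    duration: float,
    dt: float = 0.1,
    seed=None,
    I_ext=None,
    exc_rate=None,
    inh_rate=None,
    exc_spike_times=None,
    inh_spike_times=None,
    ou_current: OUNoiseSpec | None = None,
    Qe: float | None = None,
) -> TraceRecord:
    """Full single-cell trace under currents, Poisson rates, or spike schedules.

    ``exc_rate``/``inh_rate`` may be scalars (Hz) or StimulusSpec rate drives
    (total input rate); ``exc_spike_times``/``inh_spike_times`` are explicit
    schedules in ms.  Reproducible given ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    nsteps = int(round(duration / dt))
    t_grid = np.arange(nsteps) * dt
    rng = np.random.default_rng(seed)
    p = params

    def _counts_from(rate, times):
        if times is not None:
            edges = np.arange(nsteps + 1) * dt
            return np.histogram(np.asarray(times, dtype=float), bins=edges)[0]
        if rate is None:
            return np.zeros(nsteps, dtype=int)
        if isinstance(rate, StimulusSpec):
            lam = np.asarray(drive_rate(rate, t_grid)) * dt * 1e-3
        else:
            lam = np.full(nsteps, float(rate) * dt * 1e-3)
        return rng.poisson(lam)

    ke = _counts_from(exc_rate, exc_spike_times)
    ki = _counts_from(inh_rate, inh_spike_times)
    iext = _iext_array(I_ext, t_grid)
    ou = sample_ou(ou_current, duration, dt, seed=rng.integers(2**31)) if ou_current else None

    qe = p.Qe if Qe is None else float(Qe)
    state = CellState(v=p.EL)
    v_tr = np.empty(nsteps)
    w_tr = np.empty(nsteps)
    spike_times: list[float] = []
    dec_e = np.exp(-dt / p.tau_e)
    dec_i = np.exp(-dt / p.tau_i)
    v, w, ge, gi, refrac = state.v, state.w, state.Ge, state.Gi, 0.0
    for k in range(nsteps):
        ge = ge * dec_e + qe * ke[k]
        gi = gi * dec_i + p.Qi * ki[k]
        i_tot = ge * (p.Ee - v) + gi * (p.Ei - v) + iext[k]
        if ou is not None:
            i_tot += ou[k]
        w_new = w + dt * (p.a * (v - p.EL) - w) / p.tau_w
        if refrac > 0:
            v_new = p.V_reset
            refrac = max(refrac - dt, 0.0)
        else:
            v_exp = min(v, p.V_spike)
            v_new = v + dt * (
                p.gL * (p.EL - v)
                + p.gL * p.Delta * np.exp((v_exp - p.Vt) / p.Delta)
                - w
                + i_tot
            ) / p.cm
            if v_new > p.V_spike:
                v_new = p.V_reset
                w_new += p.b
                refrac = p.t_refrac
                spike_times.append(t_grid[k] + dt)
        v, w = v_new, w_new
        v_tr[k] = v
        w_tr[k] = w
        if not (np.isfinite(v) and np.isfinite(w)):
            _check_finite(np.asarray(v), np.asarray(w), t_grid[k])
    return TraceRecord(
        t=t_grid, v=v_tr, w=w_tr,
        spikes=SpikeTrain(times=np.asarray(spike_times), duration=duration),
        dt=dt,
    )


def classify_firing(
    spikes: SpikeTrain,
    stimulus_window: tuple[float, float],
    burst_isi_max: float | None = None,
    quiescence_min: float | None = None,
) -> str:
    """Classify the firing pattern within a stimulus window.

    silent : fewer than 2 spikes in the window
    burst  : at least one cluster of >= 2 spikes with intra-cluster ISIs below
             ``burst_isi_max``, and every such cluster is followed by
             quiescence of at least ``quiescence_min`` ms (until the next
             spike or the window end)
    tonic  : otherwise
    """
    defaults = classification_defaults()
    burst_isi_max = defaults["burst_isi_max"] if burst_isi_max is None else burst_isi_max
    quiescence_min = defaults["quiescence_min"] if quiescence_min is None else quiescence_min

    lo, hi = stimulus_window
    if not (0.0 <= lo < hi <= spikes.duration):
        raise ValueError("stimulus window must lie within the simulated duration")
    times = spikes.times[(spikes.times >= lo) & (spikes.times <= hi)]
    if times.size < 2:
        return "silent"

    # split into clusters at gaps larger than the intra-burst ISI ceiling
    gaps = np.diff(times)
    cluster_edges = np.flatnonzero(gaps >= burst_isi_max)
    clusters = np.split(times, cluster_edges + 1)

    multi = [c for c in clusters if c.size >= 2]
    if not multi:
        return "tonic"
    for c in clusters:
        if c.size < 2:
            continue
        last = c[-1]
        following = times[times > last]
        gap_after = (following[0] - last) if following.size else (hi - last)
        if gap_after < quiescence_min:
            return "tonic"
    return "burst"


def burst_durations(
    spikes: SpikeTrain,
    stimulus_window: tuple[float, float],
    burst_isi_max: float | None = None,
) -> np.ndarray:
    """Durations (ms) of spike clusters with >= 2 spikes inside the window."""
    defaults = classification_defaults()
    burst_isi_max = defaults["burst_isi_max"] if burst_isi_max is None else burst_isi_max
    lo, hi = stimulus_window
    times = spikes.times[(spikes.times >= lo) & (spikes.times <= hi)]
    if times.size < 2:
        return np.asarray([])
    gaps = np.diff(times)
    clusters = np.split(times, np.flatnonzero(gaps >= burst_isi_max) + 1)
    return np.asarray([c[-1] - c[0] for c in clusters if c.size >= 2])
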