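"""Erdos-Renyi TC-RE spiking network with external cortical and sensory drives.

Network layout: an excitatory thalamocortical relay population (TC) and an
inhibitory reticular population (RE).  TC cells excite RE cells but never
each other; RE cells inhibit TC cells and one another.  Two external
Poissonian drives impinge on the circuit: a cortical drive P (to both
populations, with the stronger cortico-RE amplitude carried by RE's larger
excitatory quantal increment) and a sensory drive S (to TC only).

All neurons advance with the forward-Euler AdEx step; drive neurons emit
inhomogeneous Poisson spikes by per-step thinning.  Spikes are delivered to
their targets at the next integration step (no axonal delay).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .params import CellParams, NetworkConfig
from .stimuli import OUNoiseSpec, StimulusSpec, drive_rate

__all__ = [
    "Connectivity",
    "RasterRecord",
    "build_connectivity",
    "simulate_network",
    "bin_population_rate",
    "membrane_statistics",
]

logger = logging.getLogger(__name__)

# (source population, target population, synapse sign) per projection
PROJECTIONS = {
    "TC_RE": ("TC", "RE", "e"),
    "RE_TC": ("RE", "TC", "i"),
    "RE_RE": ("RE", "RE", "i"),
    "P_TC": ("P", "TC", "e"),
    "P_RE": ("P", "RE", "e"),
    "S_TC": ("S", "TC", "e"),
}


@dataclass
class Connectivity:
    """Adjacency lists per directed projection in CSR-like form.

    For projection name -> (indptr, targets): targets of source neuron s are
    ``targets[indptr[s]:indptr[s+1]]`` as *global* cell indices (TC first,
    then RE).
    """

    config: NetworkConfig
    adjacency: dict = field(default_factory=dict)

    def in_degree(self, projection: str) -> np.ndarray:
        indptr, targets = self.adjacency[projection]
        _, tgt_pop, _ = PROJECTIONS[projection]
        n_tc = self.config.N_tc
        lo, hi = (0, n_tc) if tgt_pop == "TC" else (n_tc, n_tc + self.config.N_re)
        return np.bincount(targets, minlength=n_tc + self.config.N_re)[lo:hi]

    def edge_count(self, projection: str) -> int:
        return int(self.adjacency[projection][0][-1])


def build_connectivity(config: NetworkConfig, seed=None) -> Connectivity:
    """Independent Bernoulli(p) per ordered source-target pair; no RE self-edges."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_tc, n_re = config.N_tc, config.N_re
    sizes = {"TC": n_tc, "RE": n_re, "P": config.N_P, "S": config.N_S}
    offsets = {"TC": 0, "RE": n_tc}
    adjacency = {}
    for name, (src, tgt, _) in PROJECTIONS.items():
        p = config.p.get(name, 0.0)
        n_src, n_tgt = sizes[src], sizes[tgt]
        indptr = np.zeros(n_src + 1, dtype=np.int64)
        chunks = []
        for s in range(n_src):
            mask = rng.random(n_tgt) < p
            if src == tgt == "RE":
                mask[s] = False  # no self-edges
            tgts = np.flatnonzero(mask) + offsets[tgt]
            chunks.append(tgts)
            indptr[s + 1] = indptr[s] + tgts.size
        targets = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
        adjacency[name] = (indptr, targets.astype(np.int64))
    return Connectivity(config=config, adjacency=adjacency)


@dataclass
class RasterRecord:
    """Per-neuron spike times with population metadata."""

    spike_times: list            # list of float arrays, one per cell
    populations: dict            # label -> (lo, hi) global index range
    duration: float              # ms
    dt: float                    # ms

    def population_spikes(self, label: str) -> np.ndarray:
        lo, hi = self.populations[label]
        parts = [self.spike_times[i] for i in range(lo, hi)]
        return np.sort(np.concatenate(parts)) if parts else np.empty(0)

    def population_size(self, label: str) -> int:
        lo, hi = self.populations[label]
        return hi - lo

    def total_spikes(self, label: str | None = None) -> int:
        if label is None:
            return int(sum(len(s) for s in self.spike_times))
        lo, hi = self.populations[label]
        return int(sum(len(self.spike_times[i]) for i in range(lo, hi)))

    def to_rows(self) -> np.ndarray:
        """(neuron_id, spike_time_ms) rows for the two-column export format."""
        rows = [(i, t) for i, times in enumerate(self.spike_times) for t in times]
        return np.asarray(rows, dtype=float).reshape(-1, 2)


def _param_arrays(config: NetworkConfig):
    """Per-neuron parameter vectors (TC block then RE block)."""
    pe, pi = config.cell_params("TC"), config.cell_params("RE")
    n_tc, n_re = config.N_tc, config.N_re

    def vec(attr):
        return np.concatenate([
            np.full(n_tc, getattr(pe, attr)), np.full(n_re, getattr(pi, attr))
        ])

    names = ("cm", "gL", "EL", "Vt", "Delta", "a", "b", "tau_w",
             "Ee", "Ei", "V_spike", "V_reset", "t_refrac", "tau_e", "tau_i")
    return {n: vec(n) for n in names}, pe, pi


def simulate_network(
    conn: Connectivity,
    config: NetworkConfig,
    P_drive,
    S_drive,
    duration: float,
    dt: float = 0.1,
    seed=None,
    record_voltages=(),
    common_drive: tuple | None = None,
    ou_noise: OUNoiseSpec | None = None,
    init_v_jitter: float = 5.0,
    I_ext_tc=None,
    I_ext_re=None,
):
    """Advance the full TC-RE network; returns (RasterRecord, voltages dict).

    ``P_drive``/``S_drive`` are rate drives (Hz per drive neuron) as scalars
    or StimulusSpec.  ``common_drive`` = (rate_or_spec, Q_nS) adds a single
    shared Poisson source projecting onto every cell with quantal size Q (the
    dynamic-clamp-like protocol).  ``ou_noise`` adds an independent OU process
    per cell (current in pA, or conductance in nS depending on its target).
    Initial potentials are jittered uniformly within +-``init_v_jitter`` mV of
    rest to de-synchronize the startup transient.
    """
    rng = np.random.default_rng(seed)
    pars, pe, pi = _param_arrays(config)
    n_tc, n_re = config.N_tc, config.N_re
    n = n_tc + n_re
    nsteps = int(round(duration / dt))
    t_grid = np.arange(nsteps) * dt

    v = pars["EL"] + rng.uniform(-init_v_jitter, init_v_jitter, size=n)
    w = np.zeros(n)
    ge = np.zeros(n)
    gi = np.zeros(n)
    refrac = np.zeros(n)

    dec_e = np.exp(-dt / pars["tau_e"])
    dec_i = np.exp(-dt / pars["tau_i"])

    # quantal increment per projection: target population's Q of that sign,
    # unless overridden (driver-type sensory synapses)
    q_proj = {}
    for name, (_, tgt, sign) in PROJECTIONS.items():
        tp = pe if tgt == "TC" else pi
        q_proj[name] = config.Q_drive.get(name, tp.Qe if sign == "e" else tp.Qi)

    # per-step drive rates
    def rates_of(drv):
        if isinstance(drv, StimulusSpec):
            return np.asarray(drive_rate(drv, t_grid), dtype=float)
        return np.full(nsteps, float(drv))

    p_rate = rates_of(P_drive) * dt * 1e-3
    s_rate = rates_of(S_drive) * dt * 1e-3
    # optional per-population injected currents (pA), e.g. a hyperpolarizing
    # kick whose release triggers a synchronized rebound burst; a 3-tuple
    # (amplitude, t0, width) is a rectangular pulse and may be negative
    def current_of(spec):
        if spec is None:
            return None
        if isinstance(spec, tuple) and len(spec) == 3:
            amp, t0, width = spec
            return amp * ((t_grid >= t0) & (t_grid < t0 + width))
        arr = np.asarray(spec, dtype=float)
        return np.full(nsteps, float(arr)) if arr.ndim == 0 else arr

    i_tc = current_of(I_ext_tc)
    i_re = current_of(I_ext_re)
    if common_drive is not None:
        cd_rate = rates_of(common_drive[0]) * dt * 1e-3
        cd_q = float(common_drive[1])

    ou_state = None
    if ou_noise is not None:
        rho = np.exp(-dt / ou_noise.tau_corr)
        ou_innov = ou_noise.sd * np.sqrt(1.0 - rho**2)
        ou_state = rng.normal(ou_noise.mean, ou_noise.sd, size=n)

    record_voltages = list(record_voltages)
    volt = {i: np.empty(nsteps) for i in record_voltages}

    spike_lists: list[list[float]] = [[] for _ in range(n)]
    prev_spiking = np.empty(0, dtype=np.int64)

    def deliver(source_ids: np.ndarray, projection: str, dge, dgi):
        indptr, targets = conn.adjacency[projection]
        if source_ids.size == 0:
            return
        segs = [targets[indptr[s]:indptr[s + 1]] for s in source_ids]
        if not segs:
            return
        tg = np.concatenate(segs)
        if tg.size == 0:
            return
        sign = PROJECTIONS[projection][2]
        np.add.at(dge if sign == "e" else dgi, tg, q_proj[projection])

    for k in range(nsteps):
        dge = np.zeros(n)
        dgi = np.zeros(n)
        # drive spikes this step (per-step thinning)
        if p_rate[k] > 0:
            p_spk = np.flatnonzero(rng.random(config.N_P) < p_rate[k])
            deliver(p_spk, "P_TC", dge, dgi)
            deliver(p_spk, "P_RE", dge, dgi)
        if s_rate[k] > 0:
            s_spk = np.flatnonzero(rng.random(config.N_S) < s_rate[k])
            deliver(s_spk, "S_TC", dge, dgi)
        if common_drive is not None and cd_rate[k] > 0:
            if rng.random() < cd_rate[k]:
                dge += cd_q
        # recurrent spikes from the previous step
        if prev_spiking.size:
            tc_src = prev_spiking[prev_spiking < n_tc]
            re_src = prev_spiking[prev_spiking >= n_tc] - n_tc
            deliver(tc_src, "TC_RE", dge, dgi)
            deliver(re_src, "RE_TC", dge, dgi)
            deliver(re_src, "RE_RE", dge, dgi)

        ge = ge * dec_e + dge
        gi = gi * dec_i + dgi

        i_syn = ge * (pars["Ee"] - v) + gi * (pars["Ei"] - v)
        if i_tc is not None:
            i_syn[:n_tc] += i_tc[k]
        if i_re is not None:
            i_syn[n_tc:] += i_re[k]
        if ou_state is not None:
            ou_state = (ou_noise.mean + rho * (ou_state - ou_noise.mean)
                        + rng.normal(0.0, ou_innov, size=n))
            if ou_noise.target == "current":
                i_syn = i_syn + ou_state
            elif ou_noise.target == "conductance_e":
                i_syn = i_syn + np.clip(ou_state, 0, None) * (pars["Ee"] - v)
            else:
                i_syn = i_syn + np.clip(ou_state, 0, None) * (pars["Ei"] - v)

        w_new = w + dt * (pars["a"] * (v - pars["EL"]) - w) / pars["tau_w"]
        in_refrac = refrac > 0
        v_exp = np.minimum(v, pars["V_spike"])
        dv = (
            pars["gL"] * (pars["EL"] - v)
            + pars["gL"] * pars["Delta"] * np.exp((v_exp - pars["Vt"]) / pars["Delta"])
            - w
            + i_syn
        ) / pars["cm"]
        v_new = np.where(in_refrac, pars["V_reset"], v + dt * dv)
        refrac = np.maximum(refrac - dt, 0.0)

        spiking = (v_new > pars["V_spike"]) & ~in_refrac
        prev_spiking = np.flatnonzero(spiking)
        if prev_spiking.size:
            v_new[prev_spiking] = pars["V_reset"][prev_spiking]
            w_new[prev_spiking] += pars["b"][prev_spiking]
            refrac[prev_spiking] = pars["t_refrac"][prev_spiking]
            tk = t_grid[k] + dt
            for idx in prev_spiking:
                spike_lists[idx].append(tk)
        v, w = v_new, w_new
        for i in record_voltages:
            volt[i][k] = v[i]
        if k % 5000 == 0 and not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise FloatingPointError(
                f"membrane blow-up in neuron {bad} at t={t_grid[k]:.1f} ms")

    raster = RasterRecord(
        spike_times=[np.asarray(s) for s in spike_lists],
        populations={"TC": (0, n_tc), "RE": (n_tc, n)},
        duration=duration, dt=dt,
    )
    return raster, {"t": t_grid, "v": volt}


def bin_population_rate(raster: RasterRecord, population: str,
                        T_bin: float = 5.0, t_start: float = 0.0):
    """Population rate trace in Hz: spikes per bin / (N_pop * T_bin).

    Returns (bin_centers_ms, rate_hz).  By construction
    sum(rate) * N * T_bin[s] equals the spike count in [t_start, duration].
    """
    if T_bin < raster.dt:
        raise ValueError("T_bin must be at least the simulation dt")
    spikes = raster.population_spikes(population)
    spikes = spikes[spikes >= t_start]
    n_pop = raster.population_size(population)
    edges = np.arange(t_start, raster.duration + T_bin, T_bin)
    counts, _ = np.histogram(spikes, bins=edges)
    rate = counts / (n_pop * T_bin * 1e-3)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate


def membrane_statistics(
    voltages: dict,
    raster: RasterRecord,
    params: CellParams,
    t_start: float = 0.0,
    bins: int = 60,
):
    """Subthreshold membrane distribution with refractory segments removed.

    ``voltages`` is the dict returned by simulate_network (keys 't' and 'v').
    Samples within t_refrac after each spike of the same neuron are excluded,
    mirroring how the mean-field describes only the subthreshold dynamics.
    """
    if not voltages.get("v"):
        raise ValueError("no recorded voltages")
    t = voltages["t"]
    samples = []
    for idx, trace in voltages["v"].items():
        keep = t >= t_start
        for ts in raster.spike_times[idx]:
            keep &= ~((t >= ts - raster.dt) & (t < ts + params.t_refrac))
        samples.append(trace[keep])
    pooled = np.concatenate(samples) if samples else np.empty(0)
    if pooled.size == 0:
        return {"mean": np.nan, "sd": np.nan, "hist": None, "edges": None,
                "n_samples": 0, "flag": "empty sample set"}
    hist, edges = np.histogram(pooled, bins=bins, density=True)
    return {"mean": float(pooled.mean()), "sd": float(pooled.std()),
            "hist": hist, "edges": edges, "n_samples": int(pooled.size),
            "flag": None}
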