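import numpy as np
import pytest

from thalmf.network import (RasterRecord, bin_population_rate,
                            build_connectivity, membrane_statistics,
                            simulate_network)
from thalmf.params import network_defaults


@pytest.fixture(scope="module")
def small_net():
    """Quarter-scale network for fast structural tests."""
    return network_defaults(state="awake", seed=9, N_tc=120, N_re=120,
                            N_P=800, N_S=120)


class TestConnectivity:
    def test_zero_probability_gives_zero_edges(self):
        net = network_defaults(p={k: 0.0 for k in network_defaults().p})
        conn = build_connectivity(net)
        assert all(conn.edge_count(k) == 0 for k in conn.adjacency)

    def test_in_degrees_match_binomial_statistics(self):
        net = network_defaults(seed=21)
        conn = build_connectivity(net)
        # TC->RE: Binomial(500, 0.05), population-mean within 3 sigma/sqrt(N)
        d = conn.in_degree("TC_RE")
        sigma = np.sqrt(500 * 0.05 * 0.95)
        assert abs(d.mean() - 25.0) < 3 * sigma / np.sqrt(d.size)
        d_rr = conn.in_degree("RE_RE")
        sigma_rr = np.sqrt(499 * 0.3 * 0.7)
        assert abs(d_rr.mean() - 0.3 * 499) < 3 * sigma_rr / np.sqrt(d_rr.size)

    def test_no_self_edges_in_re_re(self):
        net = network_defaults(seed=22)
        conn = build_connectivity(net)
        indptr, targets = conn.adjacency["RE_RE"]
        for s in range(net.N_re):
            assert (s + net.N_tc) not in targets[indptr[s]:indptr[s + 1]]

    def test_reproducible_by_seed(self):
        net = network_defaults(seed=5)
        a = build_connectivity(net)
        b = build_connectivity(net)
        assert np.array_equal(a.adjacency["TC_RE"][1], b.adjacency["TC_RE"][1])


class TestSimulateNetwork:
    def test_silent_without_drives(self, small_net):
        conn = build_connectivity(small_net)
        raster, _ = simulate_network(conn, small_net, 0.0, 0.0, 500.0,
                                     seed=1, init_v_jitter=0.0)
        assert raster.total_spikes() == 0

    def test_awake_activity_is_inhibition_dominated(self):
        net = network_defaults(state="awake", seed=2)
        conn = build_connectivity(net)
        raster, _ = simulate_network(conn, net, 4.0, 0.0, 1500.0, seed=3)
        _, r_tc = bin_population_rate(raster, "TC", 5.0, t_start=500.0)
        _, r_re = bin_population_rate(raster, "RE", 5.0, t_start=500.0)
        assert r_re.mean() > r_tc.mean()
        assert r_re.mean() > 5.0       # RE clearly active

    def test_sleep_rectangular_pulse_gives_transient_then_silence(self):
        """A sustained sensory step in the sleep state evokes only an onset
        transient; activity collapses despite the maintained input."""
        from thalmf.stimuli import StimulusSpec
        net = network_defaults(state="sleep", seed=4)
        conn = build_connectivity(net)
        stim = StimulusSpec(kind="rectangular", A=5.0, t0=500.0, width=2000.0)
        raster, _ = simulate_network(conn, net, 0.0, stim, 2500.0, seed=5)
        t, r = bin_population_rate(raster, "TC", 25.0)
        onset = r[(t >= 500.0) & (t < 800.0)].max()
        late = r[(t >= 1500.0) & (t < 2500.0)].mean()
        assert onset > 5.0
        assert late < 0.25 * onset


class TestBinPopulationRate:
    def _raster(self, spikes_per_cell):
        return RasterRecord(
            spike_times=[np.asarray(s, dtype=float) for s in spikes_per_cell],
            populations={"TC": (0, len(spikes_per_cell))},
            duration=100.0, dt=0.1)

    def test_empty_raster_is_all_zero(self):
        raster = self._raster([[] for _ in range(10)])
        _, r = bin_population_rate(raster, "TC", 5.0)
        assert np.all(r == 0.0)

    def test_single_bin_rate_value(self):
        # 25 spikes among N=500 in one 5 ms bin -> 25/(500*0.005) = 10 Hz
        spikes = [[2.0] for _ in range(25)] + [[] for _ in range(475)]
        raster = self._raster(spikes)
        _, r = bin_population_rate(raster, "TC", 5.0)
        assert r[0] == pytest.approx(10.0)

    def test_spike_count_conservation(self, small_net):
        conn = build_connectivity(small_net)
        raster, _ = simulate_network(conn, small_net, 6.0, 0.0, 800.0, seed=6)
        for pop in ("TC", "RE"):
            _, r = bin_population_rate(raster, pop, 5.0)
            n = raster.population_size(pop)
            assert r.sum() * n * 5e-3 == pytest.approx(raster.total_spikes(pop))

    def test_bin_must_cover_dt(self, small_net):
        conn = build_connectivity(small_net)
        raster, _ = simulate_network(conn, small_net, 0.0, 0.0, 50.0, seed=7)
        with pytest.raises(ValueError):
            bin_population_rate(raster, "TC", 0.01)


class TestMembraneStatistics:
    def test_silent_network_distribution_degenerates_at_rest(self, small_net):
        conn = build_connectivity(small_net)
        raster, volt = simulate_network(conn, small_net, 0.0, 0.0, 300.0,
                                        seed=8, record_voltages=[0, 1],
                                        init_v_jitter=0.0)
        stats = membrane_statistics(volt, raster, small_net.cell_params("TC"))
        # rest sits ~0.2 mV above EL (spike-initiation exponential residual)
        assert stats["mean"] == pytest.approx(small_net.cell_params("TC").EL, abs=0.3)
        assert stats["sd"] < 0.05

    def test_refractory_samples_are_excluded(self):
        """Construct one neuron whose trace is at reset during refractoriness;
        those samples must not contaminate the distribution."""
        from thalmf.params import cell_preset
        p = cell_preset("TC_awake")
        t = np.arange(0.0, 100.0, 0.1)
        v = np.full_like(t, -65.0)
        spike_t = 50.0
        mask = (t >= spike_t) & (t < spike_t + p.t_refrac)
        v[mask] = p.V_reset + 10.0   # marker values inside the refractory window
        raster = RasterRecord(spike_times=[np.asarray([spike_t])],
                              populations={"TC": (0, 1)}, duration=100.0, dt=0.1)
        stats = membrane_statistics({"t": t, "v": {0: v}}, raster, p)
        assert stats["mean"] == pytest.approx(-65.0, abs=1e-6)

    def test_missing_voltages_is_an_error(self, small_net):
        conn = build_connectivity(small_net)
        raster, volt = simulate_network(conn, small_net, 0.0, 0.0, 100.0, seed=9)
        with pytest.raises(ValueError):
            membrane_statistics(volt, raster, small_net.cell_params("TC"))


def test_severed_inhibition_makes_tc_monotone_in_sensory_amplitude():
    """With the RE->TC projection cut, TC output can only grow with S."""
    net = network_defaults(state="awake", seed=10, N_tc=100, N_re=100,
                           N_P=500, N_S=100)
    p = dict(net.p)
    p["RE_TC"] = 0.0
    net = net.__class__(**{**net.__dict__, "p": p})
    conn = build_connectivity(net)
    rates = []
    for amp in (0.0, 10.0, 30.0):
        raster, _ = simulate_network(conn, net, 1.0, amp, 1000.0, seed=11)
        _, r = bin_population_rate(raster, "TC", 5.0, t_start=300.0)
        rates.append(r.mean())
    assert rates[0] <= rates[1] <= rates[2]
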