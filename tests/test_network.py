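"""Microcircuit construction, external drive and network simulation."""

import numpy as np
import pytest

import ca1mf
from ca1mf.network import (NetworkTopology, build_network,
                           make_external_drive, population_rate,
                           simulate_network, stationary_rates)
from ca1mf.single_cell import SpikeRecord, PYR_PARAMS, FS_PARAMS


def small_topology(**over):
    base = dict(n={"pyr": 200, "fs": 40},
                p={("pyr", "pyr"): 0.05, ("fs", "pyr"): 0.3,
                   ("pyr", "fs"): 0.2, ("fs", "fs"): 0.3},
                n_ext=200, p_ext={"pyr": 0.15, "fs": 0.3})
    base.update(over)
    return NetworkTopology(**base)


class TestTopology:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            small_topology(p={("pyr", "pyr"): 1.5, ("fs", "pyr"): 0.3,
                              ("pyr", "fs"): 0.2, ("fs", "fs"): 0.3})

    def test_convergence_matches_printed_values(self):
        top = NetworkTopology()
        assert top.convergence("pyr", "pyr") == pytest.approx(0.01 * 5000)
        assert top.convergence("fs", "pyr") == pytest.approx(0.3 * 500)
        assert top.convergence("pyr", "fs") == pytest.approx(0.2 * 5000)
        assert top.convergence("ext", "pyr") == pytest.approx(0.15 * 5000)
        assert top.convergence("ext", "fs") == pytest.approx(0.3 * 5000)


class TestBuildNetwork:
    def test_zero_probability_gives_zero_edges(self):
        top = small_topology(p={k: 0.0 for k in
                                [("pyr", "pyr"), ("fs", "pyr"),
                                 ("pyr", "fs"), ("fs", "fs")]})
        g = build_network(top, seed=0)
        assert len(g.indices) == 0

    def test_same_seed_identical_edge_sets(self):
        top = small_topology()
        g1 = build_network(top, seed=3)
        g2 = build_network(top, seed=3)
        np.testing.assert_array_equal(g1.indices, g2.indices)
        np.testing.assert_array_equal(g1.indptr, g2.indptr)
        np.testing.assert_array_equal(g1.ext_indices, g2.ext_indices)

    def test_no_self_connections(self):
        g = build_network(small_topology(), seed=4)
        for i in range(g.n_total):
            assert i not in g.indices[g.indptr[i]:g.indptr[i + 1]]

    @pytest.mark.parametrize("src,dst", [("pyr", "pyr"), ("fs", "pyr"),
                                         ("pyr", "fs"), ("fs", "fs")])
    def test_in_degrees_match_binomial_law(self, graph, reduced_top,
                                           src, dst):
        deg = graph.in_degrees(src, dst)
        p = reduced_top.p[(src, dst)]
        n_src = reduced_top.n[src] - (1 if src == dst else 0)
        mean, sd = n_src * p, np.sqrt(n_src * p * (1 - p))
        # 4-sigma band on the mean of n_dst binomial draws
        assert abs(deg.mean() - mean) < 4 * sd / np.sqrt(len(deg))

    def test_external_in_degree(self, graph, reduced_top):
        deg = graph.ext_in_degrees("pyr")
        mean = reduced_top.n_ext * reduced_top.p_ext["pyr"]
        sd = np.sqrt(mean * (1 - reduced_top.p_ext["pyr"]))
        assert abs(deg.mean() - mean) < 4 * sd / np.sqrt(len(deg))


class TestExternalDrive:
    def test_zero_rate_no_events(self):
        ev = make_external_drive(lambda t: 0.0, n_ext=50, p_ext=0.3,
                                 n_targets=20, duration=500.0, seed=0)
        assert all(len(e) == 0 for e in ev)

    def test_constant_rate_delivered_event_count(self):
        n_ext, p_ext, dur = 200, 0.15, 4000.0
        ev = make_external_drive(lambda t: 5.0, n_ext=n_ext, p_ext=p_ext,
                                 n_targets=50, duration=dur, seed=1)
        per_target = np.array([len(e) for e in ev]) / (dur / 1000.0)
        expect = 5.0 * p_ext * n_ext
        sd = np.sqrt(expect / (dur / 1000.0))
        assert abs(per_target.mean() - expect) < 3 * sd / np.sqrt(50) * 3

    def test_time_varying_rate_recovered_by_psth(self):
        rate = lambda t: 10.0 if t < 1000.0 else 2.0
        ev = make_external_drive(rate, n_ext=500, p_ext=0.2, n_targets=30,
                                 duration=2000.0, seed=2)
        allev = np.concatenate(ev)
        early = np.count_nonzero(allev < 1000.0) / (30 * 0.2 * 500)
        late = np.count_nonzero(allev >= 1000.0) / (30 * 0.2 * 500)
        assert early == pytest.approx(10.0, rel=0.15)
        assert late == pytest.approx(2.0, rel=0.25)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            make_external_drive(lambda t: -1.0, 10, 0.3, 5, 100.0)


class TestSimulateNetwork:
    def test_silent_without_drive(self):
        g = build_network(small_topology(), seed=6)
        rec = simulate_network(g, 0.0, duration=500.0, seed=7)
        assert len(rec) == 0

    def test_seed_determinism(self):
        g = build_network(small_topology(), seed=8)
        r1 = simulate_network(g, 5.0, duration=500.0, seed=9)
        r2 = simulate_network(g, 5.0, duration=500.0, seed=9)
        np.testing.assert_array_equal(r1.times, r2.times)
        np.testing.assert_array_equal(r1.ids, r2.ids)

    def test_stationary_rates_positive_with_fs_above_pyr(self, graph):
        rec = simulate_network(graph, 5.0, duration=3000.0, seed=11)
        rates = stationary_rates(rec, 3000.0)
        assert rates["pyr"] > 0
        assert rates["fs"] > rates["pyr"]

    def test_stronger_inhibition_lowers_pyramidal_rate(self, graph, syn):
        import dataclasses
        rates = []
        for q_fs in (4.0, 8.0, 16.0):
            s = dataclasses.replace(syn, q_fs=q_fs)
            rec = simulate_network(graph, 5.0, duration=2500.0, seed=12,
                                   syn=s)
            rates.append(stationary_rates(rec, 2500.0)["pyr"])
        assert rates[0] > rates[1] > rates[2]

    def test_merged_external_mode_matches_sources_statistically(self, graph):
        r_src = stationary_rates(simulate_network(
            graph, 5.0, 2500.0, seed=13, ext_mode="sources"), 2500.0)
        r_mrg = stationary_rates(simulate_network(
            graph, 5.0, 2500.0, seed=13, ext_mode="merged"), 2500.0)
        assert r_mrg["fs"] == pytest.approx(r_src["fs"], rel=0.15)

    def test_negative_drive_rejected(self, graph):
        with pytest.raises(ValueError):
            simulate_network(graph, lambda t: -2.0, duration=10.0, seed=0)


class TestPopulationRate:
    def test_single_spike_rate_arithmetic(self):
        rec = SpikeRecord(times=np.array([10.5]), ids=np.array([3]),
                          populations={"pyr": (0, 100)})
        tr = population_rate(rec, bin_ms=1.0, duration=20.0)
        assert tr.rates["pyr"][10] == pytest.approx(10.0)
        assert tr.rates["pyr"].sum() == pytest.approx(10.0)

    def test_conservation_of_spike_count(self, graph):
        rec = simulate_network(graph, 5.0, duration=1000.0, seed=14)
        tr = population_rate(rec, bin_ms=5.0, duration=1000.0)
        for pop in ("pyr", "fs"):
            lo, hi = rec.populations[pop]
            total = np.sum(tr.raw_counts[pop])
            assert total == rec.count(pop)
            recovered = np.sum(tr.rates[pop]) * (hi - lo) * 5.0 / 1000.0
            assert recovered == pytest.approx(rec.count(pop))

    def test_poisson_spikes_recover_rate(self):
        rng = np.random.default_rng(15)
        n, dur, rate = 100, 10000.0, 5.0
        counts = rng.poisson(rate * dur / 1000.0, size=n)
        times = np.concatenate([rng.uniform(0, dur, c) for c in counts])
        ids = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
        rec = SpikeRecord(times=times, ids=ids, populations={"pyr": (0, n)})
        tr = population_rate(rec, bin_ms=10.0, duration=dur)
        sd = np.sqrt(rate / (n * dur / 1000.0))
        assert np.mean(tr.rates["pyr"]) == pytest.approx(rate, abs=3 * sd)

    def test_empty_record_gives_zero_trace(self):
        rec = SpikeRecord(times=np.array([]), ids=np.array([], dtype=int),
                          populations={"pyr": (0, 10)})
        tr = population_rate(rec, bin_ms=1.0, duration=50.0)
        assert np.all(tr.rates["pyr"] == 0)
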