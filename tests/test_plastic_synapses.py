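"""Microscopic three-state potential-synapse simulator."""

import numpy as np
import pytest

from plastinet.patterns import generate_memory_set
from plastinet.plastic_synapses import (
    PlasticityParams, ConsolidationSignal,
    init_network, signal_from_memories, step, measure_connectivity,
    export_weights,
)


def _all_ones_signal(m, n):
    return ConsolidationSignal(Z=np.ones((m, n), dtype=np.uint8))


class TestInitNetwork:
    def test_saturated_filling_leaves_no_potential_state(self):
        net = init_network(40, 40, c_p=0.5, c_a=0.5, mode="single", seed=0)
        counts = net.state_counts()
        assert counts["P"] == 0

    def test_all_silent_without_initial_consolidation(self):
        net = init_network(40, 40, c_p=1.0, c_a=0.2, f1c=0.0, mode="single", seed=0)
        assert net.state_counts()["1"] == 0

    def test_exact_realized_count(self):
        net = init_network(100, 100, c_p=1.0, c_a=0.1, mode="single", seed=1)
        assert net.n_synapses == 1000
        multi = init_network(100, 100, c_p=1.0, c_a=0.1, mode="multi", seed=1)
        assert multi.n_synapses == 1000

    def test_initial_consolidated_fraction(self):
        net = init_network(100, 100, c_p=1.0, c_a=0.2, f1c=0.25, mode="single", seed=2)
        assert net.state_counts()["1"] == round(0.25 * 2000)

    def test_invalid_connectivities_rejected(self):
        with pytest.raises(ValueError):
            init_network(10, 10, c_p=0.3, c_a=0.5, mode="single", seed=0)


class TestSignalFromMemories:
    def test_empty_block(self):
        mem = generate_memory_set(0, 10, 12, 2, 2, seed=0)
        sig = signal_from_memories(mem)
        assert sig.load == 0 and sig.Z.shape == (10, 12)

    def test_single_memory_load(self):
        mem = generate_memory_set(1, 10, 12, 2, 2, seed=3)
        assert signal_from_memories(mem).load == pytest.approx(4 / 120)

    def test_expected_load_of_random_block(self):
        # E[load] = 1 - (1 - k l/(m n))**M
        m, n, k, l, M = 40, 40, 5, 5, 12
        loads = [signal_from_memories(generate_memory_set(M, m, n, k, l, seed=s)).load
                 for s in range(40)]
        expect = 1 - (1 - k * l / (m * n)) ** M
        se = np.std(loads) / np.sqrt(len(loads))
        assert abs(np.mean(loads) - expect) <= 3 * se


class TestStep:
    def test_frozen_structure_reduces_to_weight_plasticity(self, small_memories):
        net = init_network(20, 24, c_p=0.5, c_a=0.3, mode="single", seed=0)
        Z = signal_from_memories(small_memories)
        params = PlasticityParams(p_elim=0.0, p_cons=1.0, homeostasis="none")
        realized_before = net.realized_pairs.copy()
        for s in range(5):
            net = step(net, Z, params, seed=s)
        assert np.array_equal(net.realized_pairs, realized_before)

    def test_full_signal_consolidates_everything_in_one_step(self):
        # with Z=1 everywhere and p_cons=1 all realized synapses consolidate,
        # so measured effectual connectivity equals anatomical connectivity
        net = init_network(50, 50, c_p=1.0, c_a=0.2, mode="single", seed=1)
        Z = _all_ones_signal(50, 50)
        net = step(net, Z, PlasticityParams(p_cons=1.0), seed=0)
        rep = measure_connectivity(net, Z)
        assert rep.c_e == pytest.approx(rep.c_a)

    @pytest.mark.parametrize("mode", ["single", "multi"])
    def test_count_matched_homeostasis_is_exact(self, mode, small_memories):
        net = init_network(20, 24, c_p=1.0, c_a=0.2, mode=mode, seed=2)
        Z = signal_from_memories(small_memories)
        params = PlasticityParams(p_elim=0.7, p_cons=0.5, homeostasis="count_matched")
        n0 = net.n_synapses
        for s in range(20):
            net = step(net, Z, params, seed=s)
            assert net.n_synapses == n0
            if mode == "single":
                assert net.c_a == pytest.approx(n0 / (20 * 24))

    def test_state_counts_partition_potential_locations(self, small_memories):
        net = init_network(20, 24, c_p=0.7, c_a=0.3, f1c=0.4, mode="single", seed=3)
        Z = signal_from_memories(small_memories)
        n_pot = int(np.count_nonzero(net.potential))
        params = PlasticityParams(p_elim=0.5, p_cons=0.8, p_dec=0.2)
        for s in range(15):
            net = step(net, Z, params, seed=s)
            counts = net.state_counts()
            assert counts["P"] + counts["0"] + counts["1"] == n_pot

    def test_new_synapses_consolidate_only_next_step(self):
        # generation happens after consolidation within a step: synapses born
        # at requested locations stay silent until the following rehearsal
        net = init_network(30, 30, c_p=1.0, c_a=0.0, mode="single", seed=4)
        Z = _all_ones_signal(30, 30)
        params = PlasticityParams(p_gen=1.0, p_cons=1.0, homeostasis="none")
        net = step(net, Z, params, seed=0)
        assert net.state_counts()["1"] == 0 and net.state_counts()["0"] == 900
        net = step(net, Z, params, seed=1)
        assert net.state_counts()["1"] == 900

    def test_silent_synapse_lifetime_is_geometric(self):
        # unrequested silent synapses die at rate p_elim: survival after t
        # steps ~ (1 - p_elim)**t, hence mean lifetime 1/p_elim
        p_elim = 0.2
        net = init_network(100, 100, c_p=1.0, c_a=0.3, mode="single", seed=5)
        params = PlasticityParams(p_elim=p_elim, homeostasis="none", p_gen=0.0)
        survivors = [net.n_synapses]
        for s in range(8):
            net = step(net, None, params, seed=s)
            survivors.append(net.n_synapses)
        survivors = np.array(survivors, dtype=float)
        expect = survivors[0] * (1 - p_elim) ** np.arange(9)
        # binomial noise: 4 sigma on each count
        sigma = np.sqrt(expect * p_elim) + 1
        assert np.all(np.abs(survivors - expect) <= 4 * sigma * np.sqrt(np.arange(9) + 1))

    def test_effectual_connectivity_nondecreasing_under_constant_signal(
            self, small_memories):
        net = init_network(20, 24, c_p=1.0, c_a=0.2, mode="single", seed=6)
        Z = signal_from_memories(small_memories)
        params = PlasticityParams(p_elim=0.3, p_cons=1.0, p_dec=0.0)
        prev = measure_connectivity(net, Z).c_e
        for s in range(20):
            net = step(net, Z, params, seed=s)
            cur = measure_connectivity(net, Z).c_e
            assert cur >= prev - 1e-12
            assert cur <= net.c_p
            prev = cur

    def test_single_and_multi_modes_agree_for_short_replay(self):
        # both model variants give statistically indistinguishable effectual
        # connectivity over a short rehearsal of the same signal
        m = n = 300
        mem = generate_memory_set(10, m, n, 8, 8, seed=0)
        Z = signal_from_memories(mem)
        params = PlasticityParams(p_elim=0.5, p_cons=1.0)
        traj = {}
        for mode in ("single", "multi"):
            ce = []
            for rep in range(5):
                net = init_network(m, n, c_p=1.0, c_a=0.1, mode=mode, seed=100 + rep)
                row = []
                for s in range(6):
                    net = step(net, Z, params, seed=1000 * rep + s)
                    row.append(measure_connectivity(net, Z).c_e)
                ce.append(row)
            traj[mode] = np.array(ce)
        diff = traj["single"].mean(0) - traj["multi"].mean(0)
        se = np.sqrt(traj["single"].var(0) / 5 + traj["multi"].var(0) / 5) + 1e-3
        assert np.all(np.abs(diff) <= 4 * se)


class TestMeasureAndExport:
    def test_exact_signal_match_gives_full_effectual_connectivity(self):
        net = init_network(20, 20, c_p=1.0, c_a=0.3, f1c=1.0, mode="single", seed=7)
        Z = ConsolidationSignal(Z=(net.cons > 0).astype(np.uint8))
        assert measure_connectivity(net, Z).c_e == 1.0

    def test_no_consolidated_synapses_gives_zero(self, small_memories):
        net = init_network(20, 24, c_p=1.0, c_a=0.3, f1c=0.0, mode="single", seed=8)
        Z = signal_from_memories(small_memories)
        assert measure_connectivity(net, Z).c_e == 0.0

    def test_all_zero_signal_rejected(self):
        net = init_network(10, 10, c_p=1.0, c_a=0.3, mode="single", seed=9)
        with pytest.raises(ValueError):
            measure_connectivity(net, ConsolidationSignal(Z=np.zeros((10, 10))))

    def test_independent_signal_expectation(self):
        # a fresh network consolidated at fraction f1c, probed with an
        # unrelated signal: E[c_e] = c_a * f1c
        m = n = 120
        vals = []
        for s in range(30):
            net = init_network(m, n, c_p=1.0, c_a=0.3, f1c=0.5, mode="single", seed=s)
            mem = generate_memory_set(5, m, n, 10, 10, seed=1000 + s)
            Z = signal_from_memories(mem)
            vals.append(measure_connectivity(net, Z).c_e)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.3 * 0.5) <= 3 * se

    def test_export_weights_masks(self):
        net = init_network(30, 30, c_p=1.0, c_a=0.2, f1c=0.0, mode="single", seed=10)
        snap = export_weights(net)
        assert snap.W.sum() == 0
        assert np.array_equal(snap.A.astype(bool), net.realized_pairs)
        full = init_network(10, 10, c_p=1.0, c_a=1.0, f1c=1.0, mode="single", seed=0)
        assert np.all(export_weights(full).W == 1)

    def test_export_density_matches_consolidated_fraction(self):
        net = init_network(80, 80, c_p=1.0, c_a=0.25, f1c=0.4, mode="single", seed=11)
        snap = export_weights(net)
        assert snap.W.mean() == pytest.approx(0.25 * 0.4, abs=2e-3)


def test_snapshot_roundtrip(tmp_path):
    net = init_network(15, 15, c_p=0.8, c_a=0.3, f1c=0.5, mode="single", seed=12)
    p = tmp_path / "net.npz"
    net.save(p)
    from plastinet.plastic_synapses import PlasticNetwork
    back = PlasticNetwork.load(p)
    assert np.array_equal(back.silent, net.silent)
    assert np.array_equal(back.cons, net.cons)
    assert back.t == net.t
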