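"""Network assembly, integration determinism, weight resume, run config."""

import numpy as np
import pytest

from bulbnet.engine import (
    SimConfig,
    load_run_config,
    resume_from_weights,
    run_simulation,
    sim_config_from_mapping,
)
from bulbnet.presets import build_scaled_network, exemplar_stimulus
from bulbnet.stimulus import build_background, build_sniff_schedule
from bulbnet.synapses import weight_sigmoid


@pytest.fixture(scope="module")
def tiny_bundle():
    # smallest sensible network: 2 glomeruli, 10 mitral, 200 granule
    return build_scaled_network(0.02, seed=0)


class TestAssembly:
    def test_forest_structure(self, tiny_bundle):
        net = tiny_bundle.network
        flat = net.flat
        roots = np.flatnonzero(flat["parent"] < 0)
        assert len(roots) == net.n_cells
        assert np.all(flat["g_ax"][roots] == 0.0)
        # parents precede children (Hines ordering)
        nonroot = flat["parent"] >= 0
        assert np.all(flat["parent"][nonroot] < np.flatnonzero(nonroot))

    def test_reciprocal_components_share_sites(self, tiny_bundle):
        net = tiny_bundle.network
        g = net.graph
        assert g.n_pairs == net.conn_mc.size
        # AMPA and NMDA target the granule compartment, GABA the mitral one
        tgt = net.mech.tgt
        for q in range(0, g.n_pairs, max(1, g.n_pairs // 20)):
            assert tgt[net.conn_ampa[q]] == net.conn_gc[q]
            assert tgt[net.conn_nmda[q]] == net.conn_gc[q]
            assert tgt[net.conn_gaba[q]] == net.conn_mc[q]

    def test_mismatched_graph_rejected(self, tiny_bundle):
        from bulbnet.engine import Network

        other = build_scaled_network(0.03, seed=1)
        with pytest.raises(ValueError):
            Network(tiny_bundle.placement, other.network.graph)


class TestRunSimulation:
    def test_quiescent_without_input(self, tiny_bundle):
        cfg = SimConfig(duration_s=0.5)
        res = run_simulation(tiny_bundle.network, config=cfg)
        assert len(res.spikes_t) == 0
        assert res.p_exc.max(initial=0) == 0
        assert res.p_inh.max(initial=0) == 0

    def test_bit_deterministic(self, tiny_bundle):
        stim, _ = exemplar_stimulus(tiny_bundle, "focal_strong")
        sniffs = build_sniff_schedule(duration_s=0.5, seed=3)
        bg = build_background(seed=4)
        cfg = SimConfig(duration_s=0.5)
        r1 = run_simulation(tiny_bundle.network, stim, sniffs, bg, cfg)
        r2 = run_simulation(tiny_bundle.network, stim, sniffs, bg, cfg)
        assert np.array_equal(r1.spikes_t, r2.spikes_t)
        assert np.array_equal(r1.spikes_cell, r2.spikes_cell)
        assert np.array_equal(r1.p_inh, r2.p_inh)

    def test_snapshot_cadence(self, tiny_bundle):
        stim, _ = exemplar_stimulus(tiny_bundle, "focal_strong")
        sniffs = build_sniff_schedule(duration_s=1.0, seed=3)
        cfg = SimConfig(duration_s=1.0, weight_snapshot_period_s=0.25)
        res = run_simulation(tiny_bundle.network, stim, sniffs, None, cfg)
        assert len(res.snapshot_times_ms) == 4
        assert res.snapshot_times_ms[-1] == pytest.approx(1000.0)
        assert np.all(res.snap_exc >= 0) and np.all(res.snap_exc <= 1)

    def test_spike_times_sorted_and_probes_sampled(self, tiny_bundle):
        stim, _ = exemplar_stimulus(tiny_bundle, "focal_strong")
        sniffs = build_sniff_schedule(duration_s=0.4, seed=3)
        cfg = SimConfig(duration_s=0.4, probes=[(0, 0)])
        res = run_simulation(tiny_bundle.network, stim, sniffs,
                             build_background(seed=1), cfg)
        assert np.all(np.diff(res.spikes_t) >= 0)
        t, v = res.probe_trace((0, 0))
        assert len(t) == len(v) > 0
        assert v[0] == pytest.approx(-65.0)


class TestResume:
    def test_zero_snapshot_zero_counters(self, tiny_bundle):
        n = tiny_bundle.network.n_pairs
        exc, inh = resume_from_weights((np.zeros(n), np.zeros(n)),
                                       tiny_bundle.network)
        cfg = SimConfig(duration_s=0.05, plasticity_enabled=False)
        res = run_simulation(tiny_bundle.network, config=cfg,
                             initial_weights=(exc, inh))
        assert res.p_exc.max(initial=0) == 0

    def test_full_snapshot_saturated_counters(self, tiny_bundle):
        n = tiny_bundle.network.n_pairs
        cfg = SimConfig(duration_s=0.05, plasticity_enabled=False)
        res = run_simulation(tiny_bundle.network, config=cfg,
                             initial_weights=(np.ones(n), np.ones(n)))
        assert res.p_exc.min(initial=50) == 50
        assert res.p_inh.min(initial=50) == 50

    def test_resume_round_trip_idempotent(self, tiny_bundle):
        # learn briefly, snapshot, resume with frozen plasticity: the weight
        # configuration must be reproduced exactly
        stim, _ = exemplar_stimulus(tiny_bundle, "focal_strong")
        sniffs = build_sniff_schedule(duration_s=0.6, seed=5)
        res = run_simulation(tiny_bundle.network, stim, sniffs,
                             build_background(seed=6),
                             SimConfig(duration_s=0.6))
        init = resume_from_weights(res, tiny_bundle.network)
        res2 = run_simulation(tiny_bundle.network, config=SimConfig(
            duration_s=0.05, plasticity_enabled=False),
            initial_weights=init)
        exc2, inh2 = res2.final_weights()
        exc1, inh1 = res.final_weights()
        assert np.allclose(exc1, exc2) and np.allclose(inh1, inh2)

    def test_dimension_mismatch_rejected(self, tiny_bundle):
        with pytest.raises(ValueError):
            resume_from_weights((np.zeros(3), np.zeros(3)),
                                tiny_bundle.network)


class TestConfig:
    def test_dt_bound(self):
        with pytest.raises(ValueError):
            SimConfig(dt_us=50.0)
        with pytest.raises(ValueError):
            SimConfig(duration_s=0.0)

    def test_run_config_round_trip(self, tmp_path):
        path = tmp_path / "run.cfg"
        path.write_text(
            "dt_us = 20\nduration_s = 2.5\nplasticity_enabled = false\n"
            "# a comment\nweight_snapshot_period_s = 0.5\n"
        )
        cfg = sim_config_from_mapping(load_run_config(path))
        assert cfg.dt_us == 20.0
        assert cfg.duration_s == 2.5
        assert cfg.plasticity_enabled is False

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            sim_config_from_mapping({"not_a_key": "1"})

    def test_counter_inversion_matches_sigmoid(self):
        p = np.arange(0, 51)
        from bulbnet.synapses import inverse_weight_sigmoid

        assert np.array_equal(inverse_weight_sigmoid(weight_sigmoid(p)), p)
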