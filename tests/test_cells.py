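"""Morphology invariants and the single-cell calibration contracts."""

import numpy as np
import pytest

from bulbnet.cells import (
    ChannelDensities,
    CompartmentalCell,
    Compartment,
    GRANULE_REGIONS,
    Morphology,
    PassiveProperties,
    bap_attenuation_profile,
    build_granule,
    build_mitral,
    input_resistance,
    load_cell_parameters,
    membrane_time_constant,
    save_cell_parameters,
    tuft_spike_response,
)
from bulbnet.engine import simulate_cell


def isopotential_soma(rm=21084.8):
    """Single-compartment cell for Ohmic-limit checks."""
    morph = Morphology([Compartment("soma", 25.0, 25.0, -1)])
    passive = PassiveProperties(specific_membrane_resistance=rm)
    return CompartmentalCell(morph, passive, ChannelDensities({}))


class TestMorphology:
    def test_default_mitral_compartment_count(self, mitral):
        assert mitral.n == 312
        for branch in ("lateral_1", "lateral_2"):
            assert mitral.morphology.total_length(branch) == pytest.approx(1500.0)

    def test_refined_discretization_keeps_span(self):
        fine = build_mitral(max_segment_um=5.0)
        assert fine.n > 312
        lengths = [c.length_um for c in fine.morphology.compartments
                   if c.region.startswith("lateral")]
        assert max(lengths) <= 5.0
        assert fine.morphology.total_length("lateral_1") == pytest.approx(1500.0)

    def test_path_distance_zero_is_soma(self, mitral):
        assert mitral.path_to_compartment("lateral_1", 0.0) == 0

    def test_lateral_path_map_spans_dendrite(self, mitral):
        path, idx = mitral.lateral_path_map("lateral_1")
        assert path.max() == pytest.approx(1500.0, abs=1500.0 / 121)
        assert len(idx) == 121

    def test_too_few_compartments_rejected(self):
        with pytest.raises(ValueError):
            build_mitral(n_compartments=10)

    def test_granule_defaults(self, granule):
        assert granule.n == 21
        assert granule.morphology.total_length("gc_dendrite") == pytest.approx(250.0)

    def test_tree_structure_validation(self):
        with pytest.raises(ValueError):
            Morphology([Compartment("soma", 10, 10, -1),
                        Compartment("gc_dendrite", 10, 1, 5)])


class TestChannelPlacement:
    def test_granule_kdr_soma_only(self, granule):
        tip = granule.compartments_in("gc_dendrite")[-1]
        assert granule.density("kdr", tip) == 0.0
        assert granule.density("na", tip) > 0.0
        assert granule.density("kdr", 0) > 0.0

    def test_mitral_uniform_dendrites(self, mitral):
        regions = ("soma", "primary_dendrite", "tuft", "lateral_1", "lateral_2")
        dens = {mitral.channels.get(r) for r in regions}
        assert len(dens) == 1  # uniform over the dendritic tree


class TestPassiveCalibration:
    def test_input_resistance_near_100_mohm(self, mitral):
        assert input_resistance(mitral) == pytest.approx(100.0, rel=0.05)

    def test_doubling_rm_doubles_isopotential_resistance(self):
        r1 = input_resistance(isopotential_soma(20000.0))
        r2 = input_resistance(isopotential_soma(40000.0))
        assert r2 / r1 == pytest.approx(2.0, rel=0.01)

    def test_isopotential_time_constant_is_tau_m(self):
        tau = membrane_time_constant(isopotential_soma())
        assert tau == pytest.approx(20.0, rel=0.05)

    def test_capacitance_follows_time_constant(self):
        p = PassiveProperties(specific_membrane_resistance=20000.0)
        assert p.specific_membrane_resistance * p.specific_capacitance * 1e-3 \
            == pytest.approx(p.membrane_time_constant)

    def test_zero_input_rests_at_resting_potential(self, mitral):
        res = simulate_cell(mitral, 500.0, probes=[0, 150, 300])
        for q in range(3):
            _, v = res.probe_trace(q)
            assert abs(v[-1] - (-65.0)) < 1.0


class TestTuftResponse:
    def test_zero_input_no_spikes(self, mitral):
        assert tuft_spike_response(mitral, 0.0) == 0

    def test_spike_count_monotone_in_conductance(self, mitral):
        counts = [tuft_spike_response(mitral, g)
                  for g in np.arange(0.0, 10.01, 0.5)]
        assert counts[0] == 0
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 6

    def test_rediscretization_changes_count_by_at_most_one(self, mitral):
        fine = build_mitral(max_segment_um=5.0)
        assert abs(tuft_spike_response(fine, 10.0)
                   - tuft_spike_response(mitral, 10.0)) <= 1


class TestBackpropagation:
    def test_full_amplitude_to_lateral_tip_and_tuft(self, mitral):
        prof = bap_attenuation_profile(mitral)
        soma = prof["soma_peak_mv"]
        assert soma > 80.0
        assert prof["lateral_peak_mv"][-1] >= 0.8 * soma
        assert prof["apical_peak_mv"][-1] >= 0.8 * soma

    def test_dense_gaba_column_gates_backpropagation(self, mitral):
        # a fully potentiated inhibitory column: 3 x 3 nS synapses on every
        # lateral compartment over a 300 um mid-dendrite stretch
        loads = [(float(d), 3.0)
                 for d in np.arange(600.0, 901.0, 12.4) for _ in range(3)]
        prof = bap_attenuation_profile(mitral, inhibitory_loads=loads)
        assert prof["lateral_peak_abs_mv"][-1] < -40.0

    def test_no_stimulus_flat_profile(self, mitral):
        prof = bap_attenuation_profile(mitral, somatic_current=0.0)
        assert np.all(np.abs(prof["lateral_peak_mv"]) < 2.0)


class TestFiringContracts:
    def test_mitral_regular_firing(self, mitral):
        """Sustained suprathreshold somatic current: periodic, no bursting."""
        res = simulate_cell(mitral, 3000.0, iinj={0: 0.8})
        isi = np.diff(res.spike_times(0))
        isi = isi[5:]  # discard onset transient
        assert len(isi) > 20
        assert isi.std() / isi.mean() < 0.2

    def test_granule_latency_grows_with_ka(self):
        lats = []
        for gka in (10.0, 20.0, 40.0):
            ch = ChannelDensities(
                {"gc_soma": (60.0, gka, 40.0), "gc_dendrite": (60.0, gka, 0.0)},
                slow_na_regions=frozenset(GRANULE_REGIONS),
            )
            res = simulate_cell(build_granule(channels=ch), 1000.0,
                                iinj={0: 0.06})
            st = res.spike_times(0)
            assert len(st) > 0
            lats.append(st[0])
        assert lats[0] < lats[1] < lats[2]

    def test_granule_adaptation_under_strong_step(self, granule):
        """ISIs lengthen once past the onset settling; the train slows or
        stops before the step ends."""
        res = simulate_cell(granule, 800.0, iinj={0: 0.3})
        st = res.spike_times(0)
        isi = np.diff(st)
        assert len(isi) >= 2
        k = int(np.argmin(isi))
        assert np.all(np.diff(isi[k:]) >= -0.1)
        assert st[-1] < 700.0 or isi[-1] > isi.min()

    def test_gating_variables_bounded(self, mitral):
        res = simulate_cell(mitral, 200.0, iinj={0: 1.0})
        # vmax finite and physiological implies the gating stayed sane
        assert np.all(res.vmax < 200.0)


class TestParameterFiles:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "mitral.params"
        passive = PassiveProperties()
        channels = ChannelDensities.mitral_default()
        save_cell_parameters(path, passive, channels)
        p2, c2 = load_cell_parameters(path)
        assert p2 == passive
        assert c2.densities == channels.densities

    def test_granule_round_trip_keeps_slow_regions(self, tmp_path):
        path = tmp_path / "granule.params"
        save_cell_parameters(path, PassiveProperties(),
                             ChannelDensities.granule_default())
        _, c2 = load_cell_parameters(path)
        assert c2.slow_na_regions == frozenset(GRANULE_REGIONS)

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.params"
        path.write_text("this is not a parameter\n")
        with pytest.raises(ValueError):
            load_cell_parameters(path)
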