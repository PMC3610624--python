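"""Odor encoding, sniff scheduling, background drive, synthetic tables."""

import numpy as np
import pytest

from bulbnet.stimulus import (
    DEFAULT_BG_EVENT_RATE,
    EXEMPLAR_PATTERNS,
    OdorStimulus,
    OdorTable,
    build_background,
    build_sniff_schedule,
    default_glomerular_map,
    exemplar_levels,
    exemplar_odor_table,
    generate_synthetic_table,
    levels_to_conductances,
    load_odor_table,
)
from bulbnet.topology import place_cells


@pytest.fixture(scope="module")
def default_map():
    return default_glomerular_map()


@pytest.fixture(scope="module")
def full_placement(default_map):
    gloms, _ = default_map
    return place_cells(gloms, ratios=(5, 100), totals=(500, 10000), seed=0)


class TestOdorTable:
    def test_minimal_table_parses(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("odor\t0\t1\na\t0\t4\nb\t1\t0\n")
        table = load_odor_table(path)
        assert table.levels.shape == (2, 2)
        assert np.sum(table.row("a") > 0) == 1

    def test_out_of_range_level_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("odor\t0\t1\na\t0\t5\n")
        with pytest.raises(ValueError, match="out of range"):
            load_odor_table(path)

    def test_non_integer_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("odor\t0\t1\na\t0.5\t1\n")
        with pytest.raises(ValueError):
            load_odor_table(path)

    def test_empty_odor_rejected(self):
        with pytest.raises(ValueError, match="activates no glomerulus"):
            OdorTable(["a"], [0, 1], np.zeros((1, 2), dtype=np.int64))

    def test_round_trip(self, tmp_path, default_map):
        gloms, _ = default_map
        table = generate_synthetic_table(5, gloms, seed=3)
        path = tmp_path / "t.tsv"
        table.save(path)
        loaded = load_odor_table(path)
        assert np.array_equal(loaded.levels, table.levels)
        assert loaded.odor_names == table.odor_names


class TestLevelEncoding:
    def test_level4_full_strength_is_max_conductance(self, default_map,
                                                     full_placement):
        gloms, _ = default_map
        table = exemplar_odor_table(gloms, 5.0)
        stim, levels = levels_to_conductances(table, "focal_strong",
                                              full_placement, strength=1.0)
        driven4 = stim.peak_ns[levels == 4]
        assert driven4.size > 0
        assert np.all(driven4 == pytest.approx(0.5))
        assert stim.aggregate_ns.max() == pytest.approx(10.0)
        assert np.all(stim.peak_ns[levels == 0] == 0.0)

    def test_linear_in_strength(self, default_map, full_placement):
        gloms, _ = default_map
        table = exemplar_odor_table(gloms, 5.0)
        s1, _ = levels_to_conductances(table, "distributed", full_placement, 1.0)
        s05, _ = levels_to_conductances(table, "distributed", full_placement, 0.5)
        assert np.allclose(s05.peak_ns, 0.5 * s1.peak_ns)

    def test_strength_out_of_range(self, default_map, full_placement):
        gloms, _ = default_map
        table = exemplar_odor_table(gloms, 5.0)
        with pytest.raises(ValueError):
            levels_to_conductances(table, "distributed", full_placement, 1.5)

    def test_per_synapse_cap_enforced(self):
        with pytest.raises(ValueError):
            OdorStimulus(np.array([0.6]))


class TestSniffSchedule:
    def test_fixed_frequency(self):
        s = build_sniff_schedule(5.0, 5.0, 2.0, seed=0, t_first_ms=0.0)
        assert len(s.times_ms) == 10
        assert np.allclose(np.diff(s.times_ms), 200.0)

    def test_intervals_within_band(self):
        s = build_sniff_schedule(2.0, 10.0, 10.0, seed=3)
        iv = np.diff(s.times_ms)
        assert np.all(iv >= 100.0 - 1e-9) and np.all(iv <= 500.0 + 1e-9)

    def test_deterministic_under_seed(self):
        a = build_sniff_schedule(2.0, 10.0, 10.0, seed=11)
        b = build_sniff_schedule(2.0, 10.0, 10.0, seed=11)
        assert np.array_equal(a.times_ms, b.times_ms)

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            build_sniff_schedule(10.0, 2.0, 1.0, seed=0)


class TestBackground:
    def test_calibrated_mitral_rate(self, mitral):
        from bulbnet.engine import simulate_cell

        res = simulate_cell(mitral, 20000.0,
                            background_rate_hz=DEFAULT_BG_EVENT_RATE["mitral"],
                            background_seed=99)
        rate = len(res.spike_times(0)) / 20.0
        assert rate == pytest.approx(2.0, rel=0.2)

    def test_zero_rate_no_spikes(self, mitral):
        from bulbnet.engine import simulate_cell

        res = simulate_cell(mitral, 2000.0, background_rate_hz=0.0)
        assert len(res.spike_times(0)) == 0

    def test_independent_streams_reproducible(self):
        from bulbnet.engine import _bg_init

        st1, nx1 = _bg_init(5, 3, np.full(3, 0.01))
        st2, nx2 = _bg_init(5, 3, np.full(3, 0.01))
        assert np.array_equal(nx1, nx2)  # jointly reproducible
        assert len(np.unique(nx1)) == 3  # per-cell sequences differ

    def test_build_background_scales(self):
        bg = build_background(target_rate_hz=1.0)
        assert bg.event_rate_hz["mitral"] == pytest.approx(
            DEFAULT_BG_EVENT_RATE["mitral"] / 2.0
        )


class TestSyntheticTables:
    def test_outlier_free_stays_in_home_cluster(self, default_map):
        gloms, _ = default_map
        table = generate_synthetic_table(20, gloms, outlier_rate=0.0, seed=4)
        for o in range(20):
            active = np.flatnonzero(table.levels[o])
            clusters = {gloms[i].cluster for i in active}
            assert len(clusters) == 1

    def test_dimensions_match_study_table(self, default_map):
        gloms, _ = default_map
        table = generate_synthetic_table(72, gloms, seed=1)
        assert table.levels.shape == (72, 73)
        assert np.all(table.levels.sum(axis=1) > 0)

    def test_outliers_appear_at_positive_rate(self, default_map):
        gloms, _ = default_map
        table = generate_synthetic_table(40, gloms, outlier_rate=0.1, seed=2)
        n_out = 0
        for o in range(40):
            active = np.flatnonzero(table.levels[o])
            clusters = [gloms[i].cluster for i in active]
            if len(set(clusters)) > 1:
                n_out += 1
        assert n_out > 0

    def test_exemplar_site_ranges(self, default_map):
        gloms, track = default_map
        L = track.total_length
        for name, pieces in EXEMPLAR_PATTERNS.items():
            levels = exemplar_levels(gloms, name, L)
            active = np.flatnonzero(levels)
            assert active.size > 0
            for i in active:
                frac = gloms[i].ring_coordinate / L
                assert any(lo - 0.02 <= frac <= hi + 0.02
                           for (lo, hi), _ in pieces)
        # the strong exemplar is suprathreshold (levels 3-4), the weak one
        # subthreshold (levels 1-2)
        strong = exemplar_levels(gloms, "focal_strong", L)
        weak = exemplar_levels(gloms, "focal_weak", L)
        assert set(strong[strong > 0]) <= {3, 4}
        assert set(weak[weak > 0]) <= {1, 2}
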