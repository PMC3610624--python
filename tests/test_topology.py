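"""Ring projection, cell placement and reciprocal connectivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bulbnet.cells import build_mitral
from bulbnet.topology import (
    RingTrack,
    expected_synapse_count,
    generate_connectivity,
    generate_glomerular_map,
    load_glomerular_map,
    place_cells,
    project_to_ring,
    ring_distance,
    save_glomerular_map,
    scaled_geometry,
)


@pytest.fixture(scope="module")
def small_map():
    return generate_glomerular_map(8, ring_length_mm=1.0, seed=3)


@pytest.fixture(scope="module")
def mitral_template():
    return build_mitral()


class TestRingDistance:
    @pytest.mark.parametrize("a,b,L,expect", [(0.0, 0.0, 5.0, 0.0),
                                              (0.1, 4.9, 5.0, 0.2),
                                              (1.0, 3.0, 5.0, 2.0)])
    def test_examples(self, a, b, L, expect):
        assert ring_distance(a, b, L) == pytest.approx(expect)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=4.999),
           st.floats(min_value=0.0, max_value=4.999))
    def test_symmetric(self, a, b):
        assert ring_distance(a, b, 5.0) == pytest.approx(ring_distance(b, a, 5.0))


class TestProjection:
    def test_point_on_track_projects_to_itself(self):
        track = RingTrack.circle(5.0)
        # vertex 10 lies on the track; its arc length is the cumulative sum
        p = track.vertices[10]
        arc = track._seg_len[:10].sum()
        assert project_to_ring([p], track)[0] == pytest.approx(arc, abs=1e-6)

    def test_coordinates_inside_ring(self, small_map):
        gloms, track = small_map
        coords = np.array([g.ring_coordinate for g in gloms])
        assert np.all((coords >= 0) & (coords < track.total_length))

    def test_degenerate_track_rejected(self):
        with pytest.raises(ValueError):
            RingTrack(np.zeros((4, 2)))

    def test_open_track_rejected(self):
        with pytest.raises(ValueError):
            RingTrack(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]))


class TestPlacement:
    def test_cluster_counts_full_scale_ratios(self):
        gloms, _ = generate_glomerular_map(74, 5.0, seed=1)
        pl = place_cells(gloms, ratios=(5, 100), totals=(500, 10000), seed=0)
        assert np.sum(pl.mitral_glomerulus >= 0) == 370
        assert np.sum(pl.granule_glomerulus >= 0) == 7400
        assert pl.n_mitral == 500 and pl.n_granule == 10000

    def test_zero_filler_all_members(self, small_map):
        gloms, _ = small_map
        pl = place_cells(gloms, ratios=(5, 10), totals=(40, 80), seed=0,
                         ring_length=1.0)
        assert np.all(pl.mitral_glomerulus >= 0)
        assert np.all(pl.granule_glomerulus >= 0)

    def test_totals_below_ratio_rejected(self, small_map):
        gloms, _ = small_map
        with pytest.raises(ValueError):
            place_cells(gloms, ratios=(5, 100), totals=(10, 100), seed=0,
                        ring_length=1.0)

    def test_coords_sorted_within_ring(self, small_map):
        gloms, _ = small_map
        pl = place_cells(gloms, ratios=(5, 10), totals=(60, 120), seed=0,
                         ring_length=1.0)
        assert np.all(np.diff(pl.mitral_coords) >= 0)
        assert pl.mitral_coords.min() >= 0 and pl.mitral_coords.max() < 1.0


@pytest.fixture(scope="module")
def placement(small_map):
    gloms, _ = small_map
    return place_cells(gloms, ratios=(5, 20), totals=(50, 200), seed=0,
                       ring_length=1.0)


class TestConnectivity:

    def test_zero_fraction_empty_graph(self, placement, mitral_template):
        g = generate_connectivity(placement, mean_fraction=0.0,
                                  fraction_halfwidth=0.0, reach_mm=0.3,
                                  seed=1, mitral_cell=mitral_template)
        assert g.n_pairs == 0

    def test_reach_bound_exhaustive(self, placement, mitral_template):
        g = generate_connectivity(placement, reach_mm=0.3, seed=1,
                                  mitral_cell=mitral_template)
        d = ring_distance(placement.mitral_coords[g.mitral_id],
                          placement.granule_coords[g.granule_id], 1.0)
        assert np.all(d <= 0.3 + 1e-9)

    def test_deterministic_under_seed(self, placement, mitral_template):
        g1 = generate_connectivity(placement, reach_mm=0.3, seed=7,
                                   mitral_cell=mitral_template)
        g2 = generate_connectivity(placement, reach_mm=0.3, seed=7,
                                   mitral_cell=mitral_template)
        assert np.array_equal(g1.granule_id, g2.granule_id)
        assert np.array_equal(g1.mitral_comp, g2.mitral_comp)
        assert np.array_equal(g1.granule_comp, g2.granule_comp)

    def test_realized_fraction_matches_mean(self, mitral_template):
        # law of large numbers on a mid-size graph: the per-granule realized
        # fraction of eligible partners averages to the 10% mean
        gloms, _ = generate_glomerular_map(15, ring_length_mm=2.0, seed=5)
        pl = place_cells(gloms, ratios=(5, 100), totals=(80, 1600), seed=2,
                         ring_length=2.0)
        g = generate_connectivity(pl, mean_fraction=0.10,
                                  fraction_halfwidth=0.05, reach_mm=0.6,
                                  seed=3, mitral_cell=mitral_template)
        # eligible set size per granule: mitral within reach on either side
        per_granule = np.bincount(g.granule_id, minlength=pl.n_granule)
        n_elig = np.array([
            np.sum(ring_distance(pl.mitral_coords, x, 2.0) <= 0.6)
            for x in pl.granule_coords
        ])
        frac = (per_granule / n_elig).mean()
        assert frac == pytest.approx(0.10, abs=0.005)

    def test_attachment_matches_ring_distance(self, placement, mitral_template):
        g = generate_connectivity(placement, reach_mm=0.3, seed=1,
                                  mitral_cell=mitral_template)
        # the attachment path distance tracks the ring distance fraction
        d = ring_distance(placement.mitral_coords[g.mitral_id],
                          placement.granule_coords[g.granule_id], 1.0)
        path = mitral_template.path_um[g.mitral_comp]
        expect = d / 0.3 * 1500.0
        assert np.all(np.abs(path - expect) <= 1500.0 / 121 + 1e-6)

    def test_expected_count_product_arithmetic(self):
        assert expected_synapse_count(10000, 500, 0.10) == 500000.0

    def test_invalid_fraction_range(self, placement, mitral_template):
        with pytest.raises(ValueError):
            generate_connectivity(placement, mean_fraction=0.02,
                                  fraction_halfwidth=0.05,
                                  mitral_cell=mitral_template)


class TestMapIO:
    def test_round_trip(self, tmp_path, small_map):
        gloms, track = small_map
        path = tmp_path / "map.tsv"
        save_glomerular_map(path, gloms)
        loaded = load_glomerular_map(path, track)
        assert len(loaded) == len(gloms)
        # arc coordinates may differ by up to one polygon segment when a
        # point sits on the bisector between adjacent track segments
        seg = track.total_length / (len(track.vertices) - 1)
        for a, b in zip(gloms, loaded):
            assert a.id == b.id and a.cluster == b.cluster
            assert b.ring_coordinate == pytest.approx(a.ring_coordinate,
                                                      abs=seg)


class TestScaledGeometry:
    def test_reach_ratio_preserved(self):
        for s in (1.0, 0.1, 0.04):
            geo = scaled_geometry(s)
            assert geo["reach_mm"] / geo["ring_length_mm"] == pytest.approx(0.3)

    def test_full_scale_identity(self):
        geo = scaled_geometry(1.0)
        assert geo["n_mitral"] == 500 and geo["n_granule"] == 10000
        assert geo["reach_mm"] == pytest.approx(1.5)
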