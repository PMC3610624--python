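"""Ring topology: glomerular map projection, cell placement, connectivity.

The 2-D glomerular map is projected onto a closed track (default a 5 mm
circle), which removes edge effects.  Mitral and granule cells are placed
at their glomerulus's ring coordinate (1 glomerulus : 5 mitral : 100
granule) with filler cells added uniformly between clusters, and each
granule cell makes reciprocal dendrodendritic synapse pairs with a random
10+-5% of the mitral cells whose lateral dendrites overlie it (ring
distance <= the 1.5 mm dendritic reach).  Each pair attaches at the mitral
lateral-dendrite compartment whose path distance from the soma corresponds
to the ring distance to the granule cell, and at a uniformly drawn granule
dendritic compartment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cells import LATERAL_LENGTH_UM

__all__ = [
    "GlomerulusRecord",
    "RingTrack",
    "Placement",
    "ConnectivityGraph",
    "ring_distance",
    "ring_center",
    "project_to_ring",
    "place_cells",
    "generate_connectivity",
    "expected_synapse_count",
    "generate_glomerular_map",
    "load_glomerular_map",
    "save_glomerular_map",
    "scaled_geometry",
    "FULL_SCALE",
]

#: Full-scale study conditions: 73 mapped glomeruli (74 in some counts),
#: 500 mitral / 10,000 granule cells on a 5 mm ring, 1.5 mm reach.
FULL_SCALE = {
    "n_glomeruli": 73,
    "n_mitral": 500,
    "n_granule": 10000,
    "ring_length_mm": 5.0,
    "reach_mm": 1.5,
}


@dataclass
class GlomerulusRecord:
    id: int
    cluster: str
    x_mm: float
    y_mm: float
    ring_coordinate: float | None = None


@dataclass
class RingTrack:
    """Closed polyline (first vertex repeated last) used as the 1-D track."""

    vertices: np.ndarray  # (n, 2) mm

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3:
            raise ValueError("track needs at least 3 vertices")
        if not np.allclose(self.vertices[0], self.vertices[-1]):
            raise ValueError("track must be closed (first vertex = last)")
        seg = np.diff(self.vertices, axis=0)
        self._seg_len = np.hypot(seg[:, 0], seg[:, 1])
        if self.total_length <= 0:
            raise ValueError("degenerate (zero-length) track")

    @property
    def total_length(self) -> float:
        return float(self._seg_len.sum())

    @classmethod
    def circle(cls, length_mm: float = 5.0, n_vertices: int = 256) -> "RingTrack":
        radius = length_mm / (2.0 * np.pi)
        th = np.linspace(0.0, 2.0 * np.pi, n_vertices + 1)
        pts = np.column_stack([radius * np.cos(th), radius * np.sin(th)])
        pts[-1] = pts[0]
        track = cls(pts)
        # normalize so arc length is exactly length_mm despite the polygon
        track.vertices *= length_mm / track.total_length
        track._seg_len *= length_mm / track._seg_len.sum()
        return track


def ring_center(coords, length: float) -> float:
    """Circular mean position (mm) of points on the ring."""
    ang = np.asarray(coords, dtype=float) / length * 2.0 * np.pi
    mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((mean % (2.0 * np.pi)) / (2.0 * np.pi) * length)


def ring_distance(a, b, length: float):
    """Shortest distance on a ring of circumference ``length``."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    return np.minimum(d, length - d)


def signed_ring_offset(a, b, length: float):
    """Offset from a to b walking in the increasing-coordinate direction,
    in [0, length)."""
    return np.mod(np.asarray(b, dtype=float) - np.asarray(a, dtype=float), length)


def project_to_ring(points, track: RingTrack) -> np.ndarray:
    """Arc-length coordinate (mm, in [0, L)) of the nearest point on the
    track for each 2-D point."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a = track.vertices[:-1]
    b = track.vertices[1:]
    ab = b - a
    seg_len2 = np.einsum("ij,ij->i", ab, ab)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    arc0 = np.concatenate([[0.0], np.cumsum(track._seg_len)])[:-1]
    out = np.empty(pts.shape[0])
    for k, p in enumerate(pts):
        ap = p - a
        t = np.clip(np.einsum("ij,ij->i", ap, ab) / seg_len2, 0.0, 1.0)
        closest = a + t[:, None] * ab
        d2 = np.einsum("ij,ij->i", pts[k] - closest, pts[k] - closest)
        j = int(np.argmin(d2))
        out[k] = arc0[j] + t[j] * track._seg_len[j]
    return np.mod(out, track.total_length)


@dataclass
class Placement:
    """Ring coordinates of all cells plus glomerulus memberships.

    Cells are ordered by ring coordinate, so array index doubles as the
    "site" index used when describing activity maps.
    """

    mitral_coords: np.ndarray          # mm, sorted
    granule_coords: np.ndarray         # mm, sorted
    mitral_glomerulus: np.ndarray      # glomerulus id or -1 for filler
    granule_glomerulus: np.ndarray
    ring_length: float
    glomeruli: list[GlomerulusRecord] = field(default_factory=list)

    @property
    def n_mitral(self) -> int:
        return self.mitral_coords.size

    @property
    def n_granule(self) -> int:
        return self.granule_coords.size


def place_cells(
    glomeruli: list[GlomerulusRecord],
    ratios: tuple[int, int] = (5, 100),
    totals: tuple[int, int] | None = None,
    seed: int = 0,
    ring_length: float | None = None,
    jitter_mm: float | None = None,
) -> Placement:
    """Place mitral and granule cells on the ring.

    Per glomerulus, ``ratios`` cells are placed at its ring coordinate with
    a small uniform jitter; the remaining cells up to ``totals`` are filler
    cells placed uniformly on the ring (no glomerulus membership).
    """
    coords = np.array([g.ring_coordinate for g in glomeruli], dtype=float)
    if np.any(np.isnan(coords)):
        raise ValueError("glomeruli must carry ring coordinates (project first)")
    if ring_length is None:
        ring_length = FULL_SCALE["ring_length_mm"]
    if jitter_mm is None:
        # +-25 um at full scale, shrunk proportionally with the ring
        jitter_mm = 0.025 * ring_length / FULL_SCALE["ring_length_mm"]
    m_per, g_per = ratios
    n_glom = len(glomeruli)
    if totals is None:
        totals = (n_glom * m_per, n_glom * g_per)
    n_mitral, n_granule = totals
    if n_mitral < n_glom * m_per or n_granule < n_glom * g_per:
        raise ValueError("totals below the ratio-implied cluster cell counts")
    rng = np.random.default_rng(seed)
    ids = np.array([g.id for g in glomeruli])

    def _one_population(per_glom: int, total: int) -> tuple[np.ndarray, np.ndarray]:
        pos = np.repeat(coords, per_glom) + rng.uniform(
            -jitter_mm, jitter_mm, n_glom * per_glom
        )
        member = np.repeat(ids, per_glom)
        n_fill = total - n_glom * per_glom
        pos = np.concatenate([pos, rng.uniform(0.0, ring_length, n_fill)])
        member = np.concatenate([member, np.full(n_fill, -1, dtype=member.dtype)])
        pos = np.mod(pos, ring_length)
        order = np.argsort(pos, kind="stable")
        return pos[order], member[order]

    m_pos, m_mem = _one_population(m_per, n_mitral)
    g_pos, g_mem = _one_population(g_per, n_granule)
    return Placement(m_pos, g_pos, m_mem, g_mem, ring_length, list(glomeruli))


@dataclass
class ConnectivityGraph:
    """Reciprocal granule<->mitral synapse pairs with dendritic coordinates.

    Each row is one reciprocal pair: an excitatory mitral->granule component
    and an inhibitory granule->mitral component at the same dendritic site.
    ``mitral_comp``/``granule_comp`` index compartments of the canonical
    cell templates; ``branch`` is 0 for lateral_1 (increasing ring
    direction), 1 for lateral_2.
    """

    granule_id: np.ndarray
    mitral_id: np.ndarray
    branch: np.ndarray
    mitral_comp: np.ndarray
    granule_comp: np.ndarray
    n_mitral: int
    n_granule: int
    reach_mm: float

    @property
    def n_pairs(self) -> int:
        return self.granule_id.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "granule_id": self.granule_id,
                "mitral_id": self.mitral_id,
                "branch": np.where(self.branch == 0, "lateral_1", "lateral_2"),
                "mitral_compartment": self.mitral_comp,
                "granule_compartment": self.granule_comp,
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def expected_synapse_count(
    n_granule: int = 10000, n_mitral: int = 500, mean_fraction: float = 0.10
) -> float:
    """Structural estimate of pair count as the plain product
    n_granule x n_mitral x mean connection fraction (~0.5 million at full
    scale).  Actual graphs are reach-limited and therefore smaller; see
    :func:`generate_connectivity`."""
    return float(n_granule) * float(n_mitral) * float(mean_fraction)


def generate_connectivity(
    placement: Placement,
    mean_fraction: float = 0.10,
    fraction_halfwidth: float = 0.05,
    reach_mm: float = 1.5,
    seed: int = 0,
    mitral_cell=None,
    n_granule_dend: int = 20,
) -> ConnectivityGraph:
    """Draw the reciprocal synapse graph.

    Per granule cell a connection fraction f ~ U[mean-halfwidth,
    mean+halfwidth] is drawn and a fraction f of the eligible mitral cells
    (lateral dendrite overlying the granule cell, i.e. ring distance <=
    ``reach_mm`` on the side the dendrite runs) is selected.  The mitral
    attachment compartment is the lateral compartment whose fractional path
    distance matches the fractional ring distance (identical at full scale,
    where reach equals the 1.5 mm dendrite length).
    """
    if not (0.0 <= mean_fraction - fraction_halfwidth
            and mean_fraction + fraction_halfwidth <= 1.0):
        raise ValueError("connection fraction range must lie within [0, 1]")
    L = placement.ring_length
    if mitral_cell is None:
        from .cells import build_mitral

        mitral_cell = build_mitral()
    lat_path = {}
    for b, branch in enumerate(("lateral_1", "lateral_2")):
        path, idx = mitral_cell.lateral_path_map(branch)
        order = np.argsort(path)
        lat_path[b] = (path[order], idx[order])
    lat_len = LATERAL_LENGTH_UM

    rng = np.random.default_rng(seed)
    g_ids, m_ids, branches, m_comps, g_comps = [], [], [], [], []
    mc = placement.mitral_coords
    n_unconnected = 0
    for g in range(placement.n_granule):
        x = placement.granule_coords[g]
        delta = signed_ring_offset(mc, x, L)       # mitral -> granule, + dir
        on_lat1 = delta <= reach_mm
        on_lat2 = (L - delta) <= reach_mm
        eligible = np.flatnonzero(on_lat1 | on_lat2)
        if eligible.size == 0:
            n_unconnected += 1
            continue
        f = rng.uniform(mean_fraction - fraction_halfwidth,
                        mean_fraction + fraction_halfwidth)
        k = int(round(f * eligible.size))
        if k == 0:
            n_unconnected += 1
            continue
        chosen = rng.choice(eligible, size=k, replace=False)
        for m in chosen:
            if on_lat1[m]:
                b, dist = 0, delta[m]
            else:
                b, dist = 1, L - delta[m]
            path_um = dist / reach_mm * lat_len
            paths, idx = lat_path[b]
            j = int(np.argmin(np.abs(paths - path_um)))
            g_ids.append(g)
            m_ids.append(m)
            branches.append(b)
            m_comps.append(idx[j])
            g_comps.append(1 + rng.integers(n_granule_dend))
    if n_unconnected:
        logging.getLogger(__name__).info(
            "%d of %d granule cells received no reciprocal synapse",
            n_unconnected, placement.n_granule,
        )
    return ConnectivityGraph(
        np.asarray(g_ids, dtype=np.int64),
        np.asarray(m_ids, dtype=np.int64),
        np.asarray(branches, dtype=np.int64),
        np.asarray(m_comps, dtype=np.int64),
        np.asarray(g_comps, dtype=np.int64),
        n_mitral=placement.n_mitral,
        n_granule=placement.n_granule,
        reach_mm=reach_mm,
    )


def generate_glomerular_map(
    n_glomeruli: int = 73,
    ring_length_mm: float = 5.0,
    clusters: str = "ABCD",
    scatter_mm: float = 0.05,
    seed: int = 1,
    track: RingTrack | None = None,
) -> tuple[list[GlomerulusRecord], RingTrack]:
    """Synthetic glomerular map: clusters occupy contiguous arcs of a
    circular field, glomeruli scatter around the track, and the projected
    ring coordinates cover [0, L)."""
    track = track or RingTrack.circle(ring_length_mm)
    rng = np.random.default_rng(seed)
    radius = ring_length_mm / (2.0 * np.pi)
    frac = (np.arange(n_glomeruli) + 0.5) / n_glomeruli
    theta = 2.0 * np.pi * frac
    r = radius + rng.uniform(-scatter_mm, scatter_mm, n_glomeruli)
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    n_c = len(clusters)
    labels = [clusters[min(int(f * n_c), n_c - 1)] for f in frac]
    records = [
        GlomerulusRecord(i, labels[i], xy[i, 0], xy[i, 1]) for i in range(n_glomeruli)
    ]
    coords = project_to_ring(xy, track)
    for rec, c in zip(records, coords):
        rec.ring_coordinate = float(c)
    return records, track


def save_glomerular_map(path, glomeruli: list[GlomerulusRecord]) -> None:
    pd.DataFrame(
        {
            "id": [g.id for g in glomeruli],
            "cluster": [g.cluster for g in glomeruli],
            "x_mm": [g.x_mm for g in glomeruli],
            "y_mm": [g.y_mm for g in glomeruli],
        }
    ).to_csv(path, sep="\t", index=False)


def load_glomerular_map(path, track: RingTrack | None = None) -> list[GlomerulusRecord]:
    df = pd.read_csv(path, sep="\t")
    if df["id"].duplicated().any():
        raise ValueError("glomerulus ids must be unique")
    records = [
        GlomerulusRecord(int(r.id), str(r.cluster), float(r.x_mm), float(r.y_mm))
        for r in df.itertuples()
    ]
    if track is not None:
        coords = project_to_ring(
            np.column_stack([df["x_mm"], df["y_mm"]]), track
        )
        for rec, c in zip(records, coords):
            rec.ring_coordinate = float(c)
    return records


def scaled_geometry(scale: float) -> dict:
    """Shrink the full-scale study geometry by one factor, keeping
    reach/ring-length fixed at 0.3 so coverage geometry is preserved."""
    if not (0 < scale <= 1):
        raise ValueError("scale must be in (0, 1]")
    n_glom = max(2, round(FULL_SCALE["n_glomeruli"] * scale))
    L = FULL_SCALE["ring_length_mm"] * scale
    return {
        "n_glomeruli": n_glom,
        "n_mitral": max(n_glom * 5, round(FULL_SCALE["n_mitral"] * scale)),
        "n_granule": max(n_glom * 100, round(FULL_SCALE["n_granule"] * scale)),
        "ring_length_mm": L,
        "reach_mm": 0.3 * L,
    }
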