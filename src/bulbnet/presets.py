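"""Ready-made experiment setups: scaled networks and exemplar odors.

The full-scale study conditions (73 glomeruli, 500 mitral and 10,000
granule cells on a 5 mm ring, 10+-5% connectivity within the 1.5 mm
dendritic reach) shrink by a single scale factor with reach/ring-length
held at 0.3, so a desk-scale network preserves the coverage geometry of
the full system.  These helpers bundle map generation, placement,
connectivity and stimulus construction so that scripts, tests and the CLI
run the same conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cells import CompartmentalCell, build_mitral
from .engine import Network, SimConfig, SimResult, run_simulation
from .stimulus import (
    MAX_SYNAPSE_NS,
    OdorStimulus,
    build_background,
    build_sniff_schedule,
    exemplar_levels,
)
from .topology import (
    GlomerulusRecord,
    Placement,
    RingTrack,
    generate_connectivity,
    generate_glomerular_map,
    place_cells,
    scaled_geometry,
)

__all__ = ["NetworkBundle", "build_scaled_network", "exemplar_stimulus", "learning_run"]


@dataclass
class NetworkBundle:
    """A network plus the geometry it was built on."""

    network: Network
    placement: Placement
    glomeruli: list[GlomerulusRecord]
    track: RingTrack
    geometry: dict
    connectivity_seed: int

    @property
    def ring_length(self) -> float:
        return self.geometry["ring_length_mm"]

    @property
    def reach_mm(self) -> float:
        return self.geometry["reach_mm"]

    def mitral_levels(self, glom_levels: np.ndarray) -> np.ndarray:
        """Per-mitral input level from per-glomerulus levels."""
        return np.array(
            [glom_levels[g] if g >= 0 else 0
             for g in self.placement.mitral_glomerulus],
            dtype=np.int64,
        )


def build_scaled_network(
    scale: float = 0.1,
    connectivity_fraction: float = 0.10,
    fraction_halfwidth: float = 0.05,
    seed: int = 0,
    with_granule: bool = True,
    mitral: CompartmentalCell | None = None,
) -> NetworkBundle:
    """Build a network at a fraction of the full-scale study geometry.

    ``scale=0.1`` gives the desk default (~50 mitral, ~1000 granule cells
    on a 0.5 mm ring).  ``with_granule=False`` builds the granule-free
    control network (no reciprocal synapses).  The seed fixes map jitter,
    placement and connectivity.
    """
    geo = scaled_geometry(scale)
    gloms, track = generate_glomerular_map(
        geo["n_glomeruli"], geo["ring_length_mm"], seed=seed + 17
    )
    totals = (geo["n_mitral"], geo["n_granule"] if with_granule else 0)
    placement = place_cells(
        gloms,
        ratios=(5, 100) if with_granule else (5, 0),
        totals=totals,
        seed=seed + 29,
        ring_length=geo["ring_length_mm"],
    )
    mitral = mitral or build_mitral()
    graph = None
    if with_granule and connectivity_fraction > 0:
        graph = generate_connectivity(
            placement,
            mean_fraction=connectivity_fraction,
            fraction_halfwidth=min(fraction_halfwidth, connectivity_fraction),
            reach_mm=geo["reach_mm"],
            seed=seed + 41,
            mitral_cell=mitral,
        )
    net = Network(placement, graph, mitral=mitral)
    return NetworkBundle(net, placement, gloms, track, geo, seed)


def exemplar_stimulus(
    bundle: NetworkBundle, pattern: str, strength: float = 1.0
) -> tuple[OdorStimulus, np.ndarray]:
    """Stimulus for one of the shipped exemplar odors on this network.

    Returns the stimulus and the per-mitral input level (0-4).
    """
    glom_levels = exemplar_levels(bundle.glomeruli, pattern, bundle.ring_length)
    levels = bundle.mitral_levels(glom_levels)
    peaks = strength * (levels / 4.0) * MAX_SYNAPSE_NS
    return OdorStimulus(peaks, strength=strength), levels


def learning_run(
    bundle: NetworkBundle,
    pattern: str | None = "focal_strong",
    strength: float = 1.0,
    duration_s: float = 10.0,
    dt_us: float = 25.0,
    sniff_seed: int = 104729,
    background_seed: int = 7919,
    plasticity: bool = True,
    initial_weights=None,
    config: SimConfig | None = None,
) -> tuple[SimResult, np.ndarray]:
    """One odor presentation: sniffs at 2-10 Hz, background on.

    Returns (result, per-mitral input levels); ``pattern=None`` runs the
    no-odor control.
    """
    if pattern is not None:
        stim, levels = exemplar_stimulus(bundle, pattern, strength)
    else:
        stim, levels = None, np.zeros(bundle.placement.n_mitral, np.int64)
    sniffs = build_sniff_schedule(duration_s=duration_s, seed=sniff_seed)
    bg = build_background(seed=background_seed)
    cfg = config or SimConfig(dt_us=dt_us, duration_s=duration_s,
                              plasticity_enabled=plasticity)
    res = run_simulation(bundle.network, stim, sniffs, bg, cfg,
                         initial_weights=initial_weights)
    return res, levels
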