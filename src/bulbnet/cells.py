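"""Canonical multicompartment mitral and granule cell models.

The mitral cell is built from 312 compartments by default: a short axonal
stub, the soma, an apical (primary) dendrite ending in a 20-compartment
glomerular tuft, and two lateral dendrites of 1.5 mm path length each.  The
granule cell is a soma plus a 20-compartment radial dendrite totalling
250 um.  Na, K_A and K_DR conductances are distributed uniformly over the
mitral dendritic tree; granule cells carry Na and K_A everywhere but K_DR
only at the soma.

Passive properties are uniform (R_a = 150 Ohm*cm, tau_m = 20 ms) with the
specific membrane resistance calibrated so that the somatic input
resistance of the mitral cell is ~100 MOhm; see
:func:`calibrate_membrane_resistance`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .channels import ChannelKinetics

__all__ = [
    "PassiveProperties",
    "Compartment",
    "Morphology",
    "ChannelDensities",
    "CompartmentalCell",
    "VoltageTrace",
    "build_mitral",
    "build_granule",
    "mitral_morphology",
    "granule_morphology",
    "input_resistance",
    "membrane_time_constant",
    "tuft_spike_response",
    "bap_attenuation_profile",
    "calibrate_membrane_resistance",
    "load_cell_parameters",
    "save_cell_parameters",
    "MITRAL_REGIONS",
    "GRANULE_REGIONS",
    "N_TUFT_COMPARTMENTS",
    "LATERAL_LENGTH_UM",
    "GRANULE_DENDRITE_LENGTH_UM",
]

MITRAL_REGIONS = ("axon", "soma", "primary_dendrite", "tuft", "lateral_1", "lateral_2")
GRANULE_REGIONS = ("gc_soma", "gc_dendrite")

#: One odor-input synapse per tuft compartment; 20 x 0.5 nS = 10 nS aggregate.
N_TUFT_COMPARTMENTS = 20
LATERAL_LENGTH_UM = 1500.0
GRANULE_DENDRITE_LENGTH_UM = 250.0

# Calibrated specific membrane resistance giving ~100 MOhm somatic input
# resistance for the default mitral morphology (see
# calibrate_membrane_resistance); C_m follows from tau_m = R_m * C_m.
DEFAULT_RM_OHM_CM2 = 21084.8


@dataclass(frozen=True)
class PassiveProperties:
    """Uniform passive membrane properties.

    ``specific_membrane_resistance`` (Ohm*cm^2) is the calibration degree of
    freedom; ``specific_capacitance`` (uF/cm^2) is derived from the membrane
    time constant so that tau_m = R_m * C_m always holds.
    """

    axial_resistivity: float = 150.0          # Ohm*cm
    membrane_time_constant: float = 20.0      # ms
    specific_membrane_resistance: float = DEFAULT_RM_OHM_CM2  # Ohm*cm^2
    resting_potential: float = -65.0          # mV
    temperature: float = 35.0                 # degC

    @property
    def specific_capacitance(self) -> float:
        """uF/cm^2, derived: C_m = tau_m / R_m."""
        return self.membrane_time_constant * 1e3 / self.specific_membrane_resistance

    def __post_init__(self) -> None:
        if self.axial_resistivity <= 0 or self.membrane_time_constant <= 0:
            raise ValueError("axial resistivity and time constant must be positive")
        if self.specific_membrane_resistance <= 0:
            raise ValueError("specific membrane resistance must be positive")


@dataclass(frozen=True)
class Compartment:
    region: str
    length_um: float
    diam_um: float
    parent: int  # -1 for the root (soma)


@dataclass
class Morphology:
    """Tree-structured list of compartments; index 0 is the root soma."""

    compartments: list[Compartment]

    def __post_init__(self) -> None:
        roots = [i for i, c in enumerate(self.compartments) if c.parent < 0]
        if roots != [0]:
            raise ValueError("morphology must have exactly one root at index 0")
        for i, c in enumerate(self.compartments):
            if i > 0 and not (0 <= c.parent < i):
                raise ValueError(
                    f"compartment {i}: parent {c.parent} must precede it in the list"
                )

    def __len__(self) -> int:
        return len(self.compartments)

    @property
    def regions(self) -> np.ndarray:
        return np.array([c.region for c in self.compartments])

    def total_length(self, region: str) -> float:
        return sum(c.length_um for c in self.compartments if c.region == region)


@dataclass
class ChannelDensities:
    """Per-region peak conductance densities (mS/cm^2) for Na, K_A, K_DR."""

    densities: dict[str, tuple[float, float, float]]
    #: regions whose Na carries the slow inactivation (adaptation) gate
    slow_na_regions: frozenset[str] = frozenset()

    def get(self, region: str) -> tuple[float, float, float]:
        return self.densities.get(region, (0.0, 0.0, 0.0))

    @staticmethod
    def mitral_default() -> "ChannelDensities":
        # Uniform over the dendritic tree (calibrated; see docs/methods.md).
        dend = (60.0, 2.1, 50.0)
        return ChannelDensities(
            {
                "axon": (120.0, 0.0, 0.0),  # passive-plus-Na stub
                "soma": dend,
                "primary_dendrite": dend,
                "tuft": dend,
                "lateral_1": dend,
                "lateral_2": dend,
            }
        )

    @staticmethod
    def granule_default() -> "ChannelDensities":
        return ChannelDensities(
            {
                "gc_soma": (60.0, 20.0, 40.0),
                "gc_dendrite": (60.0, 20.0, 0.0),  # K_DR only in the soma
            },
            slow_na_regions=frozenset(GRANULE_REGIONS),
        )


@dataclass
class VoltageTrace:
    """Sampled membrane potential of one compartment."""

    compartment: int
    times_ms: np.ndarray
    potentials_mv: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.potentials_mv = np.asarray(self.potentials_mv, dtype=float)
        if self.times_ms.size != self.potentials_mv.size:
            raise ValueError("times and potentials must have equal length")
        if self.times_ms.size > 1 and not np.all(np.diff(self.times_ms) > 0):
            raise ValueError("sample times must be strictly increasing")

    def to_text(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times_ms, self.potentials_mv]),
            fmt="%.6g",
            delimiter="\t",
            header="time_ms\tmV",
            comments="",
        )


def _even_segments(region: str, total_um: float, n: int, diam: float, parent: int,
                   out: list[Compartment]) -> None:
    seg = total_um / n
    for k in range(n):
        out.append(Compartment(region, seg, diam, parent))
        parent = len(out) - 1


def mitral_morphology(
    n_compartments: int = 312, max_segment_um: float | None = None
) -> Morphology:
    """Mitral morphology: axon stub (3), soma, primary dendrite + tuft, two
    1500-um lateral dendrites.

    With the default 312 compartments the laterals get 121 segments each
    (~12.4 um), the primary dendrite 46 (460 um at 10 um) -- within the
    10-30 um control discretization.  ``max_segment_um`` refines every
    dendritic segment to at most that length instead.
    """
    n_axon, n_soma, n_tuft = 3, 1, N_TUFT_COMPARTMENTS
    primary_len = 460.0
    if max_segment_um is not None:
        if max_segment_um <= 0:
            raise ValueError("max_segment_um must be positive")
        n_lat = math.ceil(LATERAL_LENGTH_UM / max_segment_um)
        n_pri = math.ceil(primary_len / max_segment_um)
    else:
        if n_compartments < 12:
            raise ValueError("need at least 12 compartments (one per region, >=3 per lateral)")
        n_free = n_compartments - n_axon - n_soma - n_tuft
        if n_free < 8:
            raise ValueError(f"{n_compartments} compartments leave too few for the dendrites")
        # keep the default 46:242 primary-to-lateral split of the 312 model
        n_pri = max(1, round(n_free * 46 / 288))
        n_lat = (n_free - n_pri) // 2
        n_pri = n_free - 2 * n_lat  # absorb the rounding remainder
        if n_lat < 3:
            raise ValueError("each lateral dendrite needs at least 3 compartments")
    comps: list[Compartment] = [Compartment("soma", 25.0, 25.0, -1)]
    _even_segments("axon", 30.0, n_axon, 1.5, 0, comps)
    pri_start = len(comps)
    _even_segments("primary_dendrite", primary_len, n_pri, 3.5, 0, comps)
    pri_tip = len(comps) - 1
    # tuft: N_TUFT_COMPARTMENTS branches off the primary tip, one odor
    # synapse each; refined branches keep the synapse on the distal segment
    n_per_branch = 1
    if max_segment_um is not None:
        n_per_branch = math.ceil(15.0 / max_segment_um)
    for _ in range(n_tuft):
        parent = pri_tip
        for _k in range(n_per_branch):
            comps.append(Compartment("tuft", 15.0 / n_per_branch, 0.8, parent))
            parent = len(comps) - 1
    for branch in ("lateral_1", "lateral_2"):
        _even_segments(branch, LATERAL_LENGTH_UM, n_lat, 2.5, 0, comps)
    return Morphology(comps)


def granule_morphology() -> Morphology:
    comps: list[Compartment] = [Compartment("gc_soma", 8.0, 8.0, -1)]
    _even_segments("gc_dendrite", GRANULE_DENDRITE_LENGTH_UM, 20, 1.0, 0, comps)
    return Morphology(comps)


class CompartmentalCell:
    """A neuron as flat per-compartment arrays ready for integration."""

    def __init__(
        self,
        morphology: Morphology,
        passive: PassiveProperties,
        channels: ChannelDensities,
        kinetics: ChannelKinetics | None = None,
        cell_type: str = "cell",
    ):
        self.morphology = morphology
        self.passive = passive
        self.channels = channels
        self.kinetics = kinetics or ChannelKinetics()
        self.cell_type = cell_type
        comps = morphology.compartments
        n = len(comps)
        self.n = n
        self.region = morphology.regions
        self.parent = np.array([c.parent for c in comps], dtype=np.int64)
        length_cm = np.array([c.length_um for c in comps]) * 1e-4
        diam_cm = np.array([c.diam_um for c in comps]) * 1e-4
        self.area_cm2 = np.pi * diam_cm * length_cm
        cm = passive.specific_capacitance            # uF/cm^2
        self.cm_nf = cm * self.area_cm2 * 1e3        # nF
        self.g_leak = self.area_cm2 / passive.specific_membrane_resistance * 1e6  # uS
        # axial conductance between each compartment's center and its parent's
        half_r = (passive.axial_resistivity * length_cm / 2.0) / (
            np.pi * (diam_cm / 2.0) ** 2
        )  # Ohm
        self.g_axial = np.zeros(n)
        for i in range(1, n):
            self.g_axial[i] = 1e6 / (half_r[i] + half_r[self.parent[i]])  # uS
        dens = np.array([channels.get(c.region) for c in comps])  # mS/cm^2
        scale = self.area_cm2 * 1e3  # mS/cm^2 * cm^2 -> uS
        self.gna = dens[:, 0] * scale
        self.gka = dens[:, 1] * scale
        self.gkdr = dens[:, 2] * scale
        self.use_slow = np.array(
            [c.region in channels.slow_na_regions for c in comps], dtype=np.uint8
        )
        # path distance (um) from the soma center to each compartment center
        lengths = np.array([c.length_um for c in comps])
        self.path_um = np.zeros(n)
        for i in range(1, n):
            p = self.parent[i]
            self.path_um[i] = self.path_um[p] + (lengths[p] * (p != 0) + lengths[i]) / 2.0
        # state
        self.v = np.full(n, passive.resting_potential)
        self.gates = np.tile(
            self.kinetics.steady_state(passive.resting_potential)[:, None], (1, n)
        )

    # -- queries ---------------------------------------------------------
    def compartments_in(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.region == region)

    def density(self, channel: str, compartment: int) -> float:
        """Conductance density (mS/cm^2) of na/ka/kdr at a compartment."""
        idx = {"na": 0, "ka": 1, "kdr": 2}[channel]
        return self.channels.get(self.region[compartment])[idx]

    def path_to_compartment(self, branch: str, path_um: float) -> int:
        """Compartment index at a given path distance from the soma along a
        dendritic branch; ``path_um=0`` returns the soma itself."""
        if path_um <= 0:
            return 0
        idx = self.compartments_in(branch)
        if idx.size == 0:
            raise ValueError(f"no compartments in region {branch!r}")
        return int(idx[np.argmin(np.abs(self.path_um[idx] - path_um))])

    def lateral_path_map(self, branch: str = "lateral_1") -> tuple[np.ndarray, np.ndarray]:
        """(path distances um, compartment indices) along one lateral."""
        idx = self.compartments_in(branch)
        return self.path_um[idx], idx


def build_mitral(
    passive: PassiveProperties | None = None,
    channels: ChannelDensities | None = None,
    n_compartments: int = 312,
    max_segment_um: float | None = None,
    kinetics: ChannelKinetics | None = None,
) -> CompartmentalCell:
    """Build the canonical mitral cell (defaults: 312 compartments, two
    1.5 mm lateral dendrites)."""
    passive = passive or PassiveProperties()
    channels = channels or ChannelDensities.mitral_default()
    morph = mitral_morphology(n_compartments, max_segment_um)
    for branch in ("lateral_1", "lateral_2"):
        total = morph.total_length(branch)
        n_lat = int(np.sum(morph.regions == branch))
        seg = total / n_lat
        if abs(total - LATERAL_LENGTH_UM) > seg:
            raise ValueError(
                f"{branch} totals {total:.1f} um; must be within one segment of "
                f"{LATERAL_LENGTH_UM} um"
            )
    return CompartmentalCell(morph, passive, channels, kinetics, cell_type="mitral")


def build_granule(
    passive: PassiveProperties | None = None,
    channels: ChannelDensities | None = None,
    kinetics: ChannelKinetics | None = None,
) -> CompartmentalCell:
    """Build the canonical granule cell (soma + 20-compartment, 250 um
    radial dendrite; K_DR restricted to the soma)."""
    passive = passive or PassiveProperties()
    channels = channels or ChannelDensities.granule_default()
    kinetics = kinetics or ChannelKinetics.granule_default()
    return CompartmentalCell(
        granule_morphology(), passive, channels, kinetics, cell_type="granule"
    )


# -- measurement protocols ----------------------------------------------


def input_resistance(
    cell: CompartmentalCell,
    step_current: float = -0.05,
    passive_only: bool = True,
    steady_tol: float = 1e-3,
) -> float:
    """Somatic steady-state input resistance (MOhm) from a small current step.

    Active channels are disabled by default (the passive calibration
    measurement).  Raises if the somatic response has not reached steady
    state within 10 membrane time constants.
    """
    from .engine import simulate_cell

    tau = cell.passive.membrane_time_constant
    duration = 10.0 * tau
    res = simulate_cell(
        cell,
        duration_ms=duration,
        iinj={0: step_current},
        passive_only=passive_only,
        probes=[0],
        probe_stride=4,
    )
    t, v = res.probe_trace(0)
    v0 = cell.passive.resting_potential
    dv_end = v[-1] - v0
    # steady-state check over the last tau_m
    tail = v[t >= duration - tau]
    if abs(tail[-1] - tail[0]) > max(steady_tol * abs(dv_end), 1e-6):
        raise RuntimeError("response did not reach steady state within 10 tau_m")
    return float(dv_end / step_current)


def membrane_time_constant(cell: CompartmentalCell, step_current: float = -0.05) -> float:
    """Effective time constant (ms) of the passive somatic step response,
    from the 1-1/e point of the charging curve."""
    from .engine import simulate_cell

    duration = 12.0 * cell.passive.membrane_time_constant
    res = simulate_cell(
        cell,
        duration_ms=duration,
        iinj={0: step_current},
        passive_only=True,
        probes=[0],
        probe_stride=1,
    )
    t, v = res.probe_trace(0)
    dv = v - v[0]
    frac = dv / dv[-1]
    return float(np.interp(1.0 - np.exp(-1.0), frac, t))


def tuft_spike_response(
    cell: CompartmentalCell,
    aggregate_peak_conductance: float = 10.0,
    rise_ms: float = 20.0,
    decay_ms: float = 200.0,
    duration_ms: float = 1000.0,
) -> int:
    """Somatic spike count for one synchronous odor activation of the tuft.

    The aggregate peak conductance (nS) is split equally across the tuft
    synapses (one per tuft branch) as a double-exponential conductance with
    the given rise/decay; 10 nS is the maximal odor input and elicits 6
    spikes in the calibrated cell.
    """
    from .engine import simulate_cell

    tuft_tips = _tuft_synapse_compartments(cell)
    per_syn = aggregate_peak_conductance / len(tuft_tips)
    events = [(10.0, int(c), per_syn, rise_ms, decay_ms, 0.0) for c in tuft_tips]
    res = simulate_cell(cell, duration_ms=duration_ms, synaptic_events=events)
    return int(len(res.spike_times(0)))


def _tuft_synapse_compartments(cell: CompartmentalCell) -> np.ndarray:
    """Distal compartment of each tuft branch (one odor synapse each)."""
    idx = cell.compartments_in("tuft")
    parents = set(cell.parent[idx])
    return np.array([i for i in idx if i not in parents], dtype=np.int64)


def bap_attenuation_profile(
    cell: CompartmentalCell,
    inhibitory_loads: list[tuple[float, float]] | None = None,
    branch: str = "lateral_1",
    somatic_current: float = 2.0,
    pulse_ms: float = 2.0,
) -> dict[str, np.ndarray]:
    """Peak depolarization profile of a backpropagating somatic AP.

    ``inhibitory_loads`` is a list of (path distance um, GABA peak nS)
    conductances active on the lateral dendrite when the AP passes.
    Returns path distances and AP peak amplitudes (mV above rest) along the
    requested lateral and along the primary dendrite + tuft.
    """
    from .engine import simulate_cell

    events = []
    for path_um, g_nS in inhibitory_loads or []:
        comp = cell.path_to_compartment(branch, path_um)
        # activated shortly before the somatic pulse so the conductance is
        # near peak when the AP arrives
        events.append((5.0, comp, g_nS, 1.0, 200.0, -80.0))
    res = simulate_cell(
        cell,
        duration_ms=60.0,
        iinj={0: somatic_current},
        iinj_window=(10.0, 10.0 + pulse_ms),
        synaptic_events=events,
        track_vmax=True,
    )
    rest = cell.passive.resting_potential
    out: dict[str, np.ndarray] = {}
    lat_path, lat_idx = cell.lateral_path_map(branch)
    order = np.argsort(lat_path)
    out["lateral_path_um"] = lat_path[order]
    out["lateral_peak_mv"] = res.vmax[lat_idx[order]] - rest
    api = np.concatenate(
        [cell.compartments_in("primary_dendrite"), _tuft_synapse_compartments(cell)]
    )
    order = np.argsort(cell.path_um[api])
    out["apical_path_um"] = cell.path_um[api][order]
    out["apical_peak_mv"] = res.vmax[api[order]] - rest
    out["lateral_peak_abs_mv"] = out["lateral_peak_mv"] + rest
    out["soma_peak_mv"] = float(res.vmax[0] - rest)
    return out


def calibrate_membrane_resistance(
    target_mohm: float = 100.0,
    tol: float = 0.01,
    rm_bounds: tuple[float, float] = (5e3, 5e5),
    **mitral_kwargs,
) -> float:
    """Solve the specific membrane resistance (Ohm*cm^2) that gives the
    target somatic input resistance by bisection, holding tau_m = 20 ms
    (C_m co-varies).  Relative tolerance 1%."""
    lo, hi = rm_bounds

    def measure(rm: float) -> float:
        passive = PassiveProperties(specific_membrane_resistance=rm)
        cell = build_mitral(passive=passive, **mitral_kwargs)
        return input_resistance(cell)

    f_lo, f_hi = measure(lo) - target_mohm, measure(hi) - target_mohm
    if f_lo * f_hi > 0:
        raise RuntimeError("target input resistance not bracketed by rm_bounds")
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        f_mid = measure(mid) - target_mohm
        if abs(f_mid) <= tol * target_mohm:
            return mid
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return math.sqrt(lo * hi)


# -- plain-text parameter files ------------------------------------------


def save_cell_parameters(path, passive: PassiveProperties, channels: ChannelDensities) -> None:
    """One ``key = value`` per line; densities as region.channel keys."""
    with open(path, "w") as fh:
        fh.write(f"axial_resistivity = {passive.axial_resistivity}\n")
        fh.write(f"membrane_time_constant = {passive.membrane_time_constant}\n")
        fh.write(
            f"specific_membrane_resistance = {passive.specific_membrane_resistance}\n"
        )
        fh.write(f"resting_potential = {passive.resting_potential}\n")
        fh.write(f"temperature = {passive.temperature}\n")
        for region, (gna, gka, gkdr) in channels.densities.items():
            fh.write(f"{region}.na = {gna}\n{region}.ka = {gka}\n{region}.kdr = {gkdr}\n")
        if channels.slow_na_regions:
            fh.write("slow_na_regions = " + ",".join(sorted(channels.slow_na_regions)) + "\n")


def load_cell_parameters(path) -> tuple[PassiveProperties, ChannelDensities]:
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed parameter line: {line!r}")
            k, v = (s.strip() for s in line.split("=", 1))
            kv[k] = v
    passive = PassiveProperties(
        axial_resistivity=float(kv.pop("axial_resistivity", 150.0)),
        membrane_time_constant=float(kv.pop("membrane_time_constant", 20.0)),
        specific_membrane_resistance=float(
            kv.pop("specific_membrane_resistance", DEFAULT_RM_OHM_CM2)
        ),
        resting_potential=float(kv.pop("resting_potential", -65.0)),
        temperature=float(kv.pop("temperature", 35.0)),
    )
    slow = frozenset(
        s for s in kv.pop("slow_na_regions", "").split(",") if s
    )
    dens: dict[str, list[float]] = {}
    for key, val in kv.items():
        region, _, chan = key.partition(".")
        if chan not in ("na", "ka", "kdr"):
            raise ValueError(f"unknown parameter {key!r}")
        dens.setdefault(region, [0.0, 0.0, 0.0])[("na", "ka", "kdr").index(chan)] = float(val)
    channels = ChannelDensities({r: tuple(v) for r, v in dens.items()}, slow_na_regions=slow)
    return passive, channels
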