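"""Network assembly and time integration.

`Network` flattens a set of canonical cells (all mitral cells first, then
granule cells) plus a `ConnectivityGraph` into the arrays the numba kernel
integrates: one tree-structured forest of compartments, a table of synaptic
mechanisms (tuft odor synapses, somatic background synapses, and the
AMPA/NMDA/GABA components of every reciprocal pair) and the per-pair
plasticity counters.

`run_simulation` drives a run from an `OdorStimulus` + `SniffSchedule` +
`BackgroundDrive` under a `SimConfig`; `simulate_cell` is the single-cell
harness used by the calibration protocols.  Runs are bit-deterministic
given the configuration and seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .cells import CompartmentalCell, build_granule, build_mitral, _tuft_synapse_compartments
from .channels import ChannelKinetics, E_K, E_NA, build_gate_tables
from .synapses import (
    ExcKinetics,
    InhKinetics,
    PlasticityRule,
    inverse_weight_sigmoid,
    nmda_rise_constant,
    weight_sigmoid,
)
from .topology import ConnectivityGraph, Placement

__all__ = [
    "SimConfig",
    "SimResult",
    "Network",
    "run_simulation",
    "simulate_cell",
    "resume_from_weights",
    "load_run_config",
    "sim_config_from_mapping",
]


def load_run_config(path) -> dict[str, str]:
    """Plain-text ``key = value`` run configuration (one pair per line;
    '#' starts a comment)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            k, v = (s.strip() for s in line.split("=", 1))
            out[k] = v
    return out


def sim_config_from_mapping(kv: dict[str, str]) -> "SimConfig":
    """Build a SimConfig from string key/value pairs (unknown keys are
    rejected)."""
    known = {
        "dt_us": float, "duration_s": float,
        "plasticity_enabled": lambda s: s.lower() in ("1", "true", "yes"),
        "weight_snapshot_period_s": float, "probe_stride": int,
        "mg_mm": float, "spike_threshold_mv": float,
        "spike_refractory_ms": float, "max_spikes_per_cell_hz": float,
    }
    kwargs = {}
    for k, v in kv.items():
        if k not in known:
            raise ValueError(f"unknown run-configuration key {k!r}")
        kwargs[k] = known[k](v)
    return SimConfig(**kwargs)

_EMPTY_I = np.empty(0, np.int64)
_EMPTY_F = np.empty(0, np.float64)

MECH_ALPHA = 0
MECH_DUAL = 1


@dataclass
class SimConfig:
    """Run configuration.

    ``dt_us`` defaults to the production 25 us step; ``probes`` is a list
    of (cell id, local compartment index) voltage probes sampled every
    ``probe_stride`` steps.
    """

    dt_us: float = 25.0
    duration_s: float = 10.0
    plasticity_enabled: bool = True
    weight_snapshot_period_s: float = 1.0
    probes: list[tuple[int, int]] = field(default_factory=list)
    probe_stride: int = 8
    mg_mm: float = 1.0
    spike_threshold_mv: float = -10.0
    spike_refractory_ms: float = 2.0
    max_spikes_per_cell_hz: float = 400.0

    def __post_init__(self) -> None:
        if self.dt_us <= 0 or self.dt_us > 25.0 + 1e-9:
            raise ValueError("dt must be positive and <= 25 us for production runs")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


class SimResult:
    """Spikes, weight snapshots, probe traces and final synapse state."""

    def __init__(self, *, dt_ms, n_cells, n_mitral, spikes_cell, spikes_t,
                 snapshot_times_ms, snap_exc, snap_inh, p_exc, p_inh,
                 probe_meta, probe_times_ms, probe_buf, vmax, graph=None,
                 rule: PlasticityRule | None = None):
        self.dt_ms = dt_ms
        self.n_cells = n_cells
        self.n_mitral = n_mitral
        self.spikes_cell = spikes_cell
        self.spikes_t = spikes_t
        self.snapshot_times_ms = snapshot_times_ms
        self.snap_exc = snap_exc
        self.snap_inh = snap_inh
        self.p_exc = p_exc
        self.p_inh = p_inh
        self.probe_meta = probe_meta
        self.probe_times_ms = probe_times_ms
        self.probe_buf = probe_buf
        self.vmax = vmax
        self.graph = graph
        self.rule = rule or PlasticityRule()

    def spike_times(self, cell: int) -> np.ndarray:
        """Sorted spike times (ms) of one cell."""
        return self.spikes_t[self.spikes_cell == cell]

    def spike_trains(self) -> list[np.ndarray]:
        return [self.spike_times(c) for c in range(self.n_cells)]

    def probe_trace(self, probe) -> tuple[np.ndarray, np.ndarray]:
        """(times ms, mV) for a probe given by index or (cell, comp)."""
        if not isinstance(probe, (int, np.integer)):
            probe = self.probe_meta.index(tuple(probe))
        return self.probe_times_ms, self.probe_buf[probe]

    def voltage_trace(self, probe):
        """A probe as an exportable :class:`bulbnet.cells.VoltageTrace`."""
        from .cells import VoltageTrace

        if not isinstance(probe, (int, np.integer)):
            probe = self.probe_meta.index(tuple(probe))
        t, v = self.probe_trace(probe)
        return VoltageTrace(self.probe_meta[probe][1], t, v)

    def final_weights(self, normalized: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Per-pair (excitatory, inhibitory) weights; normalized = S(p) in
        [0, 1], otherwise nS."""
        exc = weight_sigmoid(self.p_exc, self.rule)
        inh = weight_sigmoid(self.p_inh, self.rule)
        if not normalized:
            exc = exc * self.rule.g_syn_exc
            inh = inh * self.rule.g_syn_inh
        return exc, inh

    def weight_matrix(self, component: str = "inhibitory",
                      snapshot: int | None = None) -> np.ndarray:
        """Dense mitral x granule matrix of normalized weights."""
        if self.graph is None:
            raise ValueError("run had no connectivity graph")
        if snapshot is None:
            vals = self.final_weights()[0 if component.startswith("exc") else 1]
        else:
            src = self.snap_exc if component.startswith("exc") else self.snap_inh
            vals = src[snapshot]
        mat = np.zeros((self.graph.n_mitral, self.graph.n_granule))
        np.add.at(mat, (self.graph.mitral_id, self.graph.granule_id), vals)
        return mat

    def save_spikes(self, path) -> None:
        np.savetxt(path, np.column_stack([self.spikes_cell, self.spikes_t]),
                   fmt=("%d", "%.4f"), delimiter="\t", header="cell_id\tt_ms",
                   comments="")


class _MechTable:
    """Accumulates synaptic mechanisms; finalized into flat arrays."""

    def __init__(self) -> None:
        self.tgt: list[int] = []
        self.kind: list[int] = []
        self.tau_r: list[float] = []
        self.tau_d: list[float] = []
        self.erev: list[float] = []
        self.nmda: list[int] = []

    def add(self, tgt: int, kind: int, tau_r: float, tau_d: float,
            erev: float, nmda: bool = False) -> int:
        self.tgt.append(int(tgt))
        self.kind.append(kind)
        self.tau_r.append(tau_r)
        self.tau_d.append(tau_d)
        self.erev.append(erev)
        self.nmda.append(int(nmda))
        return len(self.tgt) - 1

    def add_alpha(self, tgt: int, tau: float, erev: float) -> int:
        return self.add(tgt, MECH_ALPHA, tau, tau, erev)

    def add_dual(self, tgt: int, tau_r: float, tau_d: float, erev: float,
                 nmda: bool = False) -> int:
        return self.add(tgt, MECH_DUAL, tau_r, tau_d, erev, nmda)

    def __len__(self) -> int:
        return len(self.tgt)

    def finalize(self, dt_ms: float) -> dict[str, np.ndarray]:
        n = len(self.tgt)
        kind = np.asarray(self.kind, np.int64)
        tr = np.asarray(self.tau_r, float)
        td = np.asarray(self.tau_d, float)
        fr = np.exp(-dt_ms / tr)
        fd = np.exp(-dt_ms / td)
        inc = np.empty(n)
        ak = np.zeros(n)
        dual = np.zeros(n)
        is_alpha = kind == MECH_ALPHA
        inc[is_alpha] = np.e
        ak[is_alpha] = dt_ms / tr[is_alpha]
        dd = ~is_alpha
        tp = tr[dd] * td[dd] / (td[dd] - tr[dd]) * np.log(td[dd] / tr[dd])
        inc[dd] = 1.0 / (np.exp(-tp / td[dd]) - np.exp(-tp / tr[dd]))
        dual[dd] = 1.0
        return {
            "syn_tgt": np.asarray(self.tgt, np.int64),
            "syn_fr": fr, "syn_fd": fd, "syn_inc": inc,
            "syn_erev": np.asarray(self.erev, float),
            "syn_nmda": np.asarray(self.nmda, np.uint8),
            "syn_dual": dual, "syn_ak": ak,
        }


def _flatten_cells(cells: list[CompartmentalCell]) -> dict[str, np.ndarray]:
    """Concatenate per-cell compartment arrays into one forest."""
    parts = {k: [] for k in ("parent", "g_ax", "cm_nf", "g_leak", "gna", "gka",
                             "gkdr", "use_slow", "path_um")}
    soma = []
    offset = 0
    for cell in cells:
        p = cell.parent.copy()
        root = p < 0
        p = p + offset
        p[root] = -1
        parts["parent"].append(p)
        parts["g_ax"].append(cell.g_axial)
        parts["cm_nf"].append(cell.cm_nf)
        parts["g_leak"].append(cell.g_leak)
        parts["gna"].append(cell.gna)
        parts["gka"].append(cell.gka)
        parts["gkdr"].append(cell.gkdr)
        parts["use_slow"].append(cell.use_slow)
        parts["path_um"].append(cell.path_um)
        soma.append(offset)
        offset += cell.n
    out = {k: np.concatenate(v) for k, v in parts.items()}
    out["parent"] = out["parent"].astype(np.int64)
    out["use_slow"] = out["use_slow"].astype(np.uint8)
    out["cell_soma"] = np.asarray(soma, np.int64)
    out["n_comp"] = offset
    return out


def _balanced_leak(flat, kinetics: ChannelKinetics, v_rest: float,
                   sel: slice | np.ndarray = slice(None)) -> np.ndarray:
    """Leak reversal per compartment chosen so the resting potential is a
    steady state with channels at their resting activation."""
    ss = kinetics.steady_state(v_rest)
    m, h, s, a, b, n = ss
    g_na = flat["gna"][sel] * m ** 3 * h
    g_na = np.where(flat["use_slow"][sel] == 1, g_na * s, g_na)
    g_k = flat["gkdr"][sel] * n ** 4 + flat["gka"][sel] * a * b
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = (g_na * (v_rest - E_NA) + g_k * (v_rest - E_K)) / flat["g_leak"][sel]
    return v_rest + np.nan_to_num(shift)


def _balanced_leak_mixed(flat, mitral_kin, granule_kin, n_m_comp, v_rest):
    out = np.empty(flat["n_comp"])
    out[:n_m_comp] = _balanced_leak(flat, mitral_kin, v_rest, slice(0, n_m_comp))
    out[n_m_comp:] = _balanced_leak(flat, granule_kin, v_rest,
                                    slice(n_m_comp, None))
    return out


def _assemble_static(flat) -> np.ndarray:
    d0 = flat["g_leak"] + flat["g_ax"]
    parents = flat["parent"]
    mask = parents >= 0
    np.add.at(d0, parents[mask], flat["g_ax"][mask])
    return d0


def _splitmix_py(state: np.uint64) -> tuple[np.uint64, float]:
    with np.errstate(over="ignore"):
        state = np.uint64(state + np.uint64(0x9E3779B97F4A7C15))
        z = state
        z = np.uint64((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9))
        z = np.uint64((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB))
        z = np.uint64(z ^ (z >> np.uint64(31)))
    u = (float(z >> np.uint64(11)) + 1.0) / 9007199254740993.0
    return state, u


def _bg_init(seed: int, n_cells: int, rates_per_ms: np.ndarray):
    """Per-cell RNG states and first event times for the background drive."""
    states = np.empty(n_cells, np.uint64)
    nxt = np.full(n_cells, 1e30)
    base = np.uint64((seed * 0x9E3779B97F4A7C15 + 0x1234567) % (2 ** 64))
    for c in range(n_cells):
        with np.errstate(over="ignore"):
            st = np.uint64(base + np.uint64(c) * np.uint64(0xA24BAED4963EE407))
        st, _ = _splitmix_py(st)  # decorrelate nearby seeds
        if rates_per_ms[c] > 0:
            st, u = _splitmix_py(st)
            nxt[c] = -math.log(u) / rates_per_ms[c]
        states[c] = st
    return states, nxt


class Network:
    """A mitral-granule network bound to a placement and connectivity graph."""

    def __init__(
        self,
        placement: Placement,
        graph: ConnectivityGraph | None = None,
        mitral: CompartmentalCell | None = None,
        granule: CompartmentalCell | None = None,
        rule: PlasticityRule | None = None,
        exc_kinetics: ExcKinetics | None = None,
        inh_kinetics: InhKinetics | None = None,
    ):
        self.placement = placement
        self.graph = graph
        self.rule = rule or PlasticityRule()
        self.exc_kinetics = exc_kinetics or ExcKinetics()
        self.inh_kinetics = inh_kinetics or InhKinetics()
        self.mitral_template = mitral or build_mitral()
        self.granule_template = granule or build_granule()
        self.kinetics = self.mitral_template.kinetics
        self.n_mitral = placement.n_mitral
        self.n_granule = placement.n_granule
        if graph is not None:
            if graph.n_mitral != self.n_mitral or graph.n_granule != self.n_granule:
                raise ValueError("connectivity graph does not match placement sizes")
        cells = [self.mitral_template] * self.n_mitral + \
                [self.granule_template] * self.n_granule
        self.cell_types = np.array(
            ["mitral"] * self.n_mitral + ["granule"] * self.n_granule
        )
        self.granule_kinetics = self.granule_template.kinetics
        self.flat = _flatten_cells(cells)
        self.n_cells = self.n_mitral + self.n_granule
        self._offsets = np.concatenate([[0], np.cumsum(
            [c.n for c in cells])])[:-1]
        self.v_rest = self.mitral_template.passive.resting_potential
        n_m_comp = self.n_mitral * self.mitral_template.n
        self.flat["alt_ka"] = np.zeros(self.flat["n_comp"], np.uint8)
        self.flat["alt_ka"][n_m_comp:] = 1  # granule K_A variant
        self.flat["e_leak"] = _balanced_leak_mixed(
            self.flat, self.kinetics, self.granule_kinetics, n_m_comp, self.v_rest
        )
        self.flat["d0"] = _assemble_static(self.flat)
        self.flat["has_kdr"] = (self.flat["gkdr"] > 0).astype(np.uint8)

        mech = _MechTable()
        tuft_local = _tuft_synapse_compartments(self.mitral_template)
        ek = self.exc_kinetics
        self.tuft_mechs = np.empty((self.n_mitral, tuft_local.size), np.int64)
        for m in range(self.n_mitral):
            off = self._offsets[m]
            for j, comp in enumerate(tuft_local):
                self.tuft_mechs[m, j] = mech.add_dual(off + comp, 20.0, 200.0, 0.0)
        self.bg_mechs = np.array(
            [mech.add_alpha(self.flat["cell_soma"][c], ek.ampa_tau, 0.0)
             for c in range(self.n_cells)], np.int64)
        if graph is not None and graph.n_pairs > 0:
            nm_rise = nmda_rise_constant(ek.nmda_time_to_peak, ek.nmda_decay)
            ik = self.inh_kinetics
            self.conn_mc = self._offsets[graph.mitral_id] + graph.mitral_comp
            self.conn_gc = (self._offsets[self.n_mitral + graph.granule_id]
                            + graph.granule_comp)
            self.conn_ampa = np.array(
                [mech.add_alpha(c, ek.ampa_tau, ek.ampa_reversal)
                 for c in self.conn_gc], np.int64)
            self.conn_nmda = np.array(
                [mech.add_dual(c, nm_rise, ek.nmda_decay, ek.nmda_reversal, nmda=True)
                 for c in self.conn_gc], np.int64)
            self.conn_gaba = np.array(
                [mech.add_dual(c, ik.gaba_rise, ik.gaba_decay, ik.gaba_reversal)
                 for c in self.conn_mc], np.int64)
        else:
            self.conn_mc = self.conn_gc = _EMPTY_I
            self.conn_ampa = self.conn_nmda = self.conn_gaba = _EMPTY_I
        self.mech = mech

    @property
    def n_pairs(self) -> int:
        return self.conn_mc.size

    def global_comp(self, cell: int, comp: int) -> int:
        return int(self._offsets[cell] + comp)


def _initial_gates(kinetics: ChannelKinetics, v_rest: float, n: int) -> np.ndarray:
    return np.tile(kinetics.steady_state(v_rest)[:, None], (1, n))


def run_simulation(
    network: Network,
    stimulus=None,
    sniffs=None,
    background=None,
    config: SimConfig | None = None,
    initial_weights: tuple[np.ndarray, np.ndarray] | None = None,
) -> SimResult:
    """Integrate the network for one run.

    ``stimulus``/``sniffs``/``background`` may each be None (no odor, no
    sniffing, no background).  ``initial_weights`` is a per-pair
    (excitatory, inhibitory) normalized weight snapshot used to resume from
    a learned configuration; counters start at 0 otherwise.
    """
    config = config or SimConfig()
    dt = config.dt_us * 1e-3
    n_steps = int(round(config.duration_s * 1e3 / dt))
    flat = network.flat
    n_comp = flat["n_comp"]
    mech_arrays = network.mech.finalize(dt)
    n_mech = mech_arrays["syn_tgt"].size

    # scheduled odor events: every sniff activates every tuft synapse of
    # every driven mitral cell
    ev_step, ev_mech, ev_w = [], [], []
    if stimulus is not None and sniffs is not None and len(sniffs.times_ms):
        driven = stimulus.driven
        n_tuft = network.tuft_mechs.shape[1]
        for t in sniffs.times_ms:
            k = int(round(t / dt))
            if k >= n_steps:
                continue
            for m in driven:
                w = stimulus.peak_ns[m] * 1e-3
                for j in range(n_tuft):
                    ev_step.append(k)
                    ev_mech.append(network.tuft_mechs[m, j])
                    ev_w.append(w)
    if ev_step:
        order = np.argsort(np.asarray(ev_step), kind="stable")
        ev_step = np.asarray(ev_step, np.int64)[order]
        ev_mech = np.asarray(ev_mech, np.int64)[order]
        ev_w = np.asarray(ev_w, float)[order]
    else:
        ev_step, ev_mech, ev_w = _EMPTY_I, _EMPTY_I, _EMPTY_F

    # background
    bg_rate = np.zeros(network.n_cells)
    bg_w = 0.0
    bg_seed = 0
    if background is not None:
        for c in range(network.n_cells):
            bg_rate[c] = background.event_rate_hz.get(network.cell_types[c], 0.0) * 1e-3
        bg_w = background.unitary_ns * 1e-3
        bg_seed = background.seed
    bg_state, bg_next = _bg_init(bg_seed, network.n_cells, bg_rate)

    # plasticity counters
    rule = network.rule
    n_pairs = network.n_pairs
    if initial_weights is not None:
        exc0, inh0 = initial_weights
        if len(exc0) != n_pairs or len(inh0) != n_pairs:
            raise ValueError("initial weight snapshot does not match pair count")
        p_exc = inverse_weight_sigmoid(exc0, rule)
        p_inh = inverse_weight_sigmoid(inh0, rule)
    else:
        p_exc = np.zeros(n_pairs, np.int64)
        p_inh = np.zeros(n_pairs, np.int64)
    last_exc = np.full(n_pairs, -1e30)
    last_inh = np.full(n_pairs, -1e30)

    # snapshots
    snap_stride = 0
    snap_exc = np.empty((0, n_pairs))
    snap_inh = np.empty((0, n_pairs))
    snap_times = np.empty(0)
    if config.weight_snapshot_period_s and n_pairs:
        snap_stride = int(round(config.weight_snapshot_period_s * 1e3 / dt))
        n_snap = n_steps // snap_stride
        snap_exc = np.zeros((n_snap, n_pairs))
        snap_inh = np.zeros((n_snap, n_pairs))
        snap_times = (np.arange(n_snap) + 1) * snap_stride * dt

    # probes
    probe_meta = [tuple(p) for p in config.probes]
    probe_comp = np.array(
        [network.global_comp(c, k) for c, k in probe_meta], np.int64
    ) if probe_meta else _EMPTY_I
    n_samp = (n_steps - 1) // config.probe_stride + 1 if probe_meta else 0
    probe_buf = np.zeros((len(probe_meta), n_samp))
    probe_times = np.arange(n_samp) * config.probe_stride * dt

    # state
    v = np.full(n_comp, network.v_rest)
    n_m_comp = network.n_mitral * network.mitral_template.n
    gates = np.empty((6, n_comp))
    gates[:, :n_m_comp] = _initial_gates(network.kinetics, network.v_rest, n_m_comp)
    gates[:, n_m_comp:] = _initial_gates(
        network.granule_kinetics, network.v_rest, n_comp - n_m_comp
    )
    vmax = np.full(n_comp, network.v_rest)
    spk_cap = int(network.n_cells * config.duration_s
                  * config.max_spikes_per_cell_hz) + 1000
    spk_cell = np.zeros(spk_cap, np.int64)
    spk_time = np.zeros(spk_cap)
    last_spk = np.full(network.n_cells, -1e30)
    spk_above = np.zeros(network.n_cells, np.uint8)

    v_lo, v_step_, tab_inf, tab_fac = build_gate_tables(
        network.kinetics, dt, alt_kinetics=network.granule_kinetics
    )

    status, n_spk = _kernel.integrate(
        dt, n_steps, 0.0,
        flat["parent"], flat["g_ax"], flat["cm_nf"] / dt, flat["d0"],
        flat["g_leak"], flat["e_leak"],
        flat["gna"], flat["gka"], flat["gkdr"], flat["use_slow"], flat["has_kdr"],
        flat["alt_ka"],
        E_NA, E_K,
        v, gates[0], gates[1], gates[2], gates[3], gates[4], gates[5], vmax,
        v_lo, 1.0 / v_step_, tab_inf, tab_fac,
        np.zeros(n_comp), 1e30, 1e30,
        mech_arrays["syn_tgt"], mech_arrays["syn_fr"], mech_arrays["syn_fd"],
        mech_arrays["syn_inc"], mech_arrays["syn_erev"], mech_arrays["syn_nmda"],
        mech_arrays["syn_dual"], mech_arrays["syn_ak"],
        np.zeros(n_mech), np.zeros(n_mech), config.mg_mm,
        ev_step, ev_mech, ev_w,
        network.bg_mechs, bg_rate, bg_next, bg_state, bg_w,
        network.conn_mc, network.conn_gc,
        network.conn_ampa, network.conn_nmda, network.conn_gaba,
        p_exc, p_inh, last_exc, last_inh,
        rule.g_syn_exc * 1e-3, rule.g_syn_inh * 1e-3,
        rule.sigmoid_midpoint, rule.sigmoid_slope, rule.p_max,
        rule.isi_potentiate_below, rule.isi_depress_below,
        rule.presyn_threshold, 1 if config.plasticity_enabled else 0,
        flat["cell_soma"], spk_cell, spk_time, last_spk, spk_above,
        config.spike_threshold_mv, config.spike_refractory_ms,
        probe_comp, config.probe_stride, probe_buf,
        snap_stride, snap_exc, snap_inh,
    )
    if status == _kernel.STATUS_DIVERGED:
        raise RuntimeError(
            "numerical divergence: |V| exceeded 200 mV; check dt and conductances"
        )
    if status == _kernel.STATUS_SPIKE_OVERFLOW:
        raise RuntimeError("spike buffer overflow; raise max_spikes_per_cell_hz")
    return SimResult(
        dt_ms=dt, n_cells=network.n_cells, n_mitral=network.n_mitral,
        spikes_cell=spk_cell[:n_spk].copy(), spikes_t=spk_time[:n_spk].copy(),
        snapshot_times_ms=snap_times, snap_exc=snap_exc, snap_inh=snap_inh,
        p_exc=p_exc, p_inh=p_inh,
        probe_meta=probe_meta, probe_times_ms=probe_times, probe_buf=probe_buf,
        vmax=vmax, graph=network.graph, rule=rule,
    )


def resume_from_weights(
    snapshot: tuple[np.ndarray, np.ndarray] | SimResult,
    network: Network,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (exc, inh) per-pair weights ready to pass to
    ``run_simulation(initial_weights=...)``; counters are recovered as the
    nearest integer p with g_syn*S(p) matching the snapshot."""
    if isinstance(snapshot, SimResult):
        exc, inh = snapshot.final_weights()
    else:
        exc, inh = snapshot
    exc = np.asarray(exc, float)
    inh = np.asarray(inh, float)
    if exc.shape != (network.n_pairs,) or inh.shape != (network.n_pairs,):
        raise ValueError(
            f"snapshot has {exc.shape}/{inh.shape} entries; network has "
            f"{network.n_pairs} pairs"
        )
    return exc, inh


def simulate_cell(
    cell: CompartmentalCell,
    duration_ms: float,
    dt_ms: float = 0.025,
    iinj: dict[int, float] | None = None,
    iinj_window: tuple[float, float] | None = None,
    synaptic_events: list[tuple] | None = None,
    passive_only: bool = False,
    probes: list[int] | None = None,
    probe_stride: int = 8,
    background_rate_hz: float = 0.0,
    background_unitary_ns: float = 0.1,
    background_seed: int = 0,
    spike_threshold_mv: float = -10.0,
    track_vmax: bool = True,
) -> SimResult:
    """Integrate one isolated cell.

    ``synaptic_events`` rows are (t_ms, compartment, peak_nS, rise_ms,
    decay_ms, reversal_mV); ``iinj`` maps compartment to a constant current
    (nA) active inside ``iinj_window`` (whole run if None).
    """
    n_steps = int(round(duration_ms / dt_ms))
    n = cell.n
    parent = cell.parent.copy().astype(np.int64)
    gna = np.zeros(n) if passive_only else cell.gna
    gka = np.zeros(n) if passive_only else cell.gka
    gkdr = np.zeros(n) if passive_only else cell.gkdr
    flat = {
        "parent": parent, "g_ax": cell.g_axial, "cm_nf": cell.cm_nf,
        "g_leak": cell.g_leak, "gna": gna, "gka": gka, "gkdr": gkdr,
        "use_slow": cell.use_slow, "n_comp": n,
        "cell_soma": np.zeros(1, np.int64),
    }
    v_rest = cell.passive.resting_potential
    flat["e_leak"] = (np.full(n, v_rest) if passive_only
                      else _balanced_leak(flat, cell.kinetics, v_rest))
    d0 = _assemble_static(flat)
    has_kdr = (gkdr > 0).astype(np.uint8)

    mech = _MechTable()
    ev_step, ev_mech, ev_w = [], [], []
    for (t, comp, peak_ns, rise, decay, erev) in synaptic_events or []:
        if rise >= decay:
            m = mech.add_alpha(comp, decay, erev)
        else:
            m = mech.add_dual(comp, rise, decay, erev)
        ev_step.append(int(round(t / dt_ms)))
        ev_mech.append(m)
        ev_w.append(peak_ns * 1e-3)
    bg_rate = np.zeros(1)
    bg_mechs = np.zeros(1, np.int64)
    if background_rate_hz > 0:
        bg_mechs[0] = mech.add_alpha(0, 3.0, 0.0)
        bg_rate[0] = background_rate_hz * 1e-3
    bg_state, bg_next = _bg_init(background_seed, 1, bg_rate)
    if ev_step:
        order = np.argsort(np.asarray(ev_step), kind="stable")
        ev_step = np.asarray(ev_step, np.int64)[order]
        ev_mech = np.asarray(ev_mech, np.int64)[order]
        ev_w = np.asarray(ev_w, float)[order]
    else:
        ev_step, ev_mech, ev_w = _EMPTY_I, _EMPTY_I, _EMPTY_F
    mech_arrays = mech.finalize(dt_ms)
    n_mech = mech_arrays["syn_tgt"].size

    iinj_arr = np.zeros(n)
    for comp, amp in (iinj or {}).items():
        iinj_arr[comp] += amp
    on, off = iinj_window if iinj_window is not None else (0.0, 1e30)

    probes = probes if probes is not None else [0]
    probe_comp = np.asarray(probes, np.int64)
    n_samp = (n_steps - 1) // probe_stride + 1
    probe_buf = np.zeros((len(probes), n_samp))
    probe_times = np.arange(n_samp) * probe_stride * dt_ms

    v = np.full(n, v_rest)
    gates = _initial_gates(cell.kinetics, v_rest, n)
    vmax = np.full(n, v_rest)
    spk_cap = int(duration_ms) * 2 + 1000
    spk_cell = np.zeros(spk_cap, np.int64)
    spk_time = np.zeros(spk_cap)
    v_lo, v_step_, tab_inf, tab_fac = build_gate_tables(cell.kinetics, dt_ms)
    rule = PlasticityRule()

    status, n_spk = _kernel.integrate(
        dt_ms, n_steps, 0.0,
        flat["parent"], flat["g_ax"], flat["cm_nf"] / dt_ms, d0,
        flat["g_leak"], flat["e_leak"],
        gna, gka, gkdr, flat["use_slow"], has_kdr, np.zeros(n, np.uint8),
        E_NA, E_K,
        v, gates[0], gates[1], gates[2], gates[3], gates[4], gates[5], vmax,
        v_lo, 1.0 / v_step_, tab_inf, tab_fac,
        iinj_arr, on, off,
        mech_arrays["syn_tgt"], mech_arrays["syn_fr"], mech_arrays["syn_fd"],
        mech_arrays["syn_inc"], mech_arrays["syn_erev"], mech_arrays["syn_nmda"],
        mech_arrays["syn_dual"], mech_arrays["syn_ak"],
        np.zeros(n_mech), np.zeros(n_mech), 1.0,
        ev_step, ev_mech, ev_w,
        bg_mechs, bg_rate, bg_next, bg_state, background_unitary_ns * 1e-3,
        _EMPTY_I, _EMPTY_I, _EMPTY_I, _EMPTY_I, _EMPTY_I,
        _EMPTY_I, _EMPTY_I, _EMPTY_F, _EMPTY_F,
        rule.g_syn_exc * 1e-3, rule.g_syn_inh * 1e-3,
        rule.sigmoid_midpoint, rule.sigmoid_slope, rule.p_max,
        rule.isi_potentiate_below, rule.isi_depress_below,
        rule.presyn_threshold, 0,
        flat["cell_soma"], spk_cell, spk_time,
        np.full(1, -1e30), np.zeros(1, np.uint8),
        spike_threshold_mv, 2.0,
        probe_comp, probe_stride, probe_buf,
        0, np.empty((0, 0)), np.empty((0, 0)),
    )
    if status == _kernel.STATUS_DIVERGED:
        raise RuntimeError("numerical divergence in single-cell simulation")
    if status == _kernel.STATUS_SPIKE_OVERFLOW:
        raise RuntimeError("spike buffer overflow in single-cell simulation")
    return SimResult(
        dt_ms=dt_ms, n_cells=1, n_mitral=1 if cell.cell_type == "mitral" else 0,
        spikes_cell=spk_cell[:n_spk].copy(), spikes_t=spk_time[:n_spk].copy(),
        snapshot_times_ms=np.empty(0), snap_exc=np.empty((0, 0)),
        snap_inh=np.empty((0, 0)), p_exc=_EMPTY_I, p_inh=_EMPTY_I,
        probe_meta=[(0, int(c)) for c in probe_comp],
        probe_times_ms=probe_times, probe_buf=probe_buf, vmax=vmax,
    )
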