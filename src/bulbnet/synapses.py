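"""Synaptic conductance kinetics and the presynaptic-ISI plasticity rule.

Each reciprocal dendrodendritic synapse has an excitatory mitral->granule
component (AMPA alpha function, tau 3 ms, plus NMDA with 10 ms time to
peak, 50 ms decay and a voltage-dependent Mg block) and an inhibitory
granule->mitral component (GABA double exponential, 1/200 ms, reversal
-80 mV).  A component releases whenever its presynaptic compartment
crosses -40 mV from below.

Each component carries an integer counter p in [0, 50] updated from the
presynaptic interspike interval: ISI < 30 ms potentiates (+1), 30-250 ms
depresses (-1), > 250 ms leaves p unchanged.  The peak conductance is
w = g_syn * S(p) with the rising sigmoid S(p) = 1/(1 + exp(-(p-25)/3)), so
a synapse traverses fully-depressed to fully-potentiated in about 50
consecutive spikes of the appropriate frequency.  The rule is non-Hebbian:
it reads only presynaptic events.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .cells import VoltageTrace

__all__ = [
    "ExcKinetics",
    "InhKinetics",
    "PlasticityRule",
    "SynapseState",
    "ampa_conductance",
    "nmda_conductance",
    "gaba_conductance",
    "dual_exp_peak_time",
    "nmda_rise_constant",
    "mg_block",
    "detect_presyn_event",
    "classify_isi",
    "apply_plasticity_update",
    "weight_sigmoid",
    "inverse_weight_sigmoid",
]

from .channels import mg_block  # re-exported: shared with the kernel


@dataclass(frozen=True)
class ExcKinetics:
    ampa_tau: float = 3.0            # ms, alpha-function time constant
    ampa_reversal: float = 0.0       # mV
    nmda_time_to_peak: float = 10.0  # ms
    nmda_decay: float = 50.0         # ms
    nmda_reversal: float = 0.0       # mV
    mg_concentration: float = 1.0    # mM

    def __post_init__(self) -> None:
        if min(self.ampa_tau, self.nmda_time_to_peak, self.nmda_decay) <= 0:
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class InhKinetics:
    gaba_rise: float = 1.0       # ms
    gaba_decay: float = 200.0    # ms
    gaba_reversal: float = -80.0  # mV

    def __post_init__(self) -> None:
        if not 0 < self.gaba_rise < self.gaba_decay:
            raise ValueError("need 0 < rise < decay")


@dataclass(frozen=True)
class PlasticityRule:
    isi_potentiate_below: float = 30.0   # ms
    isi_depress_below: float = 250.0     # ms
    p_min: int = 0
    p_max: int = 50
    sigmoid_midpoint: float = 25.0
    sigmoid_slope: float = 3.0
    g_syn_exc: float = 0.5   # nS (~1 real synapse)
    g_syn_inh: float = 3.0   # nS (~5 real synapses)
    presyn_threshold: float = -40.0  # mV

    def __post_init__(self) -> None:
        if not 0 < self.isi_potentiate_below < self.isi_depress_below:
            raise ValueError("need 0 < potentiation window < depression window")
        if not self.p_min < self.sigmoid_midpoint < self.p_max:
            raise ValueError("sigmoid midpoint must lie inside [p_min, p_max]")


@dataclass(frozen=True)
class SynapseState:
    """Plasticity state of one synapse component."""

    p: int = 0
    last_event_time: float | None = None

    def weight(self, g_syn: float, rule: PlasticityRule) -> float:
        """Peak conductance w = g_syn * S(p) in the units of ``g_syn``."""
        return g_syn * weight_sigmoid(self.p, rule)


def weight_sigmoid(p, rule: PlasticityRule | None = None):
    """Rising sigmoid S(p) mapping the counter to a weight fraction."""
    rule = rule or PlasticityRule()
    return 1.0 / (1.0 + np.exp(-(np.asarray(p, dtype=float) - rule.sigmoid_midpoint)
                               / rule.sigmoid_slope))


def inverse_weight_sigmoid(s, rule: PlasticityRule | None = None):
    """Nearest integer counter p reproducing a normalized weight s."""
    rule = rule or PlasticityRule()
    s = np.clip(np.asarray(s, dtype=float), 1e-12, 1.0 - 1e-12)
    p = rule.sigmoid_midpoint + rule.sigmoid_slope * np.log(s / (1.0 - s))
    return np.clip(np.rint(p), rule.p_min, rule.p_max).astype(np.int64)


# -- conductance time courses --------------------------------------------


def ampa_conductance(t_since_event, weight: float, tau: float = 3.0):
    """Alpha-function conductance, peak ``weight`` at t = tau."""
    t = np.asarray(t_since_event, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since event must be >= 0")
    return weight * (t / tau) * np.exp(1.0 - t / tau)


def dual_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of maximum of exp(-t/tau_decay) - exp(-t/tau_rise)."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)) * np.log(tau_decay / tau_rise)


def _dual_exp(t, tau_rise: float, tau_decay: float):
    tp = dual_exp_peak_time(tau_rise, tau_decay)
    norm = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    return (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / norm


@lru_cache(maxsize=32)
def nmda_rise_constant(time_to_peak: float = 10.0, decay: float = 50.0) -> float:
    """Rise time constant of the NMDA double exponential solved from its
    time to peak."""
    return float(
        brentq(lambda tr: dual_exp_peak_time(tr, decay) - time_to_peak,
               1e-3, decay * 0.999)
    )


def nmda_conductance(
    t_since_event,
    membrane_potential,
    weight: float,
    kinetics: ExcKinetics | None = None,
):
    """NMDA conductance: normalized double exponential (peak = weight at
    the nominal time to peak) times the Mg-block factor at the given
    membrane potential."""
    k = kinetics or ExcKinetics()
    t = np.asarray(t_since_event, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since event must be >= 0")
    tr = nmda_rise_constant(k.nmda_time_to_peak, k.nmda_decay)
    return weight * _dual_exp(t, tr, k.nmda_decay) * mg_block(
        membrane_potential, k.mg_concentration
    )


def gaba_conductance(t_since_event, weight: float, kinetics: InhKinetics | None = None):
    """GABA conductance: normalized double exponential, rise 1 ms, decay
    200 ms, peak = weight."""
    k = kinetics or InhKinetics()
    t = np.asarray(t_since_event, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since event must be >= 0")
    return weight * _dual_exp(t, k.gaba_rise, k.gaba_decay)


# -- events and plasticity ------------------------------------------------


def detect_presyn_event(trace: VoltageTrace, threshold: float = -40.0) -> np.ndarray:
    """Times (ms) of upward threshold crossings of a local potential trace;
    no retrigger until the trace falls back below threshold."""
    above = trace.potentials_mv >= threshold
    crossings = above & ~np.concatenate([[False], above[:-1]])
    return trace.times_ms[crossings]


def classify_isi(isi: float, rule: PlasticityRule | None = None) -> int:
    """Weight-update direction from a presynaptic ISI: +1 below 30 ms, -1
    in the 30-250 ms band (boundaries inclusive), 0 above 250 ms."""
    rule = rule or PlasticityRule()
    if isi <= 0:
        raise ValueError("ISI must be positive")
    if isi < rule.isi_potentiate_below:
        return 1
    if isi <= rule.isi_depress_below:
        return -1
    return 0


def apply_plasticity_update(
    state: SynapseState, event_time: float, rule: PlasticityRule | None = None
) -> SynapseState:
    """Advance the counter for one presynaptic event (events must arrive in
    time order; the first event carries no ISI and leaves p unchanged)."""
    rule = rule or PlasticityRule()
    if state.last_event_time is not None:
        if event_time <= state.last_event_time:
            raise ValueError("events must be processed in increasing time order")
        delta = classify_isi(event_time - state.last_event_time, rule)
    else:
        delta = 0
    p = int(np.clip(state.p + delta, rule.p_min, rule.p_max))
    return SynapseState(p=p, last_event_time=event_time)
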