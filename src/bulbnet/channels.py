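"""Voltage-gated channel kinetics for mitral and granule cells.

Three conductances are used throughout the network: a fast sodium current
(transient, Traub-style rate functions), a delayed-rectifier potassium
current (K_DR), and an inactivating A-type potassium current (K_A).  Granule
cells additionally carry a slow sodium-inactivation gate that produces
spike-frequency adaptation under strong sustained input.

The rate functions are expressed at the operating temperature of the model
(35 degC); no separate Q10 scaling is applied.  All parameters are plain
module-level defaults collected in :class:`ChannelKinetics`, so the
calibration contracts (input resistance, spike counts, backpropagation,
latency and adaptation) -- not any particular parameter file -- define the
model.

Gate state variables are updated with the Rush-Larsen exponential scheme
using per-timestep lookup tables built by :func:`build_gate_tables`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChannelKinetics",
    "GATE_NAMES",
    "build_gate_tables",
    "mg_block",
]

#: Order of gating variables in table/state arrays.
GATE_NAMES = ("na_m", "na_h", "na_s", "ka_a", "ka_b", "kdr_n")

E_NA = 50.0  # mV
E_K = -90.0  # mV


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (exp(x/y) - 1) with the removable singularity at x=0 handled."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x / y) < 1e-6
    out[small] = y * (1.0 - x[small] / y / 2.0)
    xs = x[~small]
    out[~small] = xs / np.expm1(xs / y)
    return out


@dataclass
class ChannelKinetics:
    """Rate-function parameters, exposed for calibration.

    ``na_vshift`` shifts the Na/K_DR activation range (a Traub-style
    threshold parameter); the K_A parameters place the A-current in the
    perithreshold range where it delays spike onset; the slow gate
    parameters control granule-cell adaptation.
    """

    na_vshift: float = -58.0     # mV, Traub VT
    na_h_half: float | None = None  # mV; overrides the h steady state
    na_h_slope: float = 4.0      # mV, with na_h_half
    mtau_min: float = 0.02       # ms
    htau_min: float = 0.2        # ms
    ntau_min: float = 0.2        # ms
    kdr_tau_scale: float = 2.0   # slows K_DR (de)activation; sets the AHP
    kdr_b_scale: float = 0.12    # scales the closing rate only: smaller
                                 # values lengthen the AHP without slowing
                                 # spike repolarization onset
    ka_a_half: float = -38.0     # mV
    ka_a_slope: float = 6.0      # mV
    ka_b_half: float = 200.0     # mV (inactivation disabled by default)
    ka_b_slope: float = 6.6      # mV
    ka_tau_a: float = 25.0       # ms
    ka_tau_b: float = 30.0       # ms
    slow_half: float = -42.0     # mV
    slow_slope: float = 4.0      # mV
    slow_tau: float = 150.0      # ms
    slow_floor: float = 0.0      # residual availability

    def na_m(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vt = v - self.na_vshift
        a = 0.32 * _vtrap(13.0 - vt, 4.0)
        b = 0.28 * _vtrap(vt - 40.0, 5.0)
        tau = np.maximum(1.0 / (a + b), self.mtau_min)
        return a / (a + b), tau

    def na_h(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vt = v - self.na_vshift
        a = 0.128 * np.exp((17.0 - vt) / 18.0)
        b = 4.0 / (1.0 + np.exp((40.0 - vt) / 5.0))
        tau = np.maximum(1.0 / (a + b), self.htau_min)
        if self.na_h_half is not None:
            # hyperpolarized inactivation curve (closes the Na window that
            # would otherwise sustain a depolarized plateau in dendrites
            # lacking K_DR)
            inf = 1.0 / (1.0 + np.exp((v - self.na_h_half) / self.na_h_slope))
        else:
            inf = a / (a + b)
        return inf, tau

    def na_s(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        inf = self.slow_floor + (1.0 - self.slow_floor) / (
            1.0 + np.exp((v - self.slow_half) / self.slow_slope)
        )
        tau = np.full_like(np.asarray(v, dtype=float), self.slow_tau)
        return inf, tau

    def ka_a(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        inf = 1.0 / (1.0 + np.exp(-(v - self.ka_a_half) / self.ka_a_slope))
        tau = np.full_like(np.asarray(v, dtype=float), self.ka_tau_a)
        return inf, tau

    def ka_b(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        inf = 1.0 / (1.0 + np.exp((v - self.ka_b_half) / self.ka_b_slope))
        tau = np.full_like(np.asarray(v, dtype=float), self.ka_tau_b)
        return inf, tau

    def kdr_n(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vt = v - self.na_vshift
        a = 0.032 * _vtrap(15.0 - vt, 5.0)
        b = 0.5 * np.exp((10.0 - vt) / 40.0)
        # the closing-rate scale lengthens the hyperpolarized (deactivation)
        # time constant -- the AHP tail -- without shifting the steady state
        # or slowing activation at spike potentials
        tau = np.maximum(
            self.kdr_tau_scale / (a + self.kdr_b_scale * b), self.ntau_min
        )
        return a / (a + b), tau

    def gate(self, name: str, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return getattr(self, name)(v)

    @classmethod
    def mitral_default(cls) -> "ChannelKinetics":
        """Calibrated mitral kinetics (the dataclass defaults): slow,
        effectively non-inactivating K_A that sets the conductance
        threshold for slow tuft inputs; no slow Na gate in use."""
        return cls()

    @classmethod
    def granule_default(cls) -> "ChannelKinetics":
        """Calibrated granule kinetics: classic fast-activating,
        inactivating A-current (latency to first spike grows with K_A
        density) plus a slow Na-inactivation gate giving adaptation under
        strong sustained input."""
        return cls(
            na_h_half=-50.0, na_h_slope=4.0, kdr_b_scale=1.0,
            # depolarized activation keeps the resting K_A window (and hence
            # the balanced leak reversal) small
            ka_a_half=-20.0, ka_a_slope=8.0, ka_tau_a=2.0,
            ka_b_half=-70.0, ka_b_slope=6.6, ka_tau_b=10.0,
            slow_half=-45.0, slow_slope=4.0, slow_tau=30.0, slow_floor=0.2,
        )

    def steady_state(self, v: float) -> np.ndarray:
        """Gating variables at their voltage-dependent steady state."""
        va = np.asarray([v], dtype=float)
        return np.array([self.gate(g, va)[0][0] for g in GATE_NAMES])


def build_gate_tables(
    kinetics: ChannelKinetics,
    dt: float,
    alt_kinetics: ChannelKinetics | None = None,
    v_min: float = -120.0,
    v_max: float = 70.0,
    v_step: float = 0.05,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Precompute (inf, exp(-dt/tau)) lookup tables on a voltage grid.

    Returns ``(v_min, v_step, tab_inf, tab_fac)`` with 12 table rows: the
    six gates of ``kinetics`` in GATE_NAMES order, then the six gates of
    ``alt_kinetics`` (the granule cell-type variant; duplicated from
    ``kinetics`` when absent).  The kernel linearly interpolates both
    tables, making a gate update two fused multiply-adds instead of two
    transcendental evaluations.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    grid = np.arange(v_min, v_max + v_step / 2, v_step)
    n = grid.size
    n_g = len(GATE_NAMES)
    tab_inf = np.empty((2 * n_g, n))
    tab_fac = np.empty((2 * n_g, n))
    for k, src in enumerate((kinetics, alt_kinetics or kinetics)):
        for i, name in enumerate(GATE_NAMES):
            inf, tau = src.gate(name, grid)
            tab_inf[k * n_g + i] = inf
            tab_fac[k * n_g + i] = np.exp(-dt / tau)
    return float(v_min), float(v_step), tab_inf, tab_fac


def mg_block(v: np.ndarray, mg_mm: float = 1.0) -> np.ndarray:
    """Voltage-dependent magnesium unblock factor for the NMDA conductance
    (Jahr-Stevens form); tends to 1 at depolarized potentials."""
    return 1.0 / (1.0 + np.exp(-0.062 * np.asarray(v, dtype=float)) * mg_mm / 3.57)
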