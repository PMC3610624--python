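# bulbnet

A biophysical network model of the olfactory bulb's mitral-granule cell
circuit, for studying how lateral and feedback inhibition self-organize
through activity-dependent dendrodendritic synapses and shape the spatial
and temporal representation of odors.  It is aimed at computational
neuroscientists who want a desk-scale, fully scriptable re-implementation
of the large-scale circuit model: multicompartment cable-equation neurons,
a ring-projected glomerular map, level-coded odor inputs, sniff-locked
stimulation, and a presynaptic-ISI plasticity rule — all runnable on one
CPU.

## The model

- **Cells.** Mitral cells (312 compartments: axon stub, soma, apical
  dendrite + glomerular tuft, two 1.5 mm lateral dendrites) and granule
  cells (soma + 250 um radial dendrite, 21 compartments), with Na, K_A and
  K_DR conductances (uniform over the mitral dendritic tree; granule K_DR
  restricted to the soma).  Passive properties R_a = 150 Ohm*cm, tau_m =
  20 ms; R_m is calibrated so somatic input resistance is 100 MOhm.
- **Connectivity.** Glomeruli are projected onto a closed 5 mm track;
  1 glomerulus : 5 mitral : 100 granule cells (500/10,000 at full scale).
  Each granule cell forms reciprocal dendrodendritic synapse pairs with
  10±5% of the mitral lateral dendrites overlying it (≤1.5 mm reach).
- **Synapses.** Excitatory mitral→granule (AMPA α, τ 3 ms + NMDA, 10/50 ms,
  Mg block) and inhibitory granule→mitral (GABA, 1/200 ms, −80 mV) at the
  same site; release on −40 mV presynaptic crossings.  Each component
  carries a counter p∈[0,50] updated per presynaptic ISI
  (Δ = +1 below 30 ms, −1 between 30 and 250 ms, 0 above 250 ms) with weight

      w = g_syn · S(p),   S(p) = 1 / (1 + exp(−(p − 25)/3)),

  g_syn = 0.5 nS (exc) and 3 nS (inh); weights start fully depressed.
- **Stimulus.** Odor tables hold glomerular activation levels 0–4; level l
  maps to a per-tuft-synapse peak of (l/4)·0.5 nS (10 nS aggregate at
  level 4), delivered as a 20/200 ms double-exponential conductance at
  every sniff (random 2–10 Hz).  Independent somatic Poisson background
  makes every cell fire at ~2 Hz.
- **Engine.** Implicit (backward-Euler) integration of the whole cell
  forest at a fixed 25 us step (numba-compiled), bit-deterministic under
  fixed seeds, with periodic weight-matrix snapshots.

See `docs/methods.md` for calibration details, numerical choices and
limitations.

## Worked example

A 1/25-scale network (20 mitral, 400 granule cells on a 0.2 mm ring)
learning a strong focal odor for two seconds:

```python
import numpy as np
from bulbnet.presets import build_scaled_network, learning_run
from bulbnet.analysis import instantaneous_rate

bundle = build_scaled_network(scale=0.04, seed=0)
result, levels = learning_run(bundle, "focal_strong", duration_s=2.0)

driven = np.flatnonzero(levels > 0)
quiet = np.flatnonzero(levels == 0)
rate = instantaneous_rate(result, np.arange(bundle.placement.n_mitral),
                          duration_ms=2000.0)
print("reciprocal pairs:", bundle.network.n_pairs)
print("driven mitral cells:", driven.tolist())
print("mean rate driven  %.1f Hz" % rate.mean_rate(driven))
print("mean rate others  %.1f Hz" % rate.mean_rate(quiet))
print("potentiated inhibitory pairs:", int(np.sum(result.p_inh > 25)))
```

prints

```
reciprocal pairs: 601
driven mitral cells: [0, 1, 17, 18, 19]
mean rate driven  40.7 Hz
mean rate others  1.9 Hz
potentiated inhibitory pairs: 148
```

The five mitral cells of the driven glomerulus burst at each sniff
(~41 Hz smoothed) while the rest fire at the ~2 Hz background; within two
seconds their backpropagating spikes have already potentiated 148
granule→mitral synapses — the beginning of the inhibitory column that
subsequently sharpens and sparsifies the response.

The same protocols are available from the shell:

```bash
bulbnet learn --scale 0.1 --odor focal_strong --duration-s 10 --out runs/learn
bulbnet replay --scale 0.1 --odor distributed \
    --weights runs/learn/weights.npz --out runs/replay
bulbnet sweep-connectivity --scale 0.04 --out runs/sweep
bulbnet gen-table --n-odors 72 --out table.tsv
bulbnet plot --run runs/learn --scale 0.1 --out runs/learn/summary.png
```

Each run directory receives `spikes.tsv` (cell id, time), `weights.npz`
(snapshots and final counters) and `run.log` (all resolved parameters).

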