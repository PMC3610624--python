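# Methods

`bulbnet` simulates the self-organization of the mitral-granule cell
circuit of the olfactory bulb: biophysical multicompartment neurons coupled
by plastic reciprocal dendrodendritic synapses on a closed 1-D track,
driven by level-coded glomerular odor inputs delivered at sniff times.
This note records the model, its calibration, the numerical scheme, and the
design choices made where the underlying description left the design open.

## Cell models

**Mitral cell.** 312 compartments by default: a 3-compartment axonal stub,
the soma (25 x 25 um), a 460 um primary dendrite ending in a glomerular
tuft of 20 branches (one odor synapse each), and two lateral dendrites of
1500 um path length each (121 segments of ~12.4 um, i.e. inside the
10-30 um control discretization; `max_segment_um=5` rebuilds the cell at a
finer grid).  Passive properties are uniform: R_a = 150 Ohm*cm, tau_m =
20 ms, resting potential -65 mV, nominal temperature 35 degC.  The specific
membrane resistance is solved by bisection (1% tolerance) so that the
somatic input resistance of the passive cell is 100 MOhm, with C_m =
tau_m / R_m co-varying; the calibrated value is R_m = 21,085 Ohm*cm^2
(C_m = 0.95 uF/cm^2).

**Granule cell.** A soma (8 x 8 um) plus a 20-compartment radial dendrite
totalling 250 um.  Na and K_A are present in every compartment; K_DR only
at the soma.

**Channels.** Three voltage-gated conductances: transient Na (Traub-style
rate functions, threshold parameter `na_vshift` = -58 mV), delayed
rectifier K_DR (Traub n-gate, power 4), and an A-type K current (K_A,
product of an activation and an inactivation gate).  Rates are expressed at
the operating temperature; all parameters live in `ChannelKinetics` and are
plain configuration.  The binding surface is the calibration contract set,
not any particular parameter value:

- passive somatic input resistance ~100 MOhm;
- a single 10 nS aggregate tuft activation (double-exponential, 20/200 ms)
  elicits exactly 6 somatic spikes, with a monotone spike count over the
  0-10 nS sweep and a conductance threshold between the level-2 (5 nS) and
  level-3 (7.5 nS) encodings;
- sustained suprathreshold somatic current gives regular, non-bursting
  firing (ISI CV < 0.2) with the firing rate saturating near the
  physiological ~75 Hz ceiling;
- somatic action potentials backpropagate at full amplitude to the lateral
  dendrite tips and the tuft, and a dense column of active GABA synapses
  (a few 3 nS synapses per compartment over a ~300 um stretch) gates the
  backpropagation below the -40 mV release threshold distal to the column;
- granule first-spike latency grows monotonically with K_A density over a
  4x range, and under a strong current step the granule cell adapts: after
  the onset settling its ISIs are non-decreasing and the train slows or
  terminates.

Two cell-type kinetics variants are used (the integration kernel carries
both lookup-table sets).  The mitral K_A activates slowly (tau ~25 ms)
around -38 mV and does not inactivate: this makes it a perithreshold shunt
for slow synaptic envelopes -- it sets the odor-input conductance threshold
between levels 2 and 3 -- while leaving the ~1 ms backpropagating spike
untouched.  The mitral K_DR closing rate is scaled down (`kdr_b_scale`,
0.12), which lengthens the AHP tail without slowing repolarization onset;
this is what saturates the firing rate near 75 Hz under strong sustained
drive.  The granule K_A is the classic fast, inactivating A-current with
depolarized activation (half -20 mV; a hyperpolarized activation range
would leave a large standing K_A window at rest, which both distorts the
leak balancing and supports a depolarized dendritic plateau).  The granule
Na carries (i) a hyperpolarized inactivation curve (half -50 mV) -- needed
because the granule dendrite has no K_DR, so a depolarized Na window would
otherwise sustain a stable plateau -- and (ii) a slow inactivation gate
(tau 30 ms, floor 0.2) that produces spike-frequency adaptation under
strong input.

Channel current balancing: at initialization the leak reversal of every
compartment is set so that the resting potential is a true steady state
with all gates at their resting activation (the standard approach when
channels carry small standing currents at rest).

## Reciprocal synapses and plasticity

Each granule-mitral pair has one excitatory component (mitral lateral
dendrite -> granule dendrite) and one inhibitory component (granule ->
mitral) at the same dendritic site.  The excitatory component carries AMPA
(alpha function, tau 3 ms, reversal 0 mV) and NMDA (double exponential
with 10 ms time to peak and 50 ms decay, Jahr-Stevens Mg block at 1 mM,
reversal 0 mV) in equal proportion: both peaks equal the common plastic
weight.  The inhibitory component is a GABA double exponential (rise 1 ms,
decay 200 ms, reversal -80 mV).  Peak conductances at full potentiation
are 0.5 nS (excitatory) and 3 nS (inhibitory).

A component releases whenever its presynaptic compartment crosses -40 mV
from below (no somatic spike required).  Each component carries an integer
counter p in [0, 50], updated per presynaptic event from the presynaptic
ISI: +1 below 30 ms, -1 in the 30-250 ms band (boundaries assigned to the
depressing band so the rule is deterministic), 0 above 250 ms; the first
event of a train carries no ISI.  The weight is w = g_syn * S(p) with the
rising sigmoid S(p) = 1/(1 + exp(-(p - 25)/3)), so ~50 consecutive events
at the potentiating frequency traverse fully-depressed to fully-potentiated.
Counters start at 0 (S(0) ~ 2.4e-4, effectively zero weight).  The rule is
non-Hebbian: nothing postsynaptic enters the update.  AMPA and NMDA share
one counter (jointly plastic).

## Topology

The 2-D glomerular map is projected to the nearest point of a closed
polyline (default: a circle of 5 mm circumference), which removes edge
effects.  Ratios are 1 glomerulus : 5 mitral : 100 granule cells; cluster
cells sit at their glomerulus's ring coordinate with +-25 um uniform
jitter, and filler cells (to 500 mitral / 10,000 granule at full scale)
are placed uniformly.  Cells are index-ordered by ring coordinate, so the
array index is the "site" coordinate of activity maps.

Each granule cell draws a connection fraction f ~ U[5%, 15%] and connects
to that fraction of the eligible mitral cells -- those whose lateral
dendrite overlies it, i.e. ring distance <= the 1.5 mm reach on the side
the dendrite runs (the two laterals run in opposite ring directions).  The
attachment compartment is the lateral compartment whose fractional path
distance equals the fractional ring distance (identical at full scale,
where reach = dendrite length); the granule-side compartment is drawn
uniformly along the dendrite.  A separate structural estimator
(`expected_synapse_count`) reports the plain product n_granule x n_mitral
x mean fraction (~0.5 million at full scale); actual graphs are
reach-limited and smaller, which is what produces the sharp spatial cutoff
of granule recruitment at the dendritic reach.

**Scale-down rule.** A single factor s shrinks glomerulus count, cell
counts and ring length together, holding reach/ring-length at 0.3, so a
desk-scale network preserves the coverage geometry.  The physical cable of
the mitral cell stays full length at any scale; only the ring-to-path
mapping is rescaled.  The desk default is s = 0.1 (7 glomeruli, 50 mitral,
1000 granule cells, 0.5 mm ring); property tests use s = 0.04.

## Stimulus

Odor tables hold integer activation levels 0-4 per glomerulus.  Level l
maps linearly to the per-tuft-synapse peak conductance g(l) = strength *
(l/4) * 0.5 nS -- 10 nS aggregate at level 4, full strength.  Linearity is
the least-structured choice compatible with the constraint that levels 3-4
are suprathreshold; with the calibrated cell, 5 nS (level 2) is indeed
subthreshold and 7.5 nS (level 3) fires.  Every sniff activates all tuft
synapses of all odor-driven mitral cells synchronously with the 20/200 ms
double-exponential conductance; inter-sniff intervals are 1/f with f
uniform in 2-10 Hz.  Successive sniffs superpose, so sustained sniffing
holds the driven tuft near or above the single-activation peak.

Background activity is an independent Poisson train of 0.1 nS somatic AMPA
events per cell, with the event rate calibrated (bisection on the log
rate, isolated-cell simulation) so each cell type fires at ~2 Hz: 5,398
events/s for the mitral cell (mean-driven, seed-insensitive) and 43.9
events/s for the granule cell (fluctuation-driven).

**Synthetic odor tables.** The generator emulates the structure of the
intrinsic-imaging odor panel: per odor, a contiguous run of glomeruli in a
home cluster with levels graded toward a focus, plus rare outliers in
other clusters.  Three exemplar patterns (shipped, and reproducible on any
scaled map by ring fraction) mimic the canonical cases: a strong focal
odor (sites 430-490 of 500 at levels 3-4), a weak focal odor (around site
240 at levels 1-2), and a distributed odor (240-270 weak plus 460-490
strong).  The generator reproduces cluster structure and graded levels; it
does not model odorant chemistry, concentration-dependent glomerular
recruitment, or correlated trial-to-trial variability, so passing tests
show circuit-level self-organization under the stated input statistics,
not predictions for any specific odorant.

## Numerics

All compartments of all cells form one tree-structured forest integrated
implicitly (backward Euler) at a fixed step, default 25 us, by Hines
elimination; gating variables advance by the Rush-Larsen exponential
scheme between voltage solves, with (inf, exp(-dt/tau)) read from
per-timestep voltage lookup tables (0.05 mV grid, linear interpolation).
Synaptic conductances are linear one- or two-state kinetics advanced by
exact exponential decay factors; NMDA is scaled each step by the Mg-block
factor at its target compartment.  Presynaptic threshold crossings are
detected after the voltage solve and their conductance increments take
effect on the next step (one-step latency).  Runs abort with a diagnostic
if any potential leaves +-200 mV.  Simulations are bit-deterministic given
the configuration and the three seeds (connectivity, sniff schedule,
background); background events are generated online from per-cell
counter-based RNG streams.

## Analysis definitions

- *Instantaneous rate*: spike trains binned at 5 ms and smoothed with a
  Gaussian kernel; `smoothing_window` is the kernel standard deviation,
  default 100 ms (the timescale of a sniff cycle).
- *S/N*: 10*log10(mean rate of signal cells / mean rate of reference
  cells); positive when the signal cells fire faster.
- *Inhibition extent*: half-width of the contiguous ring region around an
  active site where granule activity (or potentiated inhibitory weight)
  exceeds 10% of its peak, minus the driven site's own half-width.  On
  sparse desk-scale graphs the per-granule profile is first averaged into
  ring bins (reach/5 by default in tests) to remove synapse-count shot
  noise.
- *Weight columns*: spatial clustering of the per-granule potentiated
  inhibitory weight is scored as the correlation between each granule
  cell's summed weight and the mean over its ring neighbors (a Moran-style
  statistic, robust to the strongly uneven granule density around
  glomeruli), compared against a position-shuffle null.
- Distribution comparisons use the two-sample Mann-Whitney rank-sum test
  from scipy; following the original analysis protocol, granule-free
  epochs are taken from the first second(s) and granule epochs from the
  last second(s) of a presentation, so both conditions are sampled in
  comparable burst-mode epochs.  Because long (50-200 ms) interspike
  intervals are rare events in small driven populations, the change in the
  long-ISI band is rank-tested on per-cell per-second counts of such
  intervals rather than on the interval values themselves; the short-band
  invariance is tested on the interval values directly.

## Problem sizes

Single-cell protocols run the full 312-compartment cell.  The desk-scale
learning run (acceptance) uses s = 0.1 for 10 s of simulated time (~0.5 M
integration steps over ~37,000 compartments).  Property tests use s = 0.04
networks (20 mitral, 400 granule cells) and 5 s presentations, which is
past the point where driven-synapse counters saturate; these sizes keep a
full test run within ordinary desk compute.

## Known limitations

- No Ca2+ channels, Ca2+-dependent K, Ih, persistent Na, stochastic
  channels, or intercellular variability, by design.
- The two kinetics variants are this package's own calibrated
  formulations; they satisfy the stated contracts but are not fits to
  voltage-clamp data.
- At desk scale each granule cell carries only a few reciprocal pairs, so
  per-cell weight profiles are shot-noise dominated (hence the binned
  spatial statistics) and suppression magnitudes are weaker than at full
  scale.
- The 1-D projection discards the true 2-D adjacency of glomeruli; as in
  the original treatment, interactions are faithful only in the
  along-track sense.
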