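# Methods

## Overview

`bgthsim` couples two descriptions of the basal-ganglia–thalamus (BGTH)
circuit and advances them in lockstep:

1. a **microscale** subnetwork per region — 50 modified Hodgkin–Huxley
   (HH) neurons with stochastic feed-forward drive and recurrent
   excitatory/inhibitory conductance kicks — which supplies each region
   with population-averaged presynaptic currents, and
2. a **macroscale** membrane equation per region (STN, GPi, GPe, TH) in
   the Rubin–Terman lineage, coupled through six inter-nucleus synapses,
   through diffusion over a connectome graph Laplacian, and through the
   microcircuit averages.

A disease switch (pd ∈ {0, 1}) lowers the bias currents of STN, GPi and
GPe; an open-loop DBS pulse train can be added to STN and/or GPi; and a
stochastic mode adds independent Wiener increments to the four regional
voltages, integrated by Euler–Maruyama.

All integration uses explicit Euler with dt = 0.01 ms.  Within a step
the micro subnetworks update first (Poisson draw, membrane advance,
rising-edge spike detection, same-step conductance kicks), then the
macro equations consume the fresh averages (synchronous, zero-lag
exchange).  Micro and macro share the same dt; no sub-stepping.

## Connectome and diffusion

The connectome is an undirected weighted graph with one node per region:
W_ij = n_ij / l_ij² (mean fiber count over mean fiber length squared,
count/mm²), D = diag(row sums), L = ρ(D − W).  The diagonal of W is
zero: self-loops carry no diffusion.  Each regional equation includes
−dv_p (L v)_p; nodes beyond the first four (if a larger graph is
supplied) are passive and feel only diffusion.

ρ and dv_p are not constrained by the model family; defaults are ρ = 1
and dv_p = 0.1 for all p, documented as package defaults.  The units of
W are absorbed by ρ·dv_p so that dv_p (L v)_p is mV/ms.

The synthetic generator draws each node pair with probability
`density`, splices in a random spanning tree if the draw is
disconnected, and samples log-normal fiber counts (median 500, σ = 0.6
log-units) and uniform 30–120 mm lengths — magnitudes typical of
inter-nucleus bundles in whole-brain tractography.  The shipped
configuration is the complete 4-node graph with seed 7.  Edge lists are
0-based CSV; a GraphML export is provided.  Real tractography edge lists
with the same columns can be read directly, but no tractography
processing is performed.

## Microcircuit

Membrane constants are the modern-convention HH values (C = 1 µF/cm²,
E_Na = 50, E_K = −77, E_L = −54.387 mV, g̅_Na = 120, g̅_K = 36,
g̅_L = 0.3 mS/cm²) with the standard rate functions α_m, β_m, α_h, β_h,
α_n, β_n; the removable singularities of α_m (−40 mV) and α_n (−55 mV)
are evaluated analytically, so the rates are continuous in V.

Synaptic conductances follow τ dg/dt = −g + Σ S δ(t − s): a kick of
size S jumps g by S/τ.  Within an Euler step the conductances first
decay by (1 − dt/τ) and then receive kicks; simultaneous kicks sum.
Defaults (package choices, config-exposed): E_E = 0, E_I = −80 mV,
τ_E = 2, τ_I = 3 ms, λ_dr = 0.5 kicks/ms, S_dr = 0.4,
S_EE = S_IE = 0.3, S_EI = S_II = 0.5.  The stationary mean of g_E under
drive alone is λ_dr·S_dr = 0.2 mS/cm² (jump S_dr/τ_E at rate λ_dr with
decay τ_E); the acceptance suite verifies a 10-s simulated time average
against this closed form on a 10-neuron drive-only population — the
population average estimates the same stationary mean as a single
neuron with ~3× smaller sampling error.

Wiring is directed Erdős–Rényi (p = 0.2) with no self-connections;
round(N·0.75) neurons are excitatory (the conventional ~3:1 cortical
E:I ratio).  Spikes are rising-edge crossings of V_th = −20 mV with
hysteresis (a neuron must fall below threshold before re-triggering) and
act on postsynaptic conductances in the same step (zero synaptic
delay).  Initial V is uniform on [−70, −60] mV with gating variables at
their steady state and zero conductances.

The four regional subnetworks are mutually unconnected ("simulated
independently"); the engine stacks them into one block-diagonal
population purely as a vectorization.

## Regional dynamics

Ionic currents take the Rubin–Terman functional forms: sigmoidal steady
states x∞(v) = 1/(1 + exp(−(v − θ_x)/σ_x)), first-order gates
dx/dt = e_x (x∞ − x)/τ_x(v) with sigmoidal, exponential or constant
τ(v) (the thalamic h gate uses the 1/(α + β) form), and currents
g·(gating)·(v − E).  STN and the pallidal nuclei carry I_Na, I_K, I_L,
I_T, I_Ca and a calcium-gated AHP current g_ahp (v − E_K) w/(w + k1);
TH carries I_Na, I_K, I_L and I_T only, with I_K gated by
(0.75(1 − h))⁴.  The calcium pool follows
dw/dt = e_w (−I_Ca − I_T − l_w w) — influx through the calcium currents
balanced by linear clearance.  This grouping (e_w multiplying the whole
bracket) is one of two possible readings of the model family's
typesetting; it is isolated in a single function
(`regions.gate_derivatives`).

Synaptic activations follow ds/dt = α H∞(v_pre)(1 − s) − β s with a
presynaptic sigmoid H∞ (θ_g = −20 mV, σ_g = 5 mV), zero transmission
delay.  The topology is fixed: GPe→STN, STN→GPi, STN→GPe, GPe→GPi,
GPe→GPe, GPi→TH; STN-source connections are excitatory (E_syn = 0),
pallidal-source inhibitory (E_syn = −85 mV).  The TH equation receives
exactly one inter-nucleus current (GPi→TH) plus the SMC input.

The SMC input is a rectangular pulse train (amplitude 3.5 µA/cm²,
width 5 ms, period 25 ms).  The micro averages Ī_E, Ī_I enter inside
the 1/c_m bracket (units consistency; c_m = 1 µF/cm² for all regions,
matching the micro model's C = 1).

## Calibrated defaults

The model family leaves bias currents, their Parkinsonian reductions,
and several rate scalers open.  These were calibrated once so the
shipped defaults reproduce the qualitative regime structure the model
is meant to exhibit, and are documented as calibrated, not derived:

* **I_app** (µA/cm²): STN 25 (pd −8), GPi 50 (pd −4), GPe 12 (pd −6),
  TH 0.  With the micro averages contributing ≈ +10 µA/cm² net
  depolarization per region, these make GPe fire more in the healthy
  than in the Parkinsonian state, and keep every trace inside
  [−120, +60] mV.
* **GPi kinetics**: e_h = 0.01 (slow Na-inactivation recovery),
  e_n = 0.3 (fast K activation), g_ahp = 30, e_w = 3·10⁻⁴.  The GPi is
  thus a fast tonic firer whose counted spike rate *drops* under the
  167 Hz DBS pulse train: repeated forced depolarizations keep the
  sodium inactivation gate low and build the calcium-gated AHP, so the
  cell is driven toward partial depolarization block and entrains to
  the pulses instead of firing faster.  This is the mechanism by which
  the package realizes DBS-reduced GPi activity; its spike rates (a
  property of the abstract regional trace, not of single GPi units)
  are correspondingly high.
* **TH g_Na = 2.5 mS/cm²**, centring the mean thalamic spike-peak
  voltage near −10 mV under the default drive.

## Stochastic mode and RNG policy

Noise enters only the four regional voltages as σ_i ΔW_i per step,
ΔW_i ~ N(0, dt), σ = (0.1, 0.4, 0.4, 0.5) for (STN, GPi, GPe, TH) —
never the micro-neurons, gates or synapses.  Three independent streams
(micro Poisson drive, micro initial conditions, Wiener increments) are
seeded separately, so toggling noise, or setting all σ = 0, leaves the
micro trajectory bit-identical; σ = 0 stochastic mode reproduces
deterministic mode exactly.  A single master seed can derive all three
streams (`Seeds.from_master`).

## Spike definition on regional traces

Regional voltage traces have no intrinsic spike definition; the package
imposes: a spike is a strict local maximum above −30 mV accepted left to
right with a 2 ms minimum separation.  Both numbers are config-exposed.
Peak statistics use the local-maximum value; ISI statistics require at
least two spikes.  Recording defaults to every 10th step (0.1 ms); the
2 ms refractory makes detection insensitive to this stride.

## Numerical choices

* Explicit Euler / Euler–Maruyama only; first-order convergence is
  verified on a smooth subthreshold configuration (error ratio ≈ 2.25
  when halving dt against a 10×-finer reference, the expected value
  when the reference itself carries a dt_ref = dt/10 error).
* Gates stay in [0, 1] without clamping at dt = 0.01 ms for all shipped
  configurations (asserted in tests over full trajectories).
* The Heaviside convention H(x) = 1 for x > 0 makes the DBS on-window a
  half-open interval of measure exactly δ_D; the reading
  sin(2π(t + δ_D)/ρ_D) is the only one that yields an on-window of
  width δ_D, and ρ_D is in ms, consistent with δ_D and t.
* Degenerate inputs: a zero-width DBS pulse is the always-off waveform;
  an empty connectome edge list yields zero adjacency with a warning; a
  zero-length phase-trajectory window is empty.

## What the tests do and do not show

The synthetic connectome reproduces the *scale* of tractography weights,
not any subject's anatomy; with only four nodes the diffusion term is a
weak homogenizing coupling.  The regional "spike counts" are properties
of abstract one-compartment regional voltages driven by strong
population-averaged currents — they are not single-unit firing rates,
and exceed physiological GPi rates.  Passing regime-ordering tests
therefore shows that the shipped configuration reproduces the intended
qualitative structure (healthy GPe > Parkinsonian GPe; GPi under DBS <
Parkinsonian GPi; thalamic peaks near −10 mV), not that the parameters
are physiologically identified.  Problem sizes in the test and
acceptance suites (2000 ms regime runs, 10 s conductance averages,
10⁴-replicate noise windows) were chosen as the smallest that make the
checked statistics stable.

## Known limitations

* No cross-region microcircuit wiring: each region's subnetwork is
  independent, so internal cross-region spike correlations are absent.
* One node per region in the shipped configuration; multi-node regions
  are supported by the data model but unparameterized.
* Open-loop DBS only; monophasic rectangular pulses; no electrode-field
  or charge-balancing model.
* No striatum, dopamine dynamics, or thalamocortical relay-fidelity
  metric.
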