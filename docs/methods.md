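# Methods

This note documents the models implemented in `modsnn`, the choices made
where the design was genuinely open, and what the desk-scale test
conditions do and do not establish.

## Network generation

Neurons are placed as a spatial Poisson process (uniform over a disk of
diameter 3 mm at 400 neurons/mm², ≈2,800 cells; desk scale uses a 1.5 mm
disk, ≈700 cells). Each neuron is excitatory with probability 0.8. Dendrites
are disks of radius 150 μm around the soma. Axons grow as chains of 0.1 mm
segments: total length ℓ ~ Rayleigh with mean ⟨ℓ⟩ = 1.1 mm (scale
σ = ⟨ℓ⟩·√(2/π)); each segment's heading deviates from the previous one by a
Gaussian angle with σθ = 0.1 rad; the final segment is truncated so the path
length equals ℓ exactly. Growth terminates at the dish wall (the culture
boundary is physical; the generator clips the last segment to the disk).

Track-patterned substrates are modeled as infinite horizontal bands —
0.2 mm crevices alternating with 0.3 mm valleys, phase anchored so a
crevice boundary lies at y = 0. When a proposed segment would cross a band
boundary, the axon crosses downwards (−y) with probability P_down = 0.5 and
upwards with P_up = 0.05; otherwise the heading is set parallel to the
boundary, preserving the sign of its tangential component (perpendicular
incidence broken by the generator's RNG). Axons may re-attempt crossing at
every subsequent boundary contact. Unpatterned ("non-modular") cultures
skip the boundary interaction entirely.

A directed candidate edge i→j exists when any axon segment of i passes
within the dendrite radius of soma j (analytic segment-to-disk distance,
not rasterization); each candidate *pair* is retained independently with
probability 0.2 (one Bernoulli draw per pair, however often the axon
re-enters the disk). Excitatory conduction delays are uniform in [0, 5] ms;
inhibitory delays are fixed at 1 ms.

## Spiking dynamics

Izhikevich neurons: dv/dt = 0.04v² + 5v + 140 − u + I_E + I_I + I_in,
du/dt = a(bv − u), reset v←c, u←u+d at v ≥ 30 mV. Excitatory cells are
regular-spiking ([a,b,c,d] = [0.02, 0.2, −65, 8]); inhibitory cells
fast-spiking ([0.1, 0.2, −65, 2]). Integration is fixed-step with dt = 1 ms,
two 0.5 ms substeps for v and one full step for u — the scheme of the
standard polychronization-network implementation.

Synaptic currents decay exponentially (τ_E = 5 ms, τ_I = 20 ms) and jump by
the synaptic weight when a presynaptic spike is delivered. Deliveries are
scheduled on the integration grid: delay d_ij is floored to whole steps
with a minimum of one step, so a spike can never act within the step in
which it occurs and every delivery passes through a single, canonical
delivery phase (this makes the online plasticity event order well defined
and exactly reproducible by offline replay). Background drive is a Poisson
process per neuron (rate 1 Hz, one Bernoulli draw per neuron per step),
each event adding an amplitude ξ to the cell's excitatory current.

**ξ calibration.** The noise amplitude is a free parameter of the model; it
was calibrated once on the desk-scale fixture so that a settled, undamaged
network sustains discrete, culture-like network bursts at the 1 Hz event
rate. The transition is sharp: ξ = 6.05 leaves the network nearly silent,
ξ ≳ 6.2 produces continuous reverberation; the default ξ = 6.1 yields
~0.5 bursts/s with ~80% unit participation and single-unit background
firing well below 1 Hz. ξ is a configuration knob (`NoiseConfig.xi`).

Lesioned (dead) neurons are excluded from all membrane updates and never
spike; their noise draws are still consumed so that a damaged network and
its undamaged control experience the identical drive stream.

**Determinism.** The jitted core's RNG is reseeded deterministically per
simulation chunk (a mix of the simulator seed and a chunk counter), so a
fixed seed and chunk schedule give bit-identical results, and interleaved
simulators (damaged + control) cannot perturb each other's streams.
Different chunkings of the same interval are different, equally valid noise
realizations.

## Plasticity

Nearest-neighbour STDP acts on E→E synapses only, with the
delivery-corrected timing Δt = t_post − t_pre − d_ij and soft bounds:

    Δt > 0:  Δw = η₊ (1 − w/w_max) exp(−Δt/τ)
    Δt ≤ 0:  Δw = η₋ (w/w_max) exp(Δt/τ)

with η₊ = 0.1, η₋ = −0.12, τ = 20 ms, w_max = 6.8. Each postsynaptic spike
pairs with the most recent presynaptic delivery; each delivery pairs with
the most recent postsynaptic spike; updates are applied online at the event
(not batched) and clamped to [0, w_max]. The stationary mean weight is
w̄ = w_max·η₊/(η₊−η₋) ≈ 3.09; fixed weights are w_EI = w̄, w_IE = w_II = −w̄.
E→E weights are initialized uniformly at w̄ (a uniform-random [0, w_max]
alternative is available behind `random_initial_weights`).

Settling runs plasticity-on dynamics until the weight distribution is
stationary — 72 simulated hours at full scale, 120 s at desk scale (the
desk network starts at w̄ and reaches its stationary distribution within
tens of seconds; the settled mean sits within a few percent of w̄ and
drifts < 5% over a further simulated minute).

## Lesions and the recovery protocol

A lesion is a straight segment (perpendicular to the tracks = intra-modular,
parallel = inter-modular; half-length 1.5 mm or full-diameter, centered on
the culture). Every neuron whose axon path intersects the segment is dead
(axonal transection): marked not-alive, excluded from dynamics forever, its
row and column zeroed but kept so indices are stable. Severance is decided
on the axon geometry, not soma-to-soma chords. A random-edge-deletion
control lesion (same connection count, no cell death) is available.

The protocol records a pre-damage epoch, applies the cut, and continues the
plasticity-on simulation, recording an evaluation epoch at each
post-injury timepoint (full scale: 0 min, 15 min, 2 h, 6 h, 24 h; desk
scale: 0, 60, 180, 360 s with 60 s epochs). A copy of the settled network
evolves undamaged under the matched noise stream as the control for
ratio-to-control statistics; its pre-damage history is identical to the
damaged run's by construction.

## Activity and connectivity metrics

**Bursts.** A network burst is a 200 ms window in which the number of
distinct firing units exceeds 20% of the alive units. The window slides at
1 ms; a maximal run of qualifying positions is one event (onset = first
qualifying position) so a single burst is never double-counted. The
participation denominator is the alive-unit count; an optional ROI-grid
mode pools spikes onto 150 μm squares for comparison with imaging
pipelines.

**Transfer entropy.** Spike trains are binarized into 20 ms bins; TE with
Markov order k = 2 is estimated by plug-in joint histograms (base-2 logs,
zero-count states skipped; all-zero/all-one streams give TE = 0). The
embedding conditions on past bins only. TE values are z-scored over all
ordered pairs and thresholded at z ≥ 2 for the binary effective network Z.

**Global efficiency.** Weights are converted to lengths — L = w_max/w for
synaptic matrices, L = TE_max/TE for effective ones, where TE_max is the
maximum unnormalized TE across the damage sequence — followed by Dijkstra
and the mean of inverse shortest-path distances over ordered alive pairs
(unreachable pairs contribute 0). Synaptic-mode efficiency operates on the
E→E plastic submatrix: the length transform is undefined for negative
inhibitory weights, and STDP only moves E→E weights.

**Communities.** Louvain on the symmetrized matrix (M + Mᵀ)/2 (Louvain is
defined for undirected graphs), best modularity of 10 seeded restarts.
Partition similarity uses NMI = 2·I(C,C′)/(H(C)+H(C′)), the standard
arithmetic normalization, which is 1 iff the partitions are identical up to
relabeling.

## Reservoir harness

Synthetic 78-channel cochleagrams stand in for a spoken-digit corpus
processed by an auditory filterbank (external and out of scope). Each class
is a template of formant-like band trajectories riding on a broadband
loudness envelope with class-specific bump timing; trials jitter timing
(±10%), channel offset, amplitudes and add noise; the global maximum is
normalized to 1. The broadband envelope carries the normalization peak so
that summed channel pairs reach the input units' firing threshold during
loudness bumps — with narrow-band-only stimuli the per-unit current
w̄·(ch_a+ch_b) stays below the Izhikevich rheobase and the network would not
respond. Classes are linearly separable from the raw cochleagrams (≥90% by
a logistic probe), so reservoir accuracy reflects the network, not an
impossible task.

5% of neurons receive input (each the sum of two random channels times the
snapshot's mean E→E weight ŵ, added to I_in); a disjoint 5% forms the
readout state x(t) by leaky spike integration (τ_x = 1 s, 0.1 per spike),
sampled at 1 ms. Plasticity is frozen during sessions; trials run back to
back with state carried across trials and reset between sessions. The
readout is ridge regression W_out = ŶXᵀ(XXᵀ+λI)⁻¹ with λ = 1; targets are
one-hot for 2.5 s after each onset (0.8 s in the scaled configuration);
classification integrates each output over the target window and takes the
argmax (ties to the lowest label). Following the protocol being modeled,
the default evaluation reuses the training set; a held-out mode is
available by supplying a different `TrialSet`.

## Problem sizes and what the tests show

The default suite runs everything at desk scale: a 1.5 mm / ~700-neuron
culture, 120 s settling, a 0–360 s recovery schedule with 60 s epochs,
5 replicate seeds, and a 2.5 s-per-trial reservoir session. These sizes are
the package's scaled working set; the unscaled protocol (3 mm, n = 15,
72 h + 24 h schedules, 10 s trials) is available through the defaults of
`ExperimentConfig` and `scripts/full_scale_repro.py`.

Desk-scale results establish directions and mechanisms — activity drops
after damage in proportion to cut size and orientation, recovery requires
STDP, intra-modular cuts hurt more than inter-modular ones, classification
survives damage when the readout is retrained — not the full-scale
magnitudes, which depend on network size and the longer recovery horizon.
The synthetic stimuli emulate the spectro-temporal structure of spoken
digits but not speaker variability or corpus noise; reservoir accuracies on
them say nothing quantitative about real speech.

## Known limitations

- 2-D geometry only; no axon branching, no glia, no structural rewiring
  (A is fixed after a cut; only W evolves).
- No conductance-based synapses, short-term plasticity, homeostatic
  scaling, or inhibitory plasticity.
- The Poisson drive amplitude ξ is a calibration parameter; the bursting
  regime is narrow in ξ, so other network sizes may need recalibration.
- The Schmitt-trigger calcium-to-spike inference of imaging pipelines is
  not implemented; simulated units are neurons (or ROI-grid pools).
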