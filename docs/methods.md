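# Methods

## The model

`olfdrift` simulates the first two stages of the rodent olfactory system as a
spiking network and asks how the continual rewiring caused by adult
neurogenesis reshapes odor representations downstream.

**Circuit.** Fifty glomeruli each drive 25 mitral/tufted cells (MT, 1250
total). A population of 12,500 granule cells (GC) — axonless inhibitory
interneurons — forms reciprocal and lateral dendro-dendritic contacts with MT
cells. MT cells project at random to 10,000 piriform principal cells (PC) and
1250 feedforward interneurons (FFI); PCs recur onto each other, drive 1250
feedback interneurons (FBI), and send weak, dense centrifugal feedback to the
GCs. Thirteen projection blocks define the wiring; each is parameterised by a
connection density and the mean of the uniform distribution from which
nonzero weights are drawn (`network.TABLE_RULES`). MT→MT coupling exists only
within a glomerulus. Centrifugal feedback is structured: a PC whose dominant
feedforward drive comes from glomerulus *A* contacts only GCs that are *not*
reciprocally paired with MT cells of *A*, so cortical activity inhibits bulb
channels other than its own source.

**Neurons.** Every cell is an Izhikevich quadratic integrate-and-fire unit
(dv/dt = 0.04v² + 5v + 140 − u + I, du/dt = a(bv − u), spike at v ≥ 30 mV
with v←c, u←u+d). Heterogeneity comes from per-cell uniform draws rᵢ mapped
through cell-type-specific curves: MT cells span regular-spiking to
bursting/chattering (r⁴ bias), PCs regular-spiking to chattering (linear),
and the inhibitory types fast-spiking to low-threshold-spiking (r²). Forward
Euler, dt = 1 ms, with the voltage advanced in two 0.5-ms half-steps and the
recovery variable once per step using the pre-step voltage — the standard
integration scheme for this neuron model. Cells start at rest (v = c,
u = bv) on every trial; trials are independent sniffs.

**Synapses.** A presynaptic spike makes the matching input accumulator of
each target jump by the synaptic weight; accumulators decay exponentially
with τ = 10 ms. Input currents are bookkept per source class (MT excitation,
GC inhibition, glomerular drive and centrifugal feedback for bulb cells;
bulb input, recurrent excitation and local inhibition for cortical cells) so
each pathway can be gated and inspected. MT→GC excitation is delivered after
a per-synapse latency drawn uniformly from [0, 25] ms (the latency
distribution is not constrained by data; the range gives GC spike-latency
spread of the observed order). All other projections deliver on the next
1-ms step. Per-step Gaussian current noise: σ = 1.75 (MT), 0.8 (GC), 0.9
(PC), 0 (FFI/FBI), drawn per cell per 1-ms step and added directly to I.

**Stimuli.** A model odor activates 6–20 % of the glomeruli (3–10 of 50),
each with its own onset latency (uniform on [0, 160] ms) and a 90-ms step of
drive inside the 250-ms sniff window. The default panel holds 100 odors; a
configurable fraction (default 0.2) are latency-jittered variants of earlier
panel members so pairwise odor similarity spans low to high. MT cells of one
activated glomerulus share half of their input noise variance (receptor
input to a glomerulus is strongly correlated); different glomeruli are
uncorrelated. The glomerular template for an odor never changes across
trials or days — only noise differs. The step amplitude (default 6.0) was
calibrated once on the default network so that activated MT cells fire in
the tens of Hz, granule-cell inhibition carries a large share of the drive
(removing GC→MT weights roughly doubles activated-MT rates), and the GC
response to an odor is sparse and stimulus-locked rather than noise-driven.

**Adult neurogenesis.** Each simulated day after the Day-0 baseline, 10 % of
the GCs have every synapse from and onto them — MT→GC (with fresh delays),
GC→MT, GC↔GC, and PC→GC — redrawn from the build distributions. Cohorts are
drawn without replacement, so after ten reshuffle days the whole population
has turned over, matching the regime the protocol targets. The global weight
distribution is invariant by construction; only identities and values move.
A registry records each GC's reshuffle day; reshuffled cells are adult-born
GCs (abGCs) from that day on.

**STDP.** The suppression model: each pre- and postsynaptic spike carries an
efficacy εᵢ = 1 − exp(−(tᵢ − tᵢ₋₁)/τ_s) (τ_s = 34 ms presynaptically, 75 ms
postsynaptically; an isolated or first spike has ε = 1), and every pre/post
pair within a trial contributes ε_pre ε_post F(Δt) with
F(Δt) = A₊e^(−|Δt|/τ₊) for Δt > 0 and A₋e^(−|Δt|/τ₋) for Δt < 0, F(0) = 0.
A₊ ~ N(1.03, 0.1), A₋ ~ N(−0.51, 0.01), τ₊ ~ N(13.3, 1.7) ms,
τ₋ ~ N(34.5, 1.6) ms, drawn once per synapse (clipped to their admissible
sign) and redrawn with the synapse when its GC is reshuffled. Plasticity is
restricted to abGC-related synapses: onto abGCs from MT, GC/SAC and PC
sources, and from abGCs onto MT and GC/SAC targets. Weights are frozen
within a trial and updated once at trial end, on the weight magnitude with
*soft bounds*: the potentiation sum is scaled by the remaining headroom
(1 − |w|/cap) and the depression sum by |w|/cap, with cap = 4× the block's
mean magnitude, so every synapse has a stable activity-determined
equilibrium and no synapse ever changes sign. All pre/post pairs in the
window are summed (the efficacy suppression is what tames bursts), not
nearest neighbours only. The learning rate is 5 × 10⁻⁴ × block mean
strength per unit pair-sum, calibrated so that weights change gradually
trial by trial and approach their asymptote over the course of the 11-day
protocol; substantially larger rates equilibrate within a single day and
destabilise the network's excitatory/inhibitory balance (spike counts grow
several-fold), while an additive rule with hard clipping has no equilibrium
at all.

## Analysis pipeline

Spike trains are binned into 5-ms sliding windows at 1-ms stride over the
251-sample trial grid (247 bins). One PCA eigenspace per population is
fitted on the trial-averaged responses concatenated over *all* odors and
days (per-cell grand-mean centering), so projections from different days are
directly comparable; the same eigenspace serves every day by construction.
Population vectors time-average the (cells × bins) response, giving length
n_cells (full ensemble) or k (reduced space). The reduced dimensionality is
50 components at full scale and scales with the population when the network
is shrunk (k = 50/1250 of the cell count, floor 3): a "reduced" space must
stay well below the cell count to mean anything, and the leading 4 % of
components is what the full-scale convention keeps. Metrics:

- **Within-odor correlation**: Pearson correlation of population vectors for
  the same odor on two days, averaged over odors; same-day entries compare
  even- vs odd-trial averages. Computed for full-ensemble and reduced-space
  vectors, single-trial and trial-averaged.
- **Across-odor correlation**: the same over 10 fixed odor pairs drawn once
  per experiment seed.
- **Cosine similarity**: u·v/(‖u‖‖v‖) between trial-averaged vectors; the
  same-day value subtracts the within-day variability estimate (the cosine
  deficit between even- and odd-trial averages).
- **Drift rate** (degrees/day): the least-squares slope of the mean day-pair
  angle versus day separation. The trial-averaged vectors are noisy
  estimates, so the angle between any two days has a separation-independent
  noise floor; a free intercept absorbs it and the slope isolates the
  systematic daily rotation. The literal mean consecutive-day angle is
  available as `method="consecutive"`; for a noise-free rotation both
  definitions agree exactly.
- **Decoding**: two-odor KNN classification (Euclidean distance, majority
  vote) of single-trial reduced vectors, over train ratios {0.5, 0.7, 0.9}
  and K ∈ {3, 5, 7}, 30 random stratified splits each.

## Scaled-down preset

The experiments run by default on a 1/12.5-scale network (10 glomeruli × 10
MT cells, 1000 GCs, 800 PCs, 100 FFIs, 100 FBIs) with 20 odors × 5 trials
per day for the drift protocol and 10 odors × 50 trials per day for the
STDP protocol (the analysis uses the final 10 trials of each odor's daily
block; the plastic arm experiences all 50, and the frozen comparison arm
only simulates the recorded ones, whose outcome it cannot influence) —
sizes chosen so a full 11-day experiment completes in minutes on one CPU
while keeping every mechanism active. Two quantities
cannot survive naive shrinking, and the preset handles them explicitly:

1. **Synaptic drive.** Keeping densities and strengths while shrinking all
   pools cuts every cell's expected in-degree ~12.5×, and the network falls
   silent beyond the MT layer. The preset therefore holds the *total
   expected connection weight per postsynaptic cell* (density × pool × mean
   strength) at its full-scale value, raising the density first (up to 1,
   which preserves the in-degree and hence both mean and variance of the
   summed input) and scaling the strength only for the remainder.
2. **Granularity of the reshuffled pathway.** The granule-cell *output*
   blocks — GC→MT and the lateral GC↔GC coupling — are the exception: they
   keep their full-scale densities (0.02 and 0.05) and scale strength
   instead. What the drift mechanism feels is the number of co-active
   inhibitory partners per target cell: at full scale ~250 partners of
   which a few percent respond to any one odor; at mini scale 20 partners
   of which roughly half respond. Raising the density instead gives every
   cell hundreds of weakly-tuned partners whose reshuffling averages away —
   a dynamical regime the full-scale model is not in. Blocks *onto* GCs
   stay degree-first, so which GCs respond to an odor is still decided by
   full-scale input statistics.

With this preset, redrawing the whole GC population changes individual
activated-MT responses substantially (rate-vector correlation drops from a
same-day ~0.95 to ~0.5) while the glomerulus-level population pattern — and
with it the leading principal components — stays put, reproducing the
bulb-stable / cortex-flexible ordering at reduced magnitude.

## What the synthetic data does and does not emulate

The generator reproduces the stated stimulus statistics (activation
fraction, latencies, step duration, within-glomerulus input correlation,
panel similarity structure) and nothing else: no concentration series, no
sniff-to-sniff variability, no receptor turnover, no behavioural-state or
top-down modulation. Passing tests therefore show that the *mechanism*
(reshuffling-driven drift, STDP stabilization) behaves as described under
idealised, stationary inputs — not that the model quantitatively matches any
particular biological recording.

## Numerical choices and degenerate inputs

- Integration is exactly reproducible: every run is a pure function of its
  configuration and master seed, with named substreams (build, odors,
  neurogenesis, noise, stdp, analysis) and per-trial noise generators keyed
  by (day, odor, trial) so paired experimental arms share noise.
- The compiled (numba) stepping core and the pure-numpy path implement the
  same update order and produce identical spike rasters; a scalar
  (non-vectorised) reference implementation is held to spike-for-spike
  agreement in the tests.
- Non-finite membrane state raises immediately, naming cell and time.
- Zero-variance vectors are rejected (a named error) everywhere a
  correlation or cosine is computed; flat slices inside the day-pair drivers
  propagate as NaN and are excluded by nan-aware averaging.
- Sliding-window binning uses full windows only; ties in the
  maximal-distance point resolve to the earliest time point.
- STDP's F(0) is 0 (the window is undefined at zero lag); simultaneous
  pre/post spikes contribute nothing.
- The weight-dissimilarity metric z-scores each projection block before
  concatenating, so block-mean structure cannot masquerade as correlation;
  independently built networks score ≈ 1.

## Known limitations

- The printed full-scale anatomy diagnostics (≈291 reciprocal GCs per MT
  cell; ≈7368 GCs per PC above the feedback-weight threshold) are not
  reproducible under independent Bernoulli sampling at the tabulated
  densities, which predicts ≈75 reciprocal partners. Both counts are
  implemented as diagnostics (`reciprocal_partner_count`,
  `pc_projection_count`), and a `reciprocity_boost` option retargets a
  configurable fraction of each MT cell's inhibitory inputs onto its own GC
  targets for users who want the higher reciprocity without inventing a
  hidden sampling rule. The default remains independent sampling.
- At mini scale the piriform population inherits only a weakened form of
  the bulb's drift: each PC pools many MT inputs whose changes partially
  cancel (measured: a complete granule-cell turnover changes each PC's
  summed feedforward charge by ~3 % against a ~19 % across-cell spread),
  and the competitive amplification a 10,000-cell cortex provides is not
  fully reproduced by 800 cells. Systematic cortical drift at mini scale is
  therefore near the measurement floor, and the STDP arm's drift-rate
  *reduction* — a ratio of two near-zero slopes — is not meaningful at this
  scale, even though every STDP mechanism (efficacy suppression, per-synapse
  windows, masked eligibility, convergent weight histories) is active and
  verified. The full-scale regime is where the paired
  comparison carries information.
- Whether centrifugal feedback was on or off in the reference experiments is
  not documented; it defaults to on and is switchable everywhere.
- The exact population-vector construction (time-average vs concatenation of
  the cells × bins matrix) is ambiguous in the source description;
  time-averaging is the default and full concatenation remains available via
  `population_vector(..., mode="concatenate")`.
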