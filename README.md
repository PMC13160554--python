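# olfdrift

Spiking-network model of the early olfactory system — main olfactory bulb
(MOB) and piriform cortex (PCx) — built to study **representational drift
under adult neurogenesis** and its stabilization by spike-timing-dependent
plasticity (STDP).

The MOB continually receives adult-born granule cells (abGCs): inhibitory
interneurons whose synapses with mitral/tufted (M/T) cells are rebuilt
throughout life. `olfdrift` models this as daily *weight reshuffling* — each
simulated day, 10 % of granule cells have every synapse from and onto them
redrawn from the network's build distributions — inside a full spiking
circuit of Izhikevich neurons (M/T cells, granule cells, piriform principal
cells, feedforward/feedback interneurons; 26,250 cells at full scale). The
package then quantifies what this does to odor coding: population-vector
correlations across days (full-ensemble and in a pooled PCA space),
cosine-similarity trajectories, drift rates in degrees/day, and KNN odor
decoding — and how repeated odor experience, via the suppression-model STDP
rule Δw = ε_pre ε_post F(Δt) acting on abGC synapses, slows the drift of the
cortical code.

Who it is for: computational neuroscientists studying drift, neurogenesis,
or olfactory coding who want a complete, reproducible, pure-synthetic
pipeline — no external data; odors, networks and all statistics are
generated by code from a single seed.

## Worked example

Run the scaled-down (1/12.5) drift experiment — 11 days of neurogenesis,
20 odors x 5 trials per day, STDP off:

```bash
olfdrift run-drift --preset mini --seed 1 --outdir out/drift
```

prints after a few minutes on one CPU:

```json
{
  "mt_drift_deg_per_day": 0.004,
  "pc_drift_deg_per_day": -0.127
}
```

— the systematic daily rotation of the trial-averaged reduced-space
population trajectories (the least-squares slope of day-pair angle vs day
separation; values within a fraction of a degree of zero mean the
population code is stable at this scale, and small negative values are
estimation noise). The full picture is in `out/drift/drift_report.json`:

- `weight_dissimilarity_by_day` rises from 0 to ~1.0 — by Day-10 the
  granule-cell weights have completely turned over — while
  `weight_ks_by_day` stays below 0.002: the weight *distribution* never
  changes, only the identities.
- `within_reduced["mt"][0]` (Day-0 vs each day, reduced space) stays at
  0.997-0.999: the bulb's low-dimensional odor code is preserved through
  total granule-cell turnover.
- `within_full["mt"][0]` declines from 0.991 (Day-1) to 0.970 (Day-10):
  the full ensemble — individual M/T cells — does drift, exactly the
  dissociation the model is built to show.
- `across_reduced` stays low (mean ~ -0.27): different odors remain
  decorrelated throughout.

The paired STDP experiment,

```bash
olfdrift run-stdp --preset mini --seed 1 --outdir out/stdp
```

runs two arms with matched networks, odors, reshuffling cohorts and noise —
one with STDP at abGC synapses (all 50 daily trials plastic), one without —
and reports both drift rates plus the percent change under STDP, together
with per-trial weight histories of watched synapses (constant in the frozen
arm; jumping at their reshuffle day and then converging trial by trial in
the plastic arm). At mini scale both arms' systematic PC drift sits at the
measurement floor, so the headline reduction ratio is only informative at
larger scales (`docs/methods.md`, "Known limitations").

`docs/methods.md` documents the model, every tunable parameter, the
scaled-down preset, and known limitations. `--preset paper_scale` runs the
full-size network (overnight-class on one CPU).

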