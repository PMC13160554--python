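"""End-to-end experiments: representational drift and STDP stabilization.

Two protocols, both run entirely on synthetic inputs:

* **drift** — 11 simulated days; on each day after the baseline, 10% of the
  granule cells have their weights reshuffled (adult neurogenesis), then the
  full odor panel is presented (10 trials per odor at paper scale).  STDP is
  off.  The analysis quantifies how bulb and cortical population responses to
  identical odors decorrelate across days.
* **stdp** — the same daily reshuffling while a small, fixed odor set is
  presented many times per day (50 trials per odor), run as two arms with
  matched build/odor/cohort/noise randomness: one with the suppression-model
  STDP active at abGC-related synapses, one without.  The paired drift rates
  measure how much repeated experience stabilizes the cortical code.

Randomness is organised as named seed streams (build, odors, neurogenesis,
noise, stdp, analysis) derived from one master seed; per-trial noise
generators are keyed by (day, odor, trial) so the two STDP arms see identical
noise up to the first plasticity-induced weight difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from ._exceptions import ConfigError
from . import analysis as an
from .network import (
    GC_BLOCKS, MINI_SPEC, NetworkWeights, PopulationSpec, build_network,
    scaled_rules, weight_dissimilarity,
)
from .odors import OdorPanel, generate_panel, DEFAULT_AMPLITUDE
from .plasticity import (
    AbGCRegistry, NeurogenesisSchedule, STDPConfig, STDPUpdater,
    reshuffle_granule_cells, select_cohorts,
)
from .simulator import SimConfig, Simulator, draw_all_params

logger = logging.getLogger("olfdrift")

__all__ = [
    "ExperimentConfig",
    "drift_config",
    "stdp_config",
    "run_drift_experiment",
    "run_stdp_experiment",
]

_STREAMS = ("build", "odors", "neurogenesis", "noise", "stdp", "analysis")

#: reference cell count behind the "first 50 components" convention; the
#: variance-fraction diagnostic keeps the 50/1250 = 4% ratio at any scale.
_K50_REF_RATIO = 50 / 1250


@dataclass
class ExperimentConfig:
    """Full description of one experiment; outputs are a pure function of it."""

    preset: str = "mini"
    spec: PopulationSpec = field(default_factory=lambda: MINI_SPEC)
    n_days: int = 11
    n_odors: int = 20
    n_trials: int = 5
    #: trials per odor entering the analysis (None = all).  In the STDP
    #: protocol the plastic arm still experiences every trial; the analysis
    #: uses the final ``n_recording_trials`` of each odor's daily block, and
    #: the non-plastic arm only simulates those (its network state does not
    #: depend on unrecorded trials).
    n_recording_trials: int | None = None
    stdp_enabled: bool = False
    neurogenesis_enabled: bool = True
    neurogenesis_fraction: float = 0.1
    feedback_on: bool = True
    reciprocity_boost: float = 0.0
    amplitude: float = DEFAULT_AMPLITUDE
    similarity_mix: float = 0.2
    #: reduced-space dimensionality; None = the full-scale 50 components
    #: scaled with the population (50/1250 of the cell count, floor 3), so
    #: the reduced space stays *reduced* at any scale
    k_analysis: int | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    stdp: STDPConfig = field(default_factory=STDPConfig)
    n_across_pairs: int = 10
    decoder_ratios: tuple = (0.5, 0.7, 0.9)
    decoder_ks: tuple = (3, 5, 7)
    decoder_enabled: bool = True
    decoder_repeats: int = 30
    seed: int = 0

    @property
    def rules(self):
        """Connectivity rules, strength-rescaled to this spec's size so the
        per-cell synaptic drive matches the full-scale model."""
        return scaled_rules(self.spec)

    def stream_seeds(self) -> dict[str, np.random.SeedSequence]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return dict(zip(_STREAMS, children))


def drift_config(preset: str = "mini", seed: int = 0, **over) -> ExperimentConfig:
    """Drift experiment (neurogenesis on, STDP off)."""
    if preset == "mini":
        cfg = ExperimentConfig(preset=preset, spec=MINI_SPEC, n_odors=20,
                               n_trials=5, seed=seed)
    elif preset == "paper_scale":
        cfg = ExperimentConfig(preset=preset, spec=PopulationSpec(),
                               n_odors=100, n_trials=10, seed=seed)
    else:
        raise ConfigError(f"unknown preset {preset!r}")
    return replace(cfg, **over)


def stdp_config(preset: str = "mini", seed: int = 0, **over) -> ExperimentConfig:
    """STDP experiment (repeated daily odor set, 50 trials per odor).

    Odor decoding is not part of this protocol's readout, so the decoder is
    off by default."""
    if preset == "mini":
        cfg = ExperimentConfig(preset=preset, spec=MINI_SPEC, n_odors=10,
                               n_trials=50, n_recording_trials=10,
                               stdp_enabled=True, seed=seed,
                               decoder_enabled=False)
    elif preset == "paper_scale":
        cfg = ExperimentConfig(preset=preset, spec=PopulationSpec(),
                               n_odors=10, n_trials=50, n_recording_trials=10,
                               stdp_enabled=True, seed=seed,
                               decoder_enabled=False)
    else:
        raise ConfigError(f"unknown preset {preset!r}")
    return replace(cfg, **over)


# ---------------------------------------------------------------------------

class _PopAcc:
    """Streaming per-population response store.

    Keeps the trial-summed (cells x bins) rates per (day, odor) — enough for
    the pooled PCA and trial-averaged vectors — plus time-averaged vectors
    per single trial and for the even/odd trial subsets.
    """

    def __init__(self, D, O, T, n_cells, n_bins):
        self.T = T
        self.rate_sum = np.zeros((D, O, n_cells, n_bins), dtype=np.float32)
        self.trial_vec = np.zeros((D, O, T, n_cells), dtype=np.float32)
        self.even = np.zeros((D, O, n_cells))
        self.odd = np.zeros((D, O, n_cells))
        self.n_even = (T + 1) // 2
        self.n_odd = T // 2

    def add(self, day, odor, trial, rates):
        self.rate_sum[day, odor] += rates.astype(np.float32)
        tv = rates.mean(axis=1)
        self.trial_vec[day, odor, trial] = tv
        if trial % 2 == 0:
            self.even[day, odor] += tv
        else:
            self.odd[day, odor] += tv


def _analyze_population(acc: _PopAcc, cfg: ExperimentConfig, pairs, rng):
    """All drift statistics for one population."""
    D, O, C, B = acc.rate_sum.shape
    avg_rates = acc.rate_sum.astype(np.float64) / acc.T
    X = avg_rates.transpose(2, 0, 1, 3).reshape(C, D * O * B)
    eig = an.pooled_pca(X)
    del X

    avg_full = avg_rates.mean(axis=-1)                 # (D, O, C)
    even_full = acc.even / acc.n_even
    odd_full = acc.odd / max(acc.n_odd, 1)
    trial_full = acc.trial_vec.astype(np.float64)

    if cfg.k_analysis is not None:
        k = min(cfg.k_analysis, C)
    else:
        k = min(C, max(3, round(C * _K50_REF_RATIO)))
    W = eig.components[:, :k]
    m = eig.mean
    red = (avg_full - m) @ W
    even_red = (even_full - m) @ W
    odd_red = (odd_full - m) @ W
    trial_red = (trial_full - m) @ W

    out = {
        "eig": eig,
        "avg_rates": avg_rates,
        "within_full": an.within_odor_matrix(avg_full, even_full, odd_full),
        "within_full_single": an.within_odor_matrix_single_trial(trial_full),
        "within_reduced": an.within_odor_matrix(red, even_red, odd_red),
        "within_reduced_single": an.within_odor_matrix_single_trial(trial_red),
        "across_full": an.across_odor_matrix(avg_full, pairs),
        "across_reduced": an.across_odor_matrix(red, pairs),
        "cosine_reduced": an.cosine_matrix(red, even_red, odd_red),
        "drift_rate": an.drift_rate(red),
        # the literal "first 50 components" convention (capped by cell count),
        # plus a scaled-down diagnostic that keeps the 50/1250 component ratio
        "variance_fraction": eig.variance_fraction(
            max(1, min(C, round(C * _K50_REF_RATIO)))),
        "variance_fraction_50": eig.variance_fraction(min(50, C)),
    }
    if cfg.decoder_enabled:
        acc_tab = {}
        for (a, b) in pairs:
            Xa = trial_red[:, a].reshape(D * acc.T, k)
            Xb = trial_red[:, b].reshape(D * acc.T, k)
            Xy = np.concatenate([Xa, Xb])
            y = np.repeat([0, 1], len(Xa))
            for ratio in cfg.decoder_ratios:
                for K in cfg.decoder_ks:
                    n_train = int(round(ratio * len(y)))
                    if K > n_train or len(y) - n_train < 2:
                        continue  # split infeasible at this ratio/K
                    key = f"pair{a}-{b}_ratio{ratio}_K{K}"
                    acc_tab[key] = an.knn_decode(
                        Xy, y, train_ratio=ratio, K=K,
                        n_repeats=cfg.decoder_repeats, rng=rng,
                    )
        out["decoder_accuracy"] = acc_tab
    return out


def _draw_odor_pairs(n_odors: int, n_pairs: int, rng) -> np.ndarray:
    """Fixed distinct odor pairs used by the across-odor controls."""
    pairs = set()
    while len(pairs) < min(n_pairs, n_odors * (n_odors - 1) // 2):
        a, b = rng.choice(n_odors, size=2, replace=False)
        pairs.add((min(a, b), max(a, b)))
    return np.array(sorted(pairs))


def _gc_weight_sample(net: NetworkWeights) -> np.ndarray:
    """Nonzero weights of the neurogenesis-mutable blocks (histogram sample)."""
    return np.concatenate([net.blocks[b].data for b in GC_BLOCKS])


def _trial_rng(noise_base: int, day: int, odor: int, trial: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((noise_base, day, odor, trial))
    )


def _run_protocol(
    cfg: ExperimentConfig,
    net: NetworkWeights,
    params: dict,
    panel: OdorPanel,
    cohorts,
    noise_base: int,
    updater: STDPUpdater | None,
    stdp_rng: np.random.Generator | None,
    neuro_seed: np.random.SeedSequence,
    watch: list | None = None,
) -> tuple[dict, list, list, AbGCRegistry]:
    """Day loop shared by both experiments; returns accumulators + weight logs."""
    spec = cfg.spec
    sim = Simulator(net, params, cfg.sim)
    registry = updater.registry if updater is not None else AbGCRegistry.fresh(spec.n_gc)
    n_bins = an.bin_spikes(np.zeros((1, cfg.sim.n_steps))).shape[1]
    n_rec = min(cfg.n_recording_trials or cfg.n_trials, cfg.n_trials)
    rec_start = cfg.n_trials - n_rec
    accs = {
        "mt": _PopAcc(cfg.n_days, cfg.n_odors, n_rec, spec.n_mt, n_bins),
        "pc": _PopAcc(cfg.n_days, cfg.n_odors, n_rec, spec.n_pc, n_bins),
    }
    day0 = net.copy()
    w0 = _gc_weight_sample(net)
    wd_by_day, ks_by_day = [0.0], [0.0]
    watch_log = []
    neuro_rng = np.random.default_rng(neuro_seed)

    for day in range(cfg.n_days):
        if day > 0 and cfg.neurogenesis_enabled:
            reshuffle_granule_cells(
                net, cohorts[day - 1], neuro_rng, registry, day,
                stdp_store=updater.store if updater is not None else None,
                rules=cfg.rules, stdp_rng=stdp_rng,
            )
            sim.rebuild(GC_BLOCKS)
            wd_by_day.append(weight_dissimilarity(day0, net))
            ks_by_day.append(float(
                sps.ks_2samp(w0, _gc_weight_sample(net)).statistic
            ))
        elif day > 0:
            wd_by_day.append(wd_by_day[-1])
            ks_by_day.append(ks_by_day[-1])
        for oi in range(cfg.n_odors):
            for tr in range(cfg.n_trials):
                recorded = tr >= rec_start
                if updater is None and not recorded:
                    continue  # a frozen network's state ignores skipped trials
                rng = _trial_rng(noise_base, day, oi, tr)
                raster = sim.run_trial(panel[oi], rng,
                                       key={"day": day, "odor": oi, "trial": tr})
                if recorded:
                    for pop in ("mt", "pc"):
                        accs[pop].add(day, oi, tr - rec_start,
                                      an.bin_spikes(raster, pop))
                if updater is not None:
                    changed = updater.apply_from_raster(raster)
                    if changed:
                        sim.sync_weights(changed)
                if watch:
                    for (name, r_, c_) in watch:
                        watch_log.append({
                            "day": day, "odor": oi, "trial": tr,
                            "synapse": f"{name}[{r_},{c_}]",
                            "weight": float(net.blocks[name][r_, c_]),
                        })
            logger.info("day %d odor %d done", day, oi)
    return accs, wd_by_day, ks_by_day, registry, watch_log


def _build_shared(cfg: ExperimentConfig):
    """Network, cell parameters, odor panel, cohorts — the shared substrate."""
    seeds = cfg.stream_seeds()
    build_rng = np.random.default_rng(seeds["build"])
    net = build_network(cfg.spec, cfg.rules, rng=build_rng,
                        feedback_on=cfg.feedback_on,
                        reciprocity_boost=cfg.reciprocity_boost)
    params = draw_all_params(cfg.spec, build_rng)
    panel = generate_panel(cfg.n_odors, cfg.spec.n_glomeruli,
                           rng=np.random.default_rng(seeds["odors"]),
                           similarity_mix=cfg.similarity_mix,
                           amplitude=cfg.amplitude)
    schedule = NeurogenesisSchedule(fraction_per_day=cfg.neurogenesis_fraction,
                                    n_days=cfg.n_days)
    cohort_rng = np.random.default_rng(seeds["neurogenesis"])
    cohorts = select_cohorts(cfg.spec.n_gc, schedule, cohort_rng)
    # a second child of the neurogenesis stream drives the weight redraws
    neuro_seed = seeds["neurogenesis"].spawn(1)[0]
    noise_base = int(seeds["noise"].generate_state(1)[0])
    return seeds, net, params, panel, cohorts, neuro_seed, noise_base


def _report_from(accs, cfg, pairs, analysis_rng, wd, ks) -> an.DriftReport:
    rep = an.DriftReport(days=cfg.n_days, odors=cfg.n_odors,
                         trials=min(cfg.n_recording_trials or cfg.n_trials,
                                    cfg.n_trials))
    rep.odor_pairs = [tuple(int(x) for x in p) for p in pairs]
    rep.weight_dissimilarity_by_day = [float(x) for x in wd]
    rep.weight_ks_by_day = [float(x) for x in ks]
    rep.meta = {
        "preset": cfg.preset, "seed": cfg.seed,
        "stdp_enabled": cfg.stdp_enabled,
        "neurogenesis_enabled": cfg.neurogenesis_enabled,
        "feedback_on": cfg.feedback_on,
        "k_analysis": cfg.k_analysis,
    }
    for pop in ("mt", "pc"):
        res = _analyze_population(accs[pop], cfg, pairs, analysis_rng)
        rep.within_full[pop] = res["within_full"]
        rep.within_full_single[pop] = res["within_full_single"]
        rep.within_reduced[pop] = res["within_reduced"]
        rep.within_reduced_single[pop] = res["within_reduced_single"]
        rep.across_full[pop] = res["across_full"]
        rep.across_reduced[pop] = res["across_reduced"]
        rep.cosine_reduced[pop] = res["cosine_reduced"]
        rep.drift_rate_deg_per_day[pop] = res["drift_rate"]
        rep.variance_fraction[pop] = res["variance_fraction"]
        rep.variance_fraction_50[pop] = res["variance_fraction_50"]
        if cfg.decoder_enabled:
            rep.decoder_accuracy[pop] = res["decoder_accuracy"]
    return rep


def run_drift_experiment(cfg: ExperimentConfig | None = None) -> an.DriftReport:
    """Neurogenesis-driven drift without STDP (the panel protocol)."""
    cfg = cfg or drift_config()
    if cfg.stdp_enabled:
        raise ConfigError("drift experiment runs with stdp_enabled=False")
    seeds, net, params, panel, cohorts, neuro_seed, noise_base = _build_shared(cfg)
    accs, wd, ks, registry, _ = _run_protocol(
        cfg, net, params, panel, cohorts, noise_base,
        updater=None, stdp_rng=None, neuro_seed=neuro_seed,
    )
    analysis_rng = np.random.default_rng(seeds["analysis"])
    pairs = _draw_odor_pairs(cfg.n_odors, cfg.n_across_pairs, analysis_rng)
    return _report_from(accs, cfg, pairs, analysis_rng, wd, ks)


def _pick_watch_synapses(net: NetworkWeights, cohorts, n_days: int) -> list:
    """Two synapses of a GC reshuffled mid-experiment (weight-history probes)."""
    mid = cohorts[min(3, len(cohorts) - 1)]
    mc2gc = net.blocks["mc2gc"]
    for g in mid:
        s0, s1 = mc2gc.indptr[g], mc2gc.indptr[g + 1]
        if s1 > s0:
            watch = [("mc2gc", int(g), int(mc2gc.indices[s0]))]
            gc2mc = net.blocks["gc2mc"].tocsc()
            t0, t1 = gc2mc.indptr[g], gc2mc.indptr[g + 1]
            if t1 > t0:
                watch.append(("gc2mc", int(gc2mc.indices[t0]), int(g)))
            return watch
    return []


def run_stdp_experiment(cfg: ExperimentConfig | None = None) -> dict:
    """Paired arms (STDP on / off) under matched randomness.

    Returns ``{"with_stdp": DriftReport, "without_stdp": DriftReport,
    "summary": {...}, "watch_history": [...]}``; the summary carries the PC
    and MT drift rates of both arms and the percent reduction under STDP.
    """
    cfg = cfg or stdp_config()
    seeds, net, params, panel, cohorts, neuro_seed, noise_base = _build_shared(cfg)
    watch = _pick_watch_synapses(net, cohorts, cfg.n_days)
    analysis_rng = np.random.default_rng(seeds["analysis"])
    pairs = _draw_odor_pairs(cfg.n_odors, cfg.n_across_pairs, analysis_rng)

    reports, watch_hist = {}, {}
    for arm, use_stdp in (("without_stdp", False), ("with_stdp", True)):
        net_arm = net.copy()
        updater = None
        stdp_rng = None
        if use_stdp:
            stdp_rng = np.random.default_rng(seeds["stdp"])
            updater = STDPUpdater(net_arm, AbGCRegistry.fresh(cfg.spec.n_gc),
                                  stdp_rng, cfg.stdp, rules=cfg.rules)
        accs, wd, ks, registry, wlog = _run_protocol(
            cfg, net_arm, params, panel, cohorts, noise_base,
            updater=updater, stdp_rng=stdp_rng, neuro_seed=neuro_seed,
            watch=watch,
        )
        reports[arm] = _report_from(accs, cfg, pairs,
                                    np.random.default_rng(seeds["analysis"]), wd, ks)
        watch_hist[arm] = wlog
        logger.info("arm %s complete", arm)

    d_with = reports["with_stdp"].drift_rate_deg_per_day
    d_wo = reports["without_stdp"].drift_rate_deg_per_day
    summary = {
        "pc_drift_without_stdp": d_wo["pc"],
        "pc_drift_with_stdp": d_with["pc"],
        "mt_drift_without_stdp": d_wo["mt"],
        "mt_drift_with_stdp": d_with["mt"],
        "pc_drift_reduction_pct": 100.0 * (1.0 - d_with["pc"] / d_wo["pc"]),
    }
    return {"with_stdp": reports["with_stdp"],
            "without_stdp": reports["without_stdp"],
            "summary": summary,
            "watch_history": watch_hist}
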