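"""Adult neurogenesis (daily granule-cell weight reshuffling) and STDP.

Neurogenesis is modelled as replacement-in-place: on each simulated day a
cohort of granule cells (10% by default) has every synaptic weight from and
onto it redrawn from the same distributions used to build the network, so the
global weight distribution is preserved while individual connections turn
over.  A registry tracks which GCs have become adult-born (abGC) and when.

STDP follows the suppression model: every pre- and postsynaptic spike carries
an efficacy eps_i = 1 - exp(-(t_i - t_{i-1})/tau_s) that discounts spikes
arriving close after a predecessor, and each pre/post spike pair contributes
eps_pre * eps_post * F(dt) with the asymmetric exponential window

    F(dt) = A+ exp(-|dt|/tau+)   for dt > 0 (post after pre; potentiation)
            A- exp(-|dt|/tau-)   for dt < 0 (depression), F(0) = 0.

A, tau are drawn per synapse.  Plasticity is restricted to abGC-related
synapses: onto abGCs from MT cells, GC/SAC cells and PCs, and from abGCs onto
MT and GC/SAC cells.  Updates act on the weight magnitude with soft bounds
(potentiation scaled by the headroom below the cap, depression by the
current magnitude), so every synapse has a stable activity-determined
equilibrium and no synapse ever changes sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._exceptions import ConfigError
from .network import (
    NetworkWeights, TABLE_RULES, DELAY_RANGE_MS, build_feedback_rows, _random_rows,
)
from .simulator import SpikeRaster

__all__ = [
    "NeurogenesisSchedule",
    "AbGCRegistry",
    "STDPConfig",
    "STDPStore",
    "STDPUpdater",
    "select_cohorts",
    "reshuffle_granule_cells",
    "spike_efficacy",
    "stdp_window",
    "stdp_pair_sum",
]

#: Blocks whose entries are eligible for STDP (all abGC-related projections).
PLASTIC_BLOCKS = ("mc2gc", "gc2mc", "gc2gc", "pc2gc")


@dataclass
class NeurogenesisSchedule:
    """Daily reshuffle plan.  Day 0 is the baseline (no reshuffle)."""

    fraction_per_day: float = 0.1
    n_days: int = 11
    cohort_policy: str = "without_replacement"
    cohorts: list = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 <= self.fraction_per_day <= 1.0):
            raise ConfigError("fraction_per_day must be in [0, 1]")
        if self.cohort_policy not in ("without_replacement", "with_replacement"):
            raise ConfigError(f"unknown cohort_policy {self.cohort_policy!r}")


def select_cohorts(
    n_gc: int,
    schedule: NeurogenesisSchedule,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """GC index sets for reshuffle days 1 .. n_days-1.

    Under ``without_replacement`` the cohorts are pairwise disjoint, so after
    fraction * (n_days - 1) = 1 the union covers the whole GC population —
    matching the regime in which almost every GC has turned over by the last
    day.
    """
    size = int(round(schedule.fraction_per_day * n_gc))
    n_reshuffle = schedule.n_days - 1
    if schedule.cohort_policy == "without_replacement":
        if size * n_reshuffle > n_gc:
            raise ConfigError(
                f"cannot draw {n_reshuffle} disjoint cohorts of {size} from {n_gc} GCs"
            )
        perm = rng.permutation(n_gc)
        cohorts = [np.sort(perm[i * size:(i + 1) * size]) for i in range(n_reshuffle)]
    else:
        cohorts = [np.sort(rng.choice(n_gc, size=size, replace=False))
                   for _ in range(n_reshuffle)]
    schedule.cohorts = cohorts
    return cohorts


@dataclass
class AbGCRegistry:
    """Tracks which granule cells are adult-born and their reshuffle day."""

    birth_day: np.ndarray

    @classmethod
    def fresh(cls, n_gc: int) -> "AbGCRegistry":
        return cls(birth_day=np.full(n_gc, -1, dtype=np.int64))

    def mark(self, cohort: np.ndarray, day: int) -> None:
        self.birth_day[cohort] = day

    @property
    def abgc_mask(self) -> np.ndarray:
        return self.birth_day >= 0

    @property
    def n_abgc(self) -> int:
        return int(self.abgc_mask.sum())


# ---------------------------------------------------------------------------
# STDP parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class STDPConfig:
    """Distributional and scaling constants of the suppression-model STDP.

    Window amplitudes and time constants are drawn per synapse from normal
    distributions; suppression constants differ between the pre (34 ms) and
    post (75 ms) sides.  ``lr_scale`` converts the O(1) pair sums into weight
    increments relative to each block's mean strength; ``cap_scale`` bounds
    every plastic weight magnitude at cap_scale x block mean.
    """

    a_plus: tuple[float, float] = (1.03, 0.1)
    a_minus: tuple[float, float] = (-0.51, 0.01)
    tau_plus_ms: tuple[float, float] = (13.3, 1.7)
    tau_minus_ms: tuple[float, float] = (34.5, 1.6)
    tau_s_pre_ms: float = 34.0
    tau_s_post_ms: float = 75.0
    #: weight change = lr_scale x block mean strength per unit pair-sum,
    #: calibrated so plastic weights evolve gradually trial by trial and
    #: approach their asymptote over the course of the 11-day protocol
    #: (larger rates equilibrate within a day and destabilise the
    #: excitatory/inhibitory balance)
    lr_scale: float = 5e-4
    cap_scale: float = 4.0


def draw_synapse_params(k: int, rng: np.random.Generator, cfg: STDPConfig) -> dict:
    """Per-synapse window parameters, clipped to their admissible sign."""
    return {
        "A_plus": np.maximum(rng.normal(*cfg.a_plus, size=k), 1e-6),
        "A_minus": np.minimum(rng.normal(*cfg.a_minus, size=k), -1e-6),
        "tau_plus": np.maximum(rng.normal(*cfg.tau_plus_ms, size=k), 0.1),
        "tau_minus": np.maximum(rng.normal(*cfg.tau_minus_ms, size=k), 0.1),
    }


class STDPStore:
    """Per-synapse STDP parameters aligned with each plastic block's CSR data."""

    def __init__(self, net: NetworkWeights, rng: np.random.Generator,
                 cfg: STDPConfig | None = None):
        self.cfg = cfg or STDPConfig()
        self.params: dict[str, dict[str, np.ndarray]] = {}
        for name in PLASTIC_BLOCKS:
            self.params[name] = draw_synapse_params(net.blocks[name].nnz, rng, self.cfg)


# ---------------------------------------------------------------------------
# Neurogenesis reshuffling
# ---------------------------------------------------------------------------

def _csr_multi(shape, rows, cols, value_arrays):
    """Build CSR matrices with one shared pattern and several value arrays."""
    order = np.lexsort((cols, rows))
    indices = cols[order].astype(np.int32)
    counts = np.bincount(rows, minlength=shape[0])
    indptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int32)
    return [sp.csr_matrix((vals[order], indices, indptr), shape=shape)
            for vals in value_arrays]


def reshuffle_granule_cells(
    net: NetworkWeights,
    cohort: np.ndarray,
    rng: np.random.Generator,
    registry: AbGCRegistry | None = None,
    day: int | None = None,
    stdp_store: STDPStore | None = None,
    rules=None,
    stdp_rng: np.random.Generator | None = None,
) -> None:
    """Redraw every synapse from and onto the cohort GCs, in place.

    Affected blocks: MT->GC rows (with fresh delivery delays), GC->MT columns,
    GC<->GC rows and columns, and PC->GC feedback rows (rebuilt with the
    glomerulus-crossing structure, using the cohort's new reciprocal
    partners).  All other synapses are left bit-identical.  When an
    ``stdp_store`` is given, per-synapse STDP parameters are redrawn for the
    new synapses and preserved elsewhere.
    """
    rules = dict(TABLE_RULES if rules is None else rules)
    spec = net.spec
    cohort = np.asarray(cohort, dtype=np.int64)
    in_cohort = np.zeros(spec.n_gc, dtype=bool)
    in_cohort[cohort] = True
    cfg = stdp_store.cfg if stdp_store is not None else None
    # STDP parameter draws come from their own stream so that paired runs
    # (plasticity on vs off) see identical weight redraws
    stdp_rng = rng if stdp_rng is None else stdp_rng

    def rebuild(name, keep_fn, new_rows, new_cols, extra_old=None, extra_new=None):
        """Replace block `name`: keep entries passing keep_fn, add new ones.

        extra_old/extra_new: dict of additional aligned value arrays
        (e.g. delays) keyed by label.
        """
        block = net.blocks[name]
        coo = block.tocoo()
        keep = keep_fn(coo.row, coo.col)
        rule = rules[name]
        new_vals = rule.sign * rule.draw_magnitudes(len(new_rows), rng)
        rows = np.concatenate([coo.row[keep], new_rows])
        cols = np.concatenate([coo.col[keep], new_cols])
        value_arrays = [np.concatenate([coo.data[keep], new_vals])]
        labels = ["w"]
        for lab in (extra_old or {}):
            value_arrays.append(np.concatenate([extra_old[lab][keep], extra_new[lab]]))
            labels.append(lab)
        if stdp_store is not None and name in PLASTIC_BLOCKS:
            old_p = stdp_store.params[name]
            new_p = draw_synapse_params(len(new_rows), stdp_rng, cfg)
            for lab in ("A_plus", "A_minus", "tau_plus", "tau_minus"):
                value_arrays.append(np.concatenate([old_p[lab][keep], new_p[lab]]))
                labels.append(lab)
        mats = _csr_multi(block.shape, rows, cols, value_arrays)
        net.blocks[name] = mats[0]
        out = {}
        for lab, m in zip(labels[1:], mats[1:]):
            out[lab] = m
        if stdp_store is not None and name in PLASTIC_BLOCKS:
            stdp_store.params[name] = {
                lab: out.pop(lab).data
                for lab in ("A_plus", "A_minus", "tau_plus", "tau_minus")
            }
        return out

    # MT -> GC: cohort rows, plus per-synapse delays
    r, c = _random_rows(len(cohort), spec.n_mt, rules["mc2gc"], rng)
    old_delays = net.delays_mt_gc.tocoo().data
    lo, hi = DELAY_RANGE_MS
    extra = rebuild(
        "mc2gc",
        keep_fn=lambda rr, cc: ~in_cohort[rr],
        new_rows=cohort[r], new_cols=c,
        extra_old={"delay": old_delays},
        extra_new={"delay": rng.uniform(lo, hi, size=len(r))},
    )
    net.delays_mt_gc = extra["delay"]

    # GC -> MT: cohort columns
    r, c = _random_rows(spec.n_mt, len(cohort), rules["gc2mc"], rng)
    rebuild("gc2mc", keep_fn=lambda rr, cc: ~in_cohort[cc],
            new_rows=r, new_cols=cohort[c])

    # GC <-> GC: cohort rows over all columns, plus cohort columns for
    # non-cohort rows; no autapses
    ra, ca = _random_rows(len(cohort), spec.n_gc, rules["gc2gc"], rng)
    ra, ca = cohort[ra], ca
    keep_a = ra != ca
    others = np.flatnonzero(~in_cohort)
    rb, cb = _random_rows(len(others), len(cohort), rules["gc2gc"], rng)
    rb, cb = others[rb], cohort[cb]
    rebuild("gc2gc", keep_fn=lambda rr, cc: ~in_cohort[rr] & ~in_cohort[cc],
            new_rows=np.concatenate([ra[keep_a], rb]),
            new_cols=np.concatenate([ca[keep_a], cb]))

    # PC -> GC feedback: cohort rows, rebuilt with the crossing structure
    if net.feedback_on:
        parts = {
            "mc2gc": net.blocks["mc2gc"], "gc2mc": net.blocks["gc2mc"],
            "mc2pc": net.blocks["mc2pc"], "glom_of_mt": spec.glomerulus_of_mt,
            "n_glom": spec.n_glomeruli, "n_pc": spec.n_pc, "n_gc": spec.n_gc,
        }
        sub = build_feedback_rows(cohort, parts, rules["pc2gc"], rng).tocoo()
        block = net.blocks["pc2gc"].tocoo()
        keep = ~in_cohort[block.row]
        rows = np.concatenate([block.row[keep], sub.row])
        cols = np.concatenate([block.col[keep], sub.col])
        value_arrays = [np.concatenate([block.data[keep], sub.data])]
        labels = []
        if stdp_store is not None:
            old_p = stdp_store.params["pc2gc"]
            new_p = draw_synapse_params(sub.nnz, stdp_rng, cfg)
            for lab in ("A_plus", "A_minus", "tau_plus", "tau_minus"):
                value_arrays.append(np.concatenate([old_p[lab][keep], new_p[lab]]))
                labels.append(lab)
        mats = _csr_multi(block.shape, rows, cols, value_arrays)
        net.blocks["pc2gc"] = mats[0]
        if stdp_store is not None:
            stdp_store.params["pc2gc"] = {
                lab: m.data for lab, m in zip(labels, mats[1:])
            }

    if registry is not None:
        registry.mark(cohort, 0 if day is None else day)


# ---------------------------------------------------------------------------
# STDP primitives
# ---------------------------------------------------------------------------

def spike_efficacy(train_ms: np.ndarray, tau_s_ms: float) -> np.ndarray:
    """Per-spike efficacies 1 - exp(-isi/tau_s); an isolated (first) spike has
    efficacy 1."""
    t = np.asarray(train_ms, dtype=float)
    if len(t) == 0:
        return np.empty(0)
    if np.any(np.diff(t) < 0):
        raise ConfigError("spike train must be sorted ascending")
    eps = np.ones(len(t))
    if len(t) > 1:
        eps[1:] = 1.0 - np.exp(-np.diff(t) / tau_s_ms)
    return eps


def stdp_window(delta_t_ms, A_plus, A_minus, tau_plus_ms, tau_minus_ms):
    """Asymmetric exponential STDP window; F(0) = 0 by convention."""
    dt = np.asarray(delta_t_ms, dtype=float)
    pot = A_plus * np.exp(-np.abs(dt) / tau_plus_ms)
    dep = A_minus * np.exp(-np.abs(dt) / tau_minus_ms)
    return np.where(dt > 0, pot, np.where(dt < 0, dep, 0.0))


def stdp_pair_sum(
    pre_ms: np.ndarray,
    post_ms: np.ndarray,
    A_plus: float,
    A_minus: float,
    tau_plus_ms: float,
    tau_minus_ms: float,
    tau_s_pre_ms: float = 34.0,
    tau_s_post_ms: float = 75.0,
) -> float:
    """All-pairs efficacy-weighted window sum for a single synapse."""
    if len(pre_ms) == 0 or len(post_ms) == 0:
        return 0.0
    ep = spike_efficacy(pre_ms, tau_s_pre_ms)
    eq = spike_efficacy(post_ms, tau_s_post_ms)
    dt = np.asarray(post_ms)[None, :] - np.asarray(pre_ms)[:, None]
    F = stdp_window(dt, A_plus, A_minus, tau_plus_ms, tau_minus_ms)
    return float(np.sum(ep[:, None] * eq[None, :] * F))


def _trains(raster: SpikeRaster, pop: str):
    """Per-cell spike-time arrays (local cell index) for one population."""
    sl = raster.pop_slices[pop]
    mask = (raster.cells >= sl.start) & (raster.cells < sl.stop)
    cells = raster.cells[mask] - sl.start
    times = raster.times_ms[mask]
    order = np.lexsort((times, cells))
    cells, times = cells[order], times[order]
    n = sl.stop - sl.start
    bounds = np.searchsorted(cells, np.arange(n + 1))
    return times, bounds



_NUMBA_STDP = None


def _get_stdp_kernel():
    """Compiled all-pairs pair-sum kernel; None if numba is unavailable."""
    global _NUMBA_STDP
    if _NUMBA_STDP is not None:
        return _NUMBA_STDP
    try:
        import numba
    except ImportError:       # pragma: no cover
        return None

    @numba.njit(cache=True)
    def kernel(post_rows, indptr, indices, data, Ap, Am, Tp, Tm,
               pre_t, pre_b, pre_e, post_t, post_b, post_e,
               pre_spiked, abgc, mode, excit, lr, cap, changed):
        # mode 0: any spiked pre; 1: pre abGC or post abGC (GC<->GC);
        # 2: pre must be abGC (abGC -> MT)
        nc = 0
        for r in range(len(post_rows)):
            i = post_rows[r]
            q0, q1 = post_b[i], post_b[i + 1]
            if q1 == q0:
                continue
            post_is_ab = mode == 1 and abgc[i]
            for k in range(indptr[i], indptr[i + 1]):
                j = indices[k]
                if not pre_spiked[j]:
                    continue
                if mode == 1 and not (post_is_ab or abgc[j]):
                    continue
                if mode == 2 and not abgc[j]:
                    continue
                p0, p1 = pre_b[j], pre_b[j + 1]
                if p1 == p0:
                    continue
                Sp = 0.0
                Sn = 0.0
                ap, am, tp_, tm_ = Ap[k], Am[k], Tp[k], Tm[k]
                pot_cut = 9.0 * tp_
                dep_cut = 9.0 * tm_
                for pp in range(p0, p1):
                    tpre = pre_t[pp]
                    epre = pre_e[pp]
                    for qq in range(q0, q1):
                        dtv = post_t[qq] - tpre
                        if dtv > 0.0:
                            if dtv < pot_cut:
                                Sp += epre * post_e[qq] * ap * np.exp(-dtv / tp_)
                        elif dtv < 0.0:
                            if -dtv < dep_cut:
                                Sn += epre * post_e[qq] * am * np.exp(dtv / tm_)
                if Sp != 0.0 or Sn != 0.0:
                    # soft bounds: potentiation scaled by headroom, depression
                    # by the current magnitude -> stable per-synapse
                    # equilibrium, no runaway
                    m = data[k] if excit else -data[k]
                    m = m + lr * (Sp * (1.0 - m / cap) + Sn * (m / cap))
                    m = min(max(m, 0.0), cap)
                    data[k] = m if excit else -m
                    changed[nc] = k
                    nc += 1
        return nc

    _NUMBA_STDP = kernel
    return kernel


class STDPUpdater:
    """Applies one trial's spikes to the plastic weights of a network.

    Weights are frozen within a trial and updated once at trial end from the
    complete pre/post spike trains.  The per-block learning rate is
    lr_scale x |mean strength| and the magnitude cap is cap_scale x
    |mean strength|.  Updates act on the weight magnitude with soft bounds:
    the potentiation sum is scaled by the headroom (1 - |w|/cap) and the
    depression sum by |w|/cap, so every synapse has a stable
    activity-determined equilibrium and repeated identical stimulation makes
    weights converge instead of running away.
    """

    #: presynaptic population of each plastic block
    _PRE = {"mc2gc": "mt", "gc2mc": "gc", "gc2gc": "gc", "pc2gc": "pc"}
    _POST = {"mc2gc": "gc", "gc2mc": "mt", "gc2gc": "gc", "pc2gc": "gc"}
    _EXCITATORY = {"mc2gc": True, "gc2mc": False, "gc2gc": False, "pc2gc": True}

    def __init__(self, net: NetworkWeights, registry: AbGCRegistry,
                 rng: np.random.Generator, cfg: STDPConfig | None = None,
                 rules=None):
        self.net = net
        self.registry = registry
        self.cfg = cfg or STDPConfig()
        self.store = STDPStore(net, rng, self.cfg)
        rules = dict(TABLE_RULES if rules is None else rules)
        self.lr = {b: self.cfg.lr_scale * abs(rules[b].mean_strength)
                   for b in PLASTIC_BLOCKS}
        self.cap = {b: self.cfg.cap_scale * abs(rules[b].mean_strength)
                    for b in PLASTIC_BLOCKS}
        self._changed_buf: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------------
    def _block_update(self, name, times_pre, bounds_pre, eff_pre,
                      times_post, bounds_post, eff_post,
                      post_rows, pre_eligible) -> np.ndarray:
        """Accumulate pair sums for one block; returns the CSR-data
        positions of the updated entries."""
        block = self.net.blocks[name]
        par = self.store.params[name]
        indptr, indices, data = block.indptr, block.indices, block.data
        lr, cap = self.lr[name], self.cap[name]
        excit = self._EXCITATORY[name]
        changed = []
        for i in post_rows:
            pt = times_post[bounds_post[i]:bounds_post[i + 1]]
            if len(pt) == 0:
                continue
            pe = eff_post[bounds_post[i]:bounds_post[i + 1]]
            s0, s1 = indptr[i], indptr[i + 1]
            cols = indices[s0:s1]
            ok = pre_eligible(i, cols)
            if not ok.any():
                continue
            pos = s0 + np.flatnonzero(ok)
            cs = cols[ok]
            n_pre = bounds_pre[cs + 1] - bounds_pre[cs]
            live = n_pre > 0
            if not live.any():
                continue
            pos, cs, n_pre = pos[live], cs[live], n_pre[live]
            syn_of_spike = np.repeat(np.arange(len(cs)), n_pre)
            sel = _concat_ranges(bounds_pre[cs], n_pre)
            tp = times_pre[sel]
            ep = eff_pre[sel]
            dt = pt[None, :] - tp[:, None]          # (pre spikes, post spikes)
            Ap = par["A_plus"][pos][syn_of_spike][:, None]
            Am = par["A_minus"][pos][syn_of_spike][:, None]
            Tp = par["tau_plus"][pos][syn_of_spike][:, None]
            Tm = par["tau_minus"][pos][syn_of_spike][:, None]
            Fp = np.where(dt > 0, Ap * np.exp(-dt / Tp), 0.0)
            Fn = np.where(dt < 0, Am * np.exp(dt / Tm), 0.0)
            bnd = np.concatenate([[0], np.cumsum(n_pre)])[:-1]
            wpre = ep[:, None] * pe[None, :]
            Sp = np.add.reduceat((wpre * Fp).sum(axis=1), bnd)
            Sn = np.add.reduceat((wpre * Fn).sum(axis=1), bnd)
            m = data[pos] if excit else -data[pos]
            m = np.clip(m + lr * (Sp * (1.0 - m / cap) + Sn * (m / cap)),
                        0.0, cap)
            data[pos] = m if excit else -m
            changed.append(pos)
        return np.concatenate(changed) if changed else np.empty(0, dtype=np.int64)

    # ------------------------------------------------------------------
    def apply_from_raster(self, raster: SpikeRaster) -> dict[str, np.ndarray]:
        """Update all plastic blocks from one trial's raster; returns, per
        changed block, the CSR-data positions of the updated entries."""
        cfg = self.cfg
        abgc = self.registry.abgc_mask
        if not abgc.any():
            return {}
        trains = {}
        for pop in ("mt", "gc", "pc"):
            times, bounds = _trains(raster, pop)
            eff_pre = _efficacies(times, bounds, cfg.tau_s_pre_ms)
            eff_post = _efficacies(times, bounds, cfg.tau_s_post_ms)
            trains[pop] = (times, bounds, eff_pre, eff_post)

        changed = {}
        gc_spiked = _spiked_mask(trains["gc"][1])
        mt_spiked = _spiked_mask(trains["mt"][1])
        pc_spiked = _spiked_mask(trains["pc"][1])

        spiked = {"mt": mt_spiked, "gc": gc_spiked, "pc": pc_spiked}
        specs = {
            "mc2gc": (np.flatnonzero(gc_spiked & abgc), 0,
                      lambda i, cols: mt_spiked[cols]),
            "pc2gc": (np.flatnonzero(gc_spiked & abgc), 0,
                      lambda i, cols: pc_spiked[cols]),
            "gc2gc": (np.flatnonzero(gc_spiked), 1,
                      lambda i, cols: gc_spiked[cols] & (abgc[cols] | abgc[i])),
            "gc2mc": (np.flatnonzero(mt_spiked), 2,
                      lambda i, cols: gc_spiked[cols] & abgc[cols]),
        }
        kernel = _get_stdp_kernel()
        for name, (rows, mode, eligible) in specs.items():
            block = self.net.blocks[name]
            if block.nnz == 0 or len(rows) == 0:
                continue
            pre = self._PRE[name]
            post = self._POST[name]
            tp, bp, ep, _ = trains[pre]
            tq, bq, _, eq = trains[post]
            if kernel is not None:
                par = self.store.params[name]
                buf = self._changed_buf.get(name)
                if buf is None or len(buf) < block.nnz:
                    buf = np.empty(block.nnz, dtype=np.int64)
                    self._changed_buf[name] = buf
                nc = kernel(
                    rows, block.indptr, block.indices, block.data,
                    par["A_plus"], par["A_minus"], par["tau_plus"], par["tau_minus"],
                    tp, bp, ep, tq, bq, eq,
                    spiked[pre], abgc, mode, self._EXCITATORY[name],
                    self.lr[name], self.cap[name], buf,
                )
                pos = buf[:nc].copy()
            else:
                pos = self._block_update(name, tp, bp, ep, tq, bq, eq, rows, eligible)
            if len(pos):
                changed[name] = pos
        return changed


def _concat_ranges(starts, counts):
    from .simulator import _ranges
    return _ranges(np.asarray(starts), np.asarray(counts))


def _efficacies(times, bounds, tau_s):
    """Efficacy of every spike in a (times, cell-bounds) train bundle."""
    eff = np.ones(len(times))
    if len(times):
        isi = np.diff(times)
        eff[1:] = 1.0 - np.exp(-isi / tau_s)
        eff[bounds[:-1][(bounds[:-1] < len(times))]] = 1.0  # first spike per cell
    return eff


def _spiked_mask(bounds):
    return np.diff(bounds) > 0
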