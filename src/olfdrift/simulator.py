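"""Spiking-network simulation of one sniff trial.

Every cell is an Izhikevich quadratic integrate-and-fire unit

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u),        if v >= 30 mV: spike, v <- c, u <- u + d

advanced by forward Euler at dt = 1 ms with the voltage updated in two half
steps (the standard scheme for this neuron model).  Each presynaptic spike
makes the matching synaptic-input accumulator of its targets jump by the
synaptic weight; accumulators decay exponentially with a 10-ms time constant.
MT -> GC excitation is delivered after a per-synapse latency, implemented with
a ring buffer; all other projections are delivered on the next step.

Input currents are kept in separate per-source accumulators (bulb cells:
MT excitation, GC inhibition, glomerular drive, cortical feedback, noise;
cortex cells: bulb input, PC excitation, local inhibition, noise) so that each
source class can be inspected and gated independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ConfigError, SimulationDivergence
from .network import NetworkWeights, draw_izhikevich_params
from .odors import Odor, OdorPanel, OsnParams, osn_drive

logger = logging.getLogger("olfdrift")

__all__ = [
    "SimConfig",
    "SpikeRaster",
    "Simulator",
    "izhikevich_step",
    "draw_all_params",
    "run_trial",
    "run_session",
    "rasters_to_csv",
]

POPS = ("mt", "gc", "pc", "ffi", "fbi")

# channel rows of the accumulator matrix
CH_MC_EX, CH_GC_IN, CH_FB, CH_MOB, CH_PC_EX, CH_IN = range(6)
N_CHANNELS = 6

#: (channel, delayed) for each projection block.
_PROJ_CHANNEL = {
    "mc2mc": (CH_MC_EX, False),
    "mc2gc": (CH_MC_EX, True),
    "mc2pc": (CH_MOB, False),
    "mc2ffi": (CH_MOB, False),
    "gc2mc": (CH_GC_IN, False),
    "gc2gc": (CH_GC_IN, False),
    "pc2pc": (CH_PC_EX, False),
    "pc2fbi": (CH_PC_EX, False),
    "pc2gc": (CH_FB, False),
    "ffi2pc": (CH_IN, False),
    "ffi2ffi": (CH_IN, False),
    "fbi2pc": (CH_IN, False),
    "fbi2fbi": (CH_IN, False),
}


@dataclass(frozen=True)
class SimConfig:
    """Integration and noise settings for one trial."""

    dt_ms: float = 1.0
    n_substeps: int = 2
    trial_ms: float = 250.0
    syn_tau_ms: float = 10.0
    noise_sigma: dict = field(default_factory=lambda: {
        "mt": 1.75, "gc": 0.8, "pc": 0.9, "ffi": 0.0, "fbi": 0.0,
    })
    osn: OsnParams = field(default_factory=OsnParams)
    feedback_on: bool = True
    engine: str = "auto"   # "auto" (numba when importable), "numba", "numpy"

    def __post_init__(self):
        if self.dt_ms <= 0 or self.syn_tau_ms <= 0:
            raise ConfigError("dt_ms and syn_tau_ms must be positive")
        if self.n_substeps < 1:
            raise ConfigError("n_substeps must be >= 1")

    @property
    def n_steps(self) -> int:
        """Samples at t = 0 .. trial_ms inclusive (251 at defaults)."""
        return int(round(self.trial_ms / self.dt_ms)) + 1


@dataclass
class SpikeRaster:
    """Spike times of every cell in one trial.

    Stored as flat parallel arrays (cell index, time in ms), sorted by time.
    ``pop_slices`` gives the global index range of each population; ``key``
    carries (day, odor, trial) labels when produced inside an experiment.
    """

    cells: np.ndarray
    times_ms: np.ndarray
    n_cells: int
    pop_slices: dict[str, slice]
    trial_ms: float
    key: dict = field(default_factory=dict)

    def spike_times(self, cell: int) -> np.ndarray:
        return self.times_ms[self.cells == cell]

    def counts(self, pop: str | None = None, dt_ms: float = 1.0) -> np.ndarray:
        """(n_cells x n_samples) spike-count matrix on the trial grid."""
        n_steps = int(round(self.trial_ms / dt_ms)) + 1
        if pop is None:
            sel = slice(0, self.n_cells)
        else:
            sel = self.pop_slices[pop]
        mask = (self.cells >= sel.start) & (self.cells < sel.stop)
        out = np.zeros((sel.stop - sel.start, n_steps), dtype=np.uint16)
        steps = np.round(self.times_ms[mask] / dt_ms).astype(np.int64)
        np.add.at(out, (self.cells[mask] - sel.start, steps), 1)
        return out

    def n_spikes(self, pop: str | None = None) -> int:
        if pop is None:
            return len(self.cells)
        sel = self.pop_slices[pop]
        return int(((self.cells >= sel.start) & (self.cells < sel.stop)).sum())


def izhikevich_step(v, u, I, a, b, c, d, dt: float = 1.0, n_substeps: int = 2):
    """One Euler step of the neuron model; returns (v, u, fired).

    The voltage is advanced in ``n_substeps`` sub-steps; the recovery variable
    takes a single step using the pre-step voltage.  Cells crossing 30 mV are
    flagged fired and reset (v <- c, u <- u + d).
    """
    v = np.asarray(v, dtype=float).copy()
    u = np.asarray(u, dtype=float).copy()
    v0 = v.copy()
    h = dt / n_substeps
    for _ in range(n_substeps):
        v += h * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
    u += dt * np.asarray(a) * (np.asarray(b) * v0 - u)
    fired = v >= 30.0
    if fired.any():
        v = np.where(fired, c, v)
        u = np.where(fired, u + np.asarray(d), u)
    return v, u, fired


def draw_all_params(spec, rng: np.random.Generator) -> dict:
    """Izhikevich parameters for every population of a PopulationSpec."""
    return {
        "mt": draw_izhikevich_params("MT", spec.n_mt, rng),
        "gc": draw_izhikevich_params("GC", spec.n_gc, rng),
        "pc": draw_izhikevich_params("PC", spec.n_pc, rng),
        "ffi": draw_izhikevich_params("FFI_FBI", spec.n_ffi, rng),
        "fbi": draw_izhikevich_params("FFI_FBI", spec.n_fbi, rng),
    }


def _ranges(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenation of arange(s, s+c) for each (s, c) pair, vectorised."""
    n = int(counts.sum())
    if n == 0:
        return np.empty(0, dtype=np.int64)
    shift = np.concatenate(([0], np.cumsum(counts)[:-1]))
    return np.arange(n, dtype=np.int64) + np.repeat(starts - shift, counts)



# ---------------------------------------------------------------------------
# compiled stepping core (optional; the numpy path below is the reference)
# ---------------------------------------------------------------------------

_NUMBA_CORE = None


def _get_numba_core():
    """Build (once) the numba-compiled trial loop; None if numba is absent."""
    global _NUMBA_CORE
    if _NUMBA_CORE is not None:
        return _NUMBA_CORE
    try:
        import numba
    except ImportError:          # pragma: no cover - numba is an optional dep
        return None

    @numba.njit(cache=True, fastmath=False)
    def core(n_steps, n, n_mt, n_gc, gc_off, a, b, c, d, v, u, C_flat, noise,
             drive, has_drive, m_indptr, m_targets, m_data,
             d_indptr, d_posts, d_data, d_steps,
             decay, L, n_substeps, h, dt,
             out_cells, out_steps):
        buf = np.zeros(L * n_gc)
        fired_idx = np.empty(n, dtype=np.int64)
        n2, n3, n4, n5 = 2 * n, 3 * n, 4 * n, 5 * n
        ns = 0
        for t in range(n_steps):
            nf = 0
            for i in range(n):
                I = (C_flat[i] + C_flat[n + i] + C_flat[n2 + i]
                     + C_flat[n3 + i] + C_flat[n4 + i] + C_flat[n5 + i]
                     + noise[t, i])
                if has_drive and i < n_mt:
                    I += drive[t, i]
                vi = v[i]
                v0 = vi
                ui = u[i]
                for _ in range(n_substeps):
                    vi = vi + h * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + I)
                u[i] = ui + dt * a[i] * (b[i] * v0 - ui)
                if not np.isfinite(vi):
                    return -1, i, t
                C_flat[i] *= decay
                C_flat[n + i] *= decay
                C_flat[n2 + i] *= decay
                C_flat[n3 + i] *= decay
                C_flat[n4 + i] *= decay
                C_flat[n5 + i] *= decay
                if vi >= 30.0:
                    fired_idx[nf] = i
                    nf += 1
                    v[i] = c[i]
                    u[i] += d[i]
                else:
                    v[i] = vi
            for s in range(nf):
                i = fired_idx[s]
                out_cells[ns] = i
                out_steps[ns] = t
                ns += 1
                for k in range(m_indptr[i], m_indptr[i + 1]):
                    C_flat[m_targets[k]] += m_data[k]
                if i < n_mt:
                    base_t = t
                    for k in range(d_indptr[i], d_indptr[i + 1]):
                        buf[((base_t + d_steps[k]) % L) * n_gc + d_posts[k]] += d_data[k]
            base = ((t + 1) % L) * n_gc
            off = gc_off
            for j in range(n_gc):
                C_flat[off + j] += buf[base + j]
                buf[base + j] = 0.0
        return ns, 0, 0

    _NUMBA_CORE = core
    return core


class Simulator:
    """Advances one network through sniff trials.

    All undelayed projections are merged into one flat delivery table
    (presynaptic cell -> flattened (channel, post) targets); the delayed
    MT -> GC projection has its own table feeding a ring buffer.  Call
    :meth:`rebuild` after a sparsity-pattern change (neurogenesis) and
    :meth:`sync_weights` after value-only changes (STDP).
    """

    def __init__(self, net: NetworkWeights, params: dict, config: SimConfig | None = None):
        self.net = net
        self.config = config or SimConfig()
        spec = net.spec
        counts = [spec.n_mt, spec.n_gc, spec.n_pc, spec.n_ffi, spec.n_fbi]
        offs = np.concatenate([[0], np.cumsum(counts)])
        self.n_total = int(offs[-1])
        self.pop_slices = {p: slice(int(offs[i]), int(offs[i + 1]))
                           for i, p in enumerate(POPS)}
        self._offset = {p: int(offs[i]) for i, p in enumerate(POPS)}

        for p in POPS:
            need = counts[POPS.index(p)]
            if len(params[p].a) != need:
                raise ConfigError(f"params[{p!r}] has {len(params[p].a)} cells, spec needs {need}")
        self.a = np.concatenate([params[p].a for p in POPS])
        self.b = np.concatenate([params[p].b for p in POPS])
        self.c = np.concatenate([params[p].c for p in POPS])
        self.d = np.concatenate([params[p].d for p in POPS])
        self.sigma = np.concatenate([
            np.full(counts[i], self.config.noise_sigma.get(p, 0.0))
            for i, p in enumerate(POPS)
        ])
        self._sigma32 = self.sigma.astype(np.float32)
        self._feedback = bool(net.feedback_on and self.config.feedback_on)
        self.rebuild()

    # ------------------------------------------------------------------
    def rebuild(self, blocks=None) -> None:
        """Rebuild the combined delivery tables from the network blocks.

        The ``blocks`` argument is accepted for API symmetry; any pattern
        change triggers a full rebuild (cheap relative to a day of trials).
        """
        from .network import BLOCK_SHAPES
        n = self.n_total
        pre_list, tgt_list, val_list = [], [], []
        srcs = []
        total = 0
        self._maps: dict[str, tuple[bool, np.ndarray]] = {}
        for name, (channel, delayed) in _PROJ_CHANNEL.items():
            if name == "pc2gc" and not self._feedback:
                continue
            block = self.net.blocks[name]
            if delayed:
                continue
            post_pop, pre_pop = BLOCK_SHAPES[name]
            coo = block.tocoo()       # same data order as the CSR block
            pre_list.append(coo.col.astype(np.int64) + self._offset[pre_pop])
            tgt_list.append(channel * n + coo.row.astype(np.int64)
                            + self._offset[post_pop])
            val_list.append(coo.data)
            srcs.append((name, total, block.nnz))
            total += block.nnz
        pre = np.concatenate(pre_list) if pre_list else np.empty(0, np.int64)
        tgt = np.concatenate(tgt_list) if tgt_list else np.empty(0, np.int64)
        val = np.concatenate(val_list) if val_list else np.empty(0)
        order = np.argsort(pre, kind="stable")
        self._m_targets = tgt[order].astype(np.int32)
        self._m_data = val[order].astype(np.float32)
        cnt = np.bincount(pre, minlength=n)
        self._m_indptr = np.concatenate(([0], np.cumsum(cnt))).astype(np.int64)
        inv = np.empty(total, dtype=np.int64)
        inv[order] = np.arange(total)
        for name, s0, nnz in srcs:
            self._maps[name] = (False, inv[s0:s0 + nnz])

        # delayed MT -> GC table (ring-buffer targets in local GC indices)
        block = self.net.blocks["mc2gc"]
        coo = block.tocoo()
        steps = np.maximum(
            np.round(self.net.delays_mt_gc.tocoo().data / self.config.dt_ms)
            .astype(np.int64), 1)
        order = np.argsort(coo.col, kind="stable")
        self._d_posts = coo.row.astype(np.int32)[order]
        self._d_data = coo.data[order].astype(np.float32)
        self._d_steps = steps[order]
        cnt = np.bincount(coo.col, minlength=block.shape[1])
        self._d_indptr = np.concatenate(([0], np.cumsum(cnt))).astype(np.int64)
        inv = np.empty(block.nnz, dtype=np.int64)
        inv[order] = np.arange(block.nnz)
        self._maps["mc2gc"] = (True, inv)
        self._max_delay = int(self._d_steps.max()) if len(self._d_steps) else 1

    # ------------------------------------------------------------------
    def sync_weights(self, changed: dict[str, np.ndarray]) -> None:
        """Propagate value-only weight changes into the delivery tables.

        ``changed`` maps block names to CSR-data positions whose values were
        modified (pattern unchanged)."""
        for name, pos in changed.items():
            if name not in self._maps:
                continue
            delayed, comb = self._maps[name]
            data = self.net.blocks[name].data
            if delayed:
                self._d_data[comb[pos]] = data[pos].astype(np.float32)
            else:
                self._m_data[comb[pos]] = data[pos].astype(np.float32)

    # ------------------------------------------------------------------
    def _deliver(self, spike_idx, t, C_flat, buf_flat, L, n_gc):
        """Land the synaptic jumps caused by the cells spiking at step t."""
        starts = self._m_indptr[spike_idx]
        cnts = self._m_indptr[spike_idx + 1] - starts
        sel = _ranges(starts, cnts)
        if len(sel):
            tg = self._m_targets[sel]
            vals = self._m_data[sel]
            if len(tg) > 1024:
                C_flat += np.bincount(tg, weights=vals, minlength=len(C_flat))
            else:
                np.add.at(C_flat, tg, vals)
        n_mt = self._offset["gc"]
        hi = np.searchsorted(spike_idx, n_mt)
        if hi:
            mts = spike_idx[:hi]
            starts = self._d_indptr[mts]
            cnts = self._d_indptr[mts + 1] - starts
            sel = _ranges(starts, cnts)
            if len(sel):
                flat = ((t + self._d_steps[sel]) % L) * n_gc + self._d_posts[sel]
                if len(flat) > 1024:
                    buf_flat += np.bincount(flat, weights=self._d_data[sel],
                                            minlength=len(buf_flat))
                else:
                    np.add.at(buf_flat, flat, self._d_data[sel])

    # ------------------------------------------------------------------
    def run_trial(
        self,
        odor: Odor | None,
        rng: np.random.Generator | int | None = None,
        key: dict | None = None,
    ) -> SpikeRaster:
        """Simulate one 250-ms sniff; returns the spike raster of all cells."""
        cfg = self.config
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        n = self.n_total
        n_steps = cfg.n_steps
        dt = cfg.dt_ms
        mt_sl = self.pop_slices["mt"]
        gc_sl = self.pop_slices["gc"]
        n_gc = gc_sl.stop - gc_sl.start

        v = self.c.copy()
        u = self.b * v
        C = np.zeros((N_CHANNELS, n))
        C_flat = C.reshape(-1)
        gc_ex_lo = CH_MC_EX * n + gc_sl.start
        decay = np.exp(-dt / cfg.syn_tau_ms)
        L = self._max_delay + 2
        buf_flat = np.zeros(L * n_gc)

        noise = rng.standard_normal((n_steps, n), dtype=np.float32)
        noise *= self._sigma32
        if odor is not None:
            drive = osn_drive(odor, self.net.spec.glomerulus_of_mt, n_steps, dt,
                              rng, cfg.osn)
        else:
            drive = None

        h = dt / cfg.n_substeps
        a_, b_, c_, d_ = self.a, self.b, self.c, self.d

        core = _get_numba_core() if cfg.engine in ("auto", "numba") else None
        if cfg.engine == "numba" and core is None:
            raise ConfigError("engine='numba' requested but numba is not importable")
        if core is not None:
            cap = n_steps * n
            if getattr(self, "_out_cells", None) is None or len(self._out_cells) < cap:
                self._out_cells = np.empty(cap, dtype=np.int64)
                self._out_steps = np.empty(cap, dtype=np.int64)
            dr = drive if drive is not None else np.zeros((1, 1))
            ns, ei, et = core(
                n_steps, n, mt_sl.stop, n_gc, gc_sl.start,
                a_, b_, c_, d_, v, u, C_flat, noise, dr, drive is not None,
                self._m_indptr, self._m_targets, self._m_data,
                self._d_indptr, self._d_posts, self._d_data, self._d_steps,
                decay, L, cfg.n_substeps, h, dt,
                self._out_cells, self._out_steps,
            )
            if ns < 0:
                raise SimulationDivergence(ei, et * dt)
            return SpikeRaster(
                cells=self._out_cells[:ns].copy(),
                times_ms=self._out_steps[:ns].astype(float) * dt,
                n_cells=n, pop_slices=dict(self.pop_slices),
                trial_ms=cfg.trial_ms, key=dict(key or {}),
            )

        spike_cells: list[np.ndarray] = []
        spike_steps: list[np.ndarray] = []
        for t in range(n_steps):
            I = C.sum(axis=0)
            I += noise[t]
            if drive is not None:
                I[mt_sl] += drive[t]
            v0 = v
            vt = v
            for _ in range(cfg.n_substeps):
                vt = vt + h * (0.04 * vt * vt + 5.0 * vt + 140.0 - u + I)
            v = vt
            u = u + dt * a_ * (b_ * v0 - u)
            if not np.all(np.isfinite(v)):
                bad = int(np.flatnonzero(~np.isfinite(v))[0])
                raise SimulationDivergence(bad, t * dt)
            fired = v >= 30.0
            # decay all accumulators, then land this step's (and queued) jumps
            C *= decay
            if fired.any():
                idx = np.flatnonzero(fired)
                spike_cells.append(idx)
                spike_steps.append(np.full(len(idx), t, dtype=np.int64))
                v[idx] = c_[idx]
                u[idx] += d_[idx]
                self._deliver(idx, t, C_flat, buf_flat, L, n_gc)
            nxt = (t + 1) % L
            C_flat[gc_ex_lo:gc_ex_lo + n_gc] += buf_flat[nxt * n_gc:(nxt + 1) * n_gc]
            buf_flat[nxt * n_gc:(nxt + 1) * n_gc] = 0.0

        cells = np.concatenate(spike_cells) if spike_cells else np.empty(0, dtype=np.int64)
        steps = np.concatenate(spike_steps) if spike_steps else np.empty(0, dtype=np.int64)
        return SpikeRaster(
            cells=cells, times_ms=steps * dt, n_cells=n,
            pop_slices=dict(self.pop_slices), trial_ms=cfg.trial_ms,
            key=dict(key or {}),
        )


def run_trial(net, params, odor, config=None, rng=None, key=None) -> SpikeRaster:
    """Convenience wrapper: build a Simulator and run one trial."""
    return Simulator(net, params, config).run_trial(odor, rng, key=key)


def run_session(
    net: NetworkWeights,
    params: dict,
    panel: OdorPanel,
    n_trials: int,
    config: SimConfig | None = None,
    rng: np.random.Generator | int | None = None,
    day: int = 0,
) -> dict[tuple[int, int], SpikeRaster]:
    """All (odor, trial) rasters for one recording session on a fixed network."""
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    seq = np.random.SeedSequence(rng if isinstance(rng, (int, np.integer)) or rng is None
                                 else rng.integers(2**31))
    children = seq.spawn(len(panel) * n_trials)
    sim = Simulator(net, params, config)
    out = {}
    k = 0
    for oi in range(len(panel)):
        for tr in range(n_trials):
            r = sim.run_trial(panel[oi], np.random.default_rng(children[k]),
                              key={"day": day, "odor": oi, "trial": tr})
            out[(oi, tr)] = r
            k += 1
            logger.debug("trial day=%d odor=%d trial=%d spikes=%d",
                         day, oi, tr, len(r.cells))
        logger.info("session day=%d odor=%d done (%d trials, %d spikes)",
                    day, oi, n_trials,
                    sum(len(out[(oi, t)].cells) for t in range(n_trials)))
    return out


def rasters_to_csv(rasters, path) -> None:
    """Write a raster collection as one flat CSV.

    Columns: cell_id, population, day, odor, trial, spike_time_ms.
    ``rasters`` maps (odor, trial) keys (or any keys) to SpikeRaster objects
    whose ``key`` dicts carry day/odor/trial labels.
    """
    import pandas as pd

    frames = []
    for r in rasters.values():
        pop = np.empty(len(r.cells), dtype=object)
        for name, sl in r.pop_slices.items():
            pop[(r.cells >= sl.start) & (r.cells < sl.stop)] = name
        frames.append(pd.DataFrame({
            "cell_id": r.cells,
            "population": pop,
            "day": r.key.get("day", 0),
            "odor": r.key.get("odor", -1),
            "trial": r.key.get("trial", -1),
            "spike_time_ms": r.times_ms,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
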