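"""Construction of the olfactory-bulb / piriform-cortex network.

The circuit has five cell populations: mitral/tufted cells (MT) grouped under
glomeruli, granule cells (GC) forming reciprocal dendro-dendritic synapses with
MT cells, piriform principal cells (PC), and feedforward / feedback inhibitory
interneurons (FFI / FBI) in cortex.  Connectivity is organised as 13 directed
projection blocks, each defined by a connection density and the mean of the
uniform distribution from which nonzero weights are drawn.

Weights are stored per projection as ``scipy.sparse`` CSR matrices with the
convention ``W[i, j]`` = strength from presynaptic cell ``j`` to postsynaptic
cell ``i``.  The classic macro-blocks (bulb-internal, feedforward, cortical,
and centrifugal feedback) are assembled on demand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from ._exceptions import ConfigError, ZeroVarianceError

__all__ = [
    "PopulationSpec",
    "IzhikevichParams",
    "ConnectivityRule",
    "TABLE_RULES",
    "NetworkWeights",
    "draw_izhikevich_params",
    "build_weight_block",
    "build_network",
    "weight_dissimilarity",
    "reciprocal_partner_count",
    "pc_projection_count",
    "save_network",
    "load_network",
]

# Projections whose weights are redrawn when a granule cell is replaced by an
# adult-born one, and which are eligible for STDP.
GC_BLOCKS = ("mc2gc", "gc2mc", "gc2gc", "pc2gc")

BLOCK_NAMES = (
    "mc2mc", "mc2gc", "gc2mc", "gc2gc",
    "mc2pc", "mc2ffi",
    "pc2pc", "ffi2pc", "fbi2pc", "ffi2ffi", "pc2fbi", "fbi2fbi",
    "pc2gc",
)

# (postsynaptic population, presynaptic population) per block.
BLOCK_SHAPES = {
    "mc2mc": ("mt", "mt"),
    "mc2gc": ("gc", "mt"),
    "gc2mc": ("mt", "gc"),
    "gc2gc": ("gc", "gc"),
    "mc2pc": ("pc", "mt"),
    "mc2ffi": ("ffi", "mt"),
    "pc2pc": ("pc", "pc"),
    "ffi2pc": ("pc", "ffi"),
    "fbi2pc": ("pc", "fbi"),
    "ffi2ffi": ("ffi", "ffi"),
    "pc2fbi": ("fbi", "pc"),
    "fbi2fbi": ("fbi", "fbi"),
    "pc2gc": ("gc", "pc"),
}


@dataclass(frozen=True)
class PopulationSpec:
    """Cell counts of the model.

    ``n_mt`` is derived: every glomerulus drives ``mt_per_glomerulus`` MT cells.
    """

    n_glomeruli: int = 50
    mt_per_glomerulus: int = 25
    n_gc: int = 12500
    n_pc: int = 10000
    n_ffi: int = 1250
    n_fbi: int = 1250
    scale_factor: float = 1.0

    def __post_init__(self):
        for name in ("n_glomeruli", "mt_per_glomerulus", "n_gc", "n_pc", "n_ffi", "n_fbi"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.scale_factor <= 0:
            raise ConfigError("scale_factor must be positive")

    @property
    def n_mt(self) -> int:
        return self.n_glomeruli * self.mt_per_glomerulus

    def counts(self) -> dict[str, int]:
        return {
            "mt": self.n_mt,
            "gc": self.n_gc,
            "pc": self.n_pc,
            "ffi": self.n_ffi,
            "fbi": self.n_fbi,
        }

    @property
    def glomerulus_of_mt(self) -> np.ndarray:
        """Glomerulus index of each MT cell (contiguous groups)."""
        return np.repeat(np.arange(self.n_glomeruli), self.mt_per_glomerulus)

    def scaled(self, factor: float) -> "PopulationSpec":
        """Uniformly shrink every population (used by mini presets)."""
        def s(x: int) -> int:
            return max(1, round(x * factor))

        return PopulationSpec(
            n_glomeruli=s(self.n_glomeruli),
            mt_per_glomerulus=self.mt_per_glomerulus,
            n_gc=s(self.n_gc),
            n_pc=s(self.n_pc),
            n_ffi=s(self.n_ffi),
            n_fbi=s(self.n_fbi),
            scale_factor=self.scale_factor * factor,
        )


MINI_SPEC = PopulationSpec(
    n_glomeruli=10, mt_per_glomerulus=10, n_gc=1000, n_pc=800,
    n_ffi=100, n_fbi=100, scale_factor=0.1,
)


@dataclass
class IzhikevichParams:
    """Per-cell quadratic integrate-and-fire parameters.

    ``a`` controls recovery speed, ``b`` recovery sensitivity, ``c`` the reset
    voltage (mV), ``d`` the after-spike recovery jump.  ``r`` is the uniform
    [0, 1] draw used to heterogenise each cell.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    r: np.ndarray


_CELL_TYPES = ("MT", "GC", "PC", "FFI_FBI")


def draw_izhikevich_params(cell_type: str, n: int, rng: np.random.Generator) -> IzhikevichParams:
    """Draw per-cell neuron parameters for one population.

    MT cells span regular-spiking to bursting/chattering regimes (r**4 bias),
    PCs span regular-spiking to chattering (linear in r), and the inhibitory
    populations (GC, FFI/FBI) span fast-spiking to low-threshold-spiking
    regimes (r**2 bias).
    """
    if cell_type not in _CELL_TYPES:
        raise ConfigError(f"unknown cell_type {cell_type!r}; expected one of {_CELL_TYPES}")
    if n < 1:
        raise ConfigError("n must be >= 1")
    r = rng.uniform(0.0, 1.0, size=n)
    b = np.full(n, 0.2)
    if cell_type == "MT":
        a = 0.1 - 0.08 * r**4
        c = np.full(n, -65.0)
        d = 2.0 + 6.0 * r**4
    elif cell_type == "PC":
        a = 0.02 + 0.08 * r
        c = np.full(n, -65.0)
        d = 8.0 - 6.0 * r
    else:  # GC, FFI_FBI share the inhibitory parameterisation
        a = 0.1 - 0.08 * r**2
        c = -65.0 + 15.0 * r**2
        d = np.full(n, 2.0)
    return IzhikevichParams(a=a, b=b, c=c, d=d, r=r)


@dataclass(frozen=True)
class ConnectivityRule:
    """Density and mean strength of one projection block.

    Nonzero weights are drawn uniformly on ``[0, 2*|mean_strength|]`` (which
    preserves the stated mean) and signed according to ``sign``.  A magnitude
    range can override the default support (used for the weak, dense
    cortical feedback block).
    """

    density: float
    mean_strength: float
    magnitude_range: tuple[float, float] | None = None

    def __post_init__(self):
        if not (0.0 <= self.density <= 1.0):
            raise ConfigError(f"density must be in [0, 1], got {self.density}")
        if self.magnitude_range is not None:
            lo, hi = self.magnitude_range
            if not (0.0 <= lo <= hi):
                raise ConfigError("magnitude_range must satisfy 0 <= lo <= hi")

    @property
    def sign(self) -> float:
        return float(np.sign(self.mean_strength))

    def draw_magnitudes(self, k: int, rng: np.random.Generator) -> np.ndarray:
        if self.magnitude_range is not None:
            lo, hi = self.magnitude_range
        else:
            lo, hi = 0.0, 2.0 * abs(self.mean_strength)
        return rng.uniform(lo, hi, size=k)


#: Connection density and mean strength per projection.  The same-glomerulus
#: restriction on MT->MT and the glomerulus-crossing structure of PC->GC are
#: applied by :func:`build_network`, not encoded here.
TABLE_RULES: dict[str, ConnectivityRule] = {
    "mc2mc": ConnectivityRule(0.8, 0.25),       # within one glomerulus only
    "mc2gc": ConnectivityRule(0.3, 0.25),
    "gc2mc": ConnectivityRule(0.02, -0.4),
    "gc2gc": ConnectivityRule(0.05, -0.1),      # lateral GC/SAC inhibition
    "mc2pc": ConnectivityRule(0.5, 0.06),
    "mc2ffi": ConnectivityRule(0.2, 0.2),
    "pc2gc": ConnectivityRule(0.9, 0.03, magnitude_range=(0.01, 0.05)),
    "pc2pc": ConnectivityRule(0.01, 0.1),
    "ffi2pc": ConnectivityRule(0.1, -0.1),
    "fbi2pc": ConnectivityRule(0.8, -0.1),
    "ffi2ffi": ConnectivityRule(0.01, -1.0),
    "pc2fbi": ConnectivityRule(0.02, 0.3),
    "fbi2fbi": ConnectivityRule(0.02, -0.5),
}

#: MT->GC dendro-dendritic delivery latencies are drawn uniformly on this
#: range (ms); the distribution itself is a modelling choice.
DELAY_RANGE_MS = (0.0, 25.0)


def scaled_rules(
    spec: PopulationSpec,
    base_spec: PopulationSpec | None = None,
    rules: dict[str, ConnectivityRule] | None = None,
) -> dict[str, ConnectivityRule]:
    """Connectivity rules rescaled for a shrunken network.

    Shrinking every population while keeping the per-projection densities and
    strengths starves each cell of synaptic drive (its expected in-degree
    falls with the presynaptic pool).  To keep the operating point of the
    full-scale model, the total connection weight expected per postsynaptic
    cell (density x pool x mean strength) is held fixed: the density is
    raised first, up to 1, which preserves the in-degree — and with it both
    the mean and the variance of the summed input — and any remaining factor
    goes into the mean strength (and magnitude range, if any).  For the
    within-glomerulus MT->MT block the relevant pool is the per-glomerulus MT
    count.

    The granule-cell *output* blocks (GC -> MT and GC <-> GC,
    ``granular_blocks``) are the exception: they keep their full-scale
    *density* and scale the strength instead.  Rationale: what the drift
    mechanism feels is the number of co-active inhibitory partners per
    target cell.  At full scale each MT cell draws on ~250 granule cells of
    which only a few percent respond to any one odor; keeping the density
    (tens of partners at mini scale, about half odor-responsive) preserves
    that effective granularity, whereas raising the density would average
    the reshuffled inhibition into invisibility.  Input blocks *onto* GCs
    stay degree-first so that which GCs respond to an odor is decided by
    full-scale input statistics.  At full scale this whole function is the
    identity.
    """
    base = PopulationSpec() if base_spec is None else base_spec
    rules = dict(TABLE_RULES if rules is None else rules)
    counts, base_counts = spec.counts(), base.counts()
    granular_blocks = ("gc2mc", "gc2gc")
    out = {}
    for name, rule in rules.items():
        if name == "mc2mc":
            f = base.mt_per_glomerulus / spec.mt_per_glomerulus
        else:
            _, pre = BLOCK_SHAPES[name]
            f = base_counts[pre] / counts[pre]
        if name in granular_blocks:
            new_density = rule.density
        else:
            new_density = min(1.0, rule.density * f)
        f_strength = f * rule.density / new_density if rule.density > 0 else 1.0
        mag = rule.magnitude_range
        out[name] = ConnectivityRule(
            density=new_density,
            mean_strength=rule.mean_strength * f_strength,
            magnitude_range=None if mag is None else
                (mag[0] * f_strength, mag[1] * f_strength),
        )
    return out


def _random_rows(n_post, n_pre, rule, rng, allowed=None):
    """COO triplets for independent-Bernoulli rows.

    ``allowed``: optional callable row -> candidate column array.
    """
    rows, cols = [], []
    for i in range(n_post):
        cand = allowed(i) if allowed is not None else None
        m = n_pre if cand is None else len(cand)
        if m == 0:
            continue
        k = rng.binomial(m, rule.density)
        if k == 0:
            continue
        pick = rng.choice(m, size=k, replace=False)
        rows.append(np.full(k, i, dtype=np.int64))
        cols.append(pick if cand is None else cand[pick])
    if not rows:
        return (np.empty(0, dtype=np.int64),) * 2
    return np.concatenate(rows), np.concatenate(cols)


def build_weight_block(
    n_post: int,
    n_pre: int,
    rule: ConnectivityRule,
    rng: np.random.Generator,
    allowed=None,
) -> sp.csr_matrix:
    """Sample one projection block.

    Each ordered (post, pre) pair is connected independently with probability
    ``rule.density``; nonzero magnitudes come from ``rule.draw_magnitudes``.
    """
    rows, cols = _random_rows(n_post, n_pre, rule, rng, allowed=allowed)
    vals = rule.sign * rule.draw_magnitudes(len(rows), rng)
    out = sp.csr_matrix((vals, (rows, cols)), shape=(n_post, n_pre))
    out.sum_duplicates()
    return out


@dataclass
class NetworkWeights:
    """All synaptic weights of one network instance.

    ``blocks`` maps projection names to CSR matrices (post x pre).
    ``delays_mt_gc`` shares the MT->GC sparsity pattern; its data are delivery
    latencies in ms.  When ``feedback_on`` is False the centrifugal PC->GC
    block is identically zero.
    """

    spec: PopulationSpec
    blocks: dict[str, sp.csr_matrix]
    delays_mt_gc: sp.csr_matrix
    feedback_on: bool = True
    build_seed: int | None = None
    meta: dict = field(default_factory=dict)

    # -- macro-block views ---------------------------------------------------
    @property
    def W_mob(self) -> sp.csr_matrix:
        """Bulb-internal weights, cell order [MT, GC]."""
        b = self.blocks
        return sp.bmat(
            [[b["mc2mc"], b["gc2mc"]], [b["mc2gc"], b["gc2gc"]]], format="csr"
        )

    @property
    def W_ff(self) -> sp.csr_matrix:
        """Feedforward bulb-to-cortex weights, target order [PC, FFI]."""
        return sp.vstack([self.blocks["mc2pc"], self.blocks["mc2ffi"]], format="csr")

    @property
    def W_pcx(self) -> sp.csr_matrix:
        """Cortex-internal weights, cell order [PC, FFI, FBI]."""
        b = self.blocks
        n_pc, n_ffi, n_fbi = self.spec.n_pc, self.spec.n_ffi, self.spec.n_fbi
        z = lambda r, c: sp.csr_matrix((r, c))
        return sp.bmat(
            [
                [b["pc2pc"], b["ffi2pc"], b["fbi2pc"]],
                [z(n_ffi, n_pc), b["ffi2ffi"], z(n_ffi, n_fbi)],
                [b["pc2fbi"], z(n_fbi, n_ffi), b["fbi2fbi"]],
            ],
            format="csr",
        )

    @property
    def W_fb(self) -> sp.csr_matrix:
        """Centrifugal PC -> GC feedback weights (zero when feedback is off)."""
        if not self.feedback_on:
            return sp.csr_matrix((self.spec.n_gc, self.spec.n_pc))
        return self.blocks["pc2gc"]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            spec=self.spec,
            blocks={k: v.copy() for k, v in self.blocks.items()},
            delays_mt_gc=self.delays_mt_gc.copy(),
            feedback_on=self.feedback_on,
            build_seed=self.build_seed,
            meta=dict(self.meta),
        )


def _pc_source_glomerulus(mc2pc: sp.csr_matrix, glom_of_mt: np.ndarray, n_glom: int) -> np.ndarray:
    """Dominant input glomerulus of each PC (largest summed feedforward weight)."""
    onehot = sp.csr_matrix(
        (np.ones(len(glom_of_mt)), (np.arange(len(glom_of_mt)), glom_of_mt)),
        shape=(len(glom_of_mt), n_glom),
    )
    per_glom = np.asarray((mc2pc @ onehot).todense())
    return np.asarray(per_glom.argmax(axis=1)).ravel()


def _gc_reciprocal_glomeruli(
    mc2gc: sp.csr_matrix, gc2mc: sp.csr_matrix, glom_of_mt: np.ndarray, n_glom: int
) -> np.ndarray:
    """Boolean (n_gc x n_glom): does GC g reciprocally pair with any MT of glomerulus G?"""
    recip = mc2gc.astype(bool).multiply(gc2mc.T.astype(bool))  # (n_gc x n_mt)
    onehot = sp.csr_matrix(
        (np.ones(len(glom_of_mt)), (np.arange(len(glom_of_mt)), glom_of_mt)),
        shape=(len(glom_of_mt), n_glom),
    )
    return np.asarray((recip @ onehot).todense()) > 0


def build_feedback_rows(
    gc_rows: np.ndarray,
    net_or_parts,
    rule: ConnectivityRule,
    rng: np.random.Generator,
) -> sp.csr_matrix:
    """Build PC->GC feedback rows for the given GCs.

    Structure: PCs whose dominant feedforward drive comes from one glomerulus
    project to GCs reciprocally connected with MT cells of *other* glomeruli.
    Weights are dense (high density) but weak (magnitudes < 0.05).

    ``net_or_parts`` is a dict with keys ``mc2gc``, ``gc2mc``, ``mc2pc``,
    ``glom_of_mt``, ``n_glom``, ``n_pc``, ``n_gc``.
    """
    p = net_or_parts
    src = _pc_source_glomerulus(p["mc2pc"], p["glom_of_mt"], p["n_glom"])
    recip = _gc_reciprocal_glomeruli(p["mc2gc"], p["gc2mc"], p["glom_of_mt"], p["n_glom"])
    pcs_by_glom = [np.flatnonzero(src == g) for g in range(p["n_glom"])]

    def allowed(row_idx: int):
        g = gc_rows[row_idx]
        blocked = recip[g]  # glomeruli this GC is reciprocal with
        if not blocked.any():
            return np.arange(p["n_pc"])
        keep = np.flatnonzero(~blocked)
        if len(keep) == 0:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([pcs_by_glom[G] for G in keep])

    rows, cols = _random_rows(len(gc_rows), p["n_pc"], rule, rng, allowed=allowed)
    vals = rule.sign * rule.draw_magnitudes(len(rows), rng)
    sub = sp.csr_matrix((vals, (gc_rows[rows], cols)), shape=(p["n_gc"], p["n_pc"]))
    sub.sum_duplicates()
    return sub


def _build_mc2mc(spec: PopulationSpec, rule: ConnectivityRule, rng) -> sp.csr_matrix:
    """MT->MT coupling exists only between cells of the same glomerulus."""
    glom = spec.glomerulus_of_mt

    def allowed(i: int):
        cand = np.flatnonzero(glom == glom[i])
        return cand[cand != i]  # no autapses

    rows, cols = _random_rows(spec.n_mt, spec.n_mt, rule, rng, allowed=allowed)
    vals = rule.sign * rule.draw_magnitudes(len(rows), rng)
    out = sp.csr_matrix((vals, (rows, cols)), shape=(spec.n_mt, spec.n_mt))
    out.sum_duplicates()
    return out


def draw_delays(pattern: sp.csr_matrix, rng: np.random.Generator) -> sp.csr_matrix:
    """Per-synapse MT->GC delivery latencies on the given sparsity pattern."""
    lo, hi = DELAY_RANGE_MS
    d = pattern.copy()
    d.data = rng.uniform(lo, hi, size=d.nnz)
    return d


def apply_reciprocity_boost(
    mc2gc: sp.csr_matrix,
    gc2mc: sp.csr_matrix,
    boost: float,
    rng: np.random.Generator,
) -> sp.csr_matrix:
    """Resample a fraction of each MT cell's GC inputs from its own GC targets.

    Independent Bernoulli sampling of MT->GC and GC->MC under the tabulated
    densities yields far fewer reciprocal MT/GC pairs than the printed
    diagnostic; ``boost`` in [0, 1] retargets that fraction of each MT cell's
    presynaptic GCs onto GCs the MT cell itself excites, raising reciprocity
    without changing either block's density or weight distribution.
    """
    if boost <= 0:
        return gc2mc
    out = gc2mc.tolil()
    targets_of_mt = mc2gc.tocsc()
    n_mt = gc2mc.shape[0]
    for m in range(n_mt):
        cols = np.asarray(out.rows[m], dtype=np.int64)
        vals = np.asarray(out.data[m], dtype=float)
        if len(cols) == 0:
            continue
        k = int(round(boost * len(cols)))
        if k == 0:
            continue
        pool = targets_of_mt.indices[
            targets_of_mt.indptr[m]: targets_of_mt.indptr[m + 1]
        ]
        pool = np.setdiff1d(pool, cols, assume_unique=False)
        k = min(k, len(pool))
        if k == 0:
            continue
        drop = rng.choice(len(cols), size=k, replace=False)
        new = rng.choice(pool, size=k, replace=False)
        cols[drop] = new
        order = np.argsort(cols)
        out.rows[m] = cols[order].tolist()
        out.data[m] = vals[order].tolist()
    return out.tocsr()


def build_network(
    spec: PopulationSpec,
    rules_table: dict[str, ConnectivityRule] | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    feedback_on: bool = True,
    reciprocity_boost: float = 0.0,
) -> NetworkWeights:
    """Assemble every projection block of a network instance.

    The build is a pure function of (spec, rules, seed).  When ``feedback_on``
    is False the PC->GC block is left as an explicit zero matrix and no
    feedback structure is computed.
    """
    rules = dict(TABLE_RULES if rules_table is None else rules_table)
    missing = set(BLOCK_NAMES) - set(rules)
    if missing:
        raise ConfigError(f"rules_table missing blocks: {sorted(missing)}")
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(rng)

    counts = spec.counts()
    blocks: dict[str, sp.csr_matrix] = {}
    blocks["mc2mc"] = _build_mc2mc(spec, rules["mc2mc"], rng)
    for name in ("mc2gc", "gc2mc", "gc2gc", "mc2pc", "mc2ffi", "pc2pc",
                 "ffi2pc", "fbi2pc", "ffi2ffi", "pc2fbi", "fbi2fbi"):
        post, pre = BLOCK_SHAPES[name]
        blocks[name] = build_weight_block(counts[post], counts[pre], rules[name], rng)
        if post == pre:  # recurrent block: no autapses
            blocks[name].setdiag(0.0)
            blocks[name].eliminate_zeros()
    if reciprocity_boost > 0:
        blocks["gc2mc"] = apply_reciprocity_boost(
            blocks["mc2gc"], blocks["gc2mc"], reciprocity_boost, rng
        )
    if feedback_on:
        parts = {
            "mc2gc": blocks["mc2gc"], "gc2mc": blocks["gc2mc"],
            "mc2pc": blocks["mc2pc"], "glom_of_mt": spec.glomerulus_of_mt,
            "n_glom": spec.n_glomeruli, "n_pc": spec.n_pc, "n_gc": spec.n_gc,
        }
        blocks["pc2gc"] = build_feedback_rows(
            np.arange(spec.n_gc), parts, rules["pc2gc"], rng
        )
    else:
        blocks["pc2gc"] = sp.csr_matrix((spec.n_gc, spec.n_pc))
    delays = draw_delays(blocks["mc2gc"], rng)
    return NetworkWeights(
        spec=spec, blocks=blocks, delays_mt_gc=delays,
        feedback_on=feedback_on, build_seed=seed,
        meta={"reciprocity_boost": reciprocity_boost},
    )


def weight_dissimilarity(net_a: NetworkWeights, net_b: NetworkWeights) -> float:
    """1 - Pearson correlation of the flattened GC-related weight entries.

    Compares the four projection blocks that neurogenesis rewires (MT->GC,
    GC->MT, GC<->GC, PC->GC), zeros included.  Each block is z-scored before
    concatenation so that differences in block-wise means and scales do not
    masquerade as correlation.  Identical networks give 0; independently
    redrawn GC weights give values near 1.
    """
    xs, ys = [], []
    for name in GC_BLOCKS:
        a, b = net_a.blocks[name], net_b.blocks[name]
        if a.shape != b.shape:
            raise ConfigError(f"block {name}: shape mismatch {a.shape} vs {b.shape}")
        for mat, out in ((a, xs), (b, ys)):
            flat = np.asarray(mat.todense(), dtype=np.float64).ravel()
            sd = flat.std()
            if sd == 0:
                raise ZeroVarianceError(
                    f"weight_dissimilarity: block {name} has zero variance")
            out.append((flat - flat.mean()) / sd)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return float(1.0 - np.corrcoef(x, y)[0, 1])


def reciprocal_partner_count(net: NetworkWeights) -> np.ndarray:
    """Per-MT number of GCs connected both MT->GC and GC->MT (diagnostic)."""
    recip = net.blocks["gc2mc"].astype(bool).multiply(net.blocks["mc2gc"].T.astype(bool))
    return np.asarray(recip.sum(axis=1)).ravel().astype(int)


def pc_projection_count(net: NetworkWeights, threshold: float = 0.01) -> np.ndarray:
    """Per-PC number of GCs reached with feedback weight magnitude > threshold."""
    w = net.W_fb
    strong = sp.csr_matrix(
        (np.abs(w.data) > threshold, w.indices, w.indptr), shape=w.shape
    )
    return np.asarray(strong.sum(axis=0)).ravel().astype(int)


# -- serialization -----------------------------------------------------------

def save_network(net: NetworkWeights, path: str | Path) -> None:
    """Write blocks as COO triplets to an NPZ archive plus a JSON sidecar."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for name, block in net.blocks.items():
        coo = block.tocoo()
        arrays[f"{name}_row"] = coo.row
        arrays[f"{name}_col"] = coo.col
        arrays[f"{name}_val"] = coo.data
    dl = net.delays_mt_gc.tocoo()
    arrays["delays_row"], arrays["delays_col"], arrays["delays_val"] = dl.row, dl.col, dl.data
    np.savez_compressed(path, **arrays)
    sidecar = {
        "spec": {k: getattr(net.spec, k) for k in (
            "n_glomeruli", "mt_per_glomerulus", "n_gc", "n_pc", "n_ffi", "n_fbi",
            "scale_factor")},
        "feedback_on": net.feedback_on,
        "build_seed": net.build_seed,
        "meta": net.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_network(path: str | Path) -> NetworkWeights:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    spec = PopulationSpec(**sidecar["spec"])
    counts = spec.counts()
    data = np.load(path)
    blocks = {}
    for name in BLOCK_NAMES:
        post, pre = BLOCK_SHAPES[name]
        blocks[name] = sp.csr_matrix(
            (data[f"{name}_val"], (data[f"{name}_row"], data[f"{name}_col"])),
            shape=(counts[post], counts[pre]),
        )
    delays = sp.csr_matrix(
        (data["delays_val"], (data["delays_row"], data["delays_col"])),
        shape=blocks["mc2gc"].shape,
    )
    return NetworkWeights(
        spec=spec, blocks=blocks, delays_mt_gc=delays,
        feedback_on=sidecar["feedback_on"], build_seed=sidecar["build_seed"],
        meta=sidecar.get("meta", {}),
    )
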