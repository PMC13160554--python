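"""Model odors and glomerular input currents.

An odor is a combination of activated glomeruli, each switching on at its own
onset latency and driving its MT cells with a 90-ms step current.  A panel of
such odors (100 by default) is the stimulus set for every experiment; the
glomerular input for a given odor is identical on every trial and every
simulated day — only the noise realisations differ.

Input statistics: MT cells of the same activated glomerulus receive a shared
Gaussian noise component on top of the step (receptor-neuron input to one
glomerulus is strongly correlated), plus an independent per-cell component.
MT cells of different glomeruli receive uncorrelated input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._exceptions import ConfigError

__all__ = [
    "Odor",
    "OdorPanel",
    "OsnParams",
    "generate_odor",
    "generate_panel",
    "osn_input",
    "osn_drive",
    "odor_pairwise_correlation",
]

#: Step amplitude of the glomerular drive (current units of the neuron model).
#: Calibrated once on the default network so that activated MT cells fire in
#: the tens of Hz during their activation window while granule-cell
#: inhibition carries a substantial share of the drive (activated-MT rates
#: roughly halve when GC->MT weights are removed) and the granule-cell
#: response to an odor is sparse and stimulus-locked.
DEFAULT_AMPLITUDE = 6.0

#: Onset latencies are uniform on [0, 160] ms so that the 90-ms step always
#: ends within the 250-ms sniff window.
LATENCY_MAX_MS = 160.0

#: Bounds on the activated fraction of glomeruli (3-10 out of 50 by default).
ACTIVATION_FRACTION = (0.06, 0.20)

DURATION_MS = 90.0


@dataclass(frozen=True)
class Odor:
    """One model odor: activated glomeruli with per-glomerulus onset latency."""

    glomerulus_ids: np.ndarray       # sorted int indices
    onset_latency_ms: np.ndarray     # same length, >= 0
    duration_ms: float = DURATION_MS
    amplitude: float = DEFAULT_AMPLITUDE

    def __post_init__(self):
        object.__setattr__(self, "glomerulus_ids", np.asarray(self.glomerulus_ids, dtype=np.int64))
        object.__setattr__(self, "onset_latency_ms", np.asarray(self.onset_latency_ms, dtype=float))
        if len(self.glomerulus_ids) != len(self.onset_latency_ms):
            raise ConfigError("glomerulus_ids and onset_latency_ms must match in length")
        if np.any(self.onset_latency_ms < 0):
            raise ConfigError("onset latencies must be >= 0")

    def template(self, n_glomeruli: int, n_steps: int, dt_ms: float = 1.0) -> np.ndarray:
        """Noise-free (n_steps x n_glomeruli) step indicator times amplitude."""
        out = np.zeros((n_steps, n_glomeruli))
        t = np.arange(n_steps) * dt_ms
        for g, lat in zip(self.glomerulus_ids, self.onset_latency_ms):
            out[(t >= lat) & (t < lat + self.duration_ms), g] = self.amplitude
        return out


@dataclass
class OdorPanel:
    """Ordered list of model odors, exactly regenerable from its seed."""

    odors: list[Odor]
    n_glomeruli: int
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.odors)

    def __getitem__(self, i: int) -> Odor:
        return self.odors[i]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_glomeruli": self.n_glomeruli,
            "seed": self.seed,
            "meta": self.meta,
            "odors": [
                {
                    "glomerulus_ids": o.glomerulus_ids.tolist(),
                    "onset_latency_ms": o.onset_latency_ms.tolist(),
                    "duration_ms": o.duration_ms,
                    "amplitude": o.amplitude,
                }
                for o in self.odors
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "OdorPanel":
        doc = json.loads(Path(path).read_text())
        odors = [
            Odor(
                glomerulus_ids=np.array(o["glomerulus_ids"]),
                onset_latency_ms=np.array(o["onset_latency_ms"]),
                duration_ms=o["duration_ms"],
                amplitude=o["amplitude"],
            )
            for o in doc["odors"]
        ]
        return cls(odors=odors, n_glomeruli=doc["n_glomeruli"], seed=doc.get("seed"),
                   meta=doc.get("meta", {}))


def _activation_bounds(n_glomeruli: int) -> tuple[int, int]:
    lo = max(1, int(np.ceil(ACTIVATION_FRACTION[0] * n_glomeruli)))
    hi = max(lo, int(np.floor(ACTIVATION_FRACTION[1] * n_glomeruli)))
    return lo, hi


def generate_odor(
    n_glomeruli: int,
    rng: np.random.Generator,
    amplitude: float = DEFAULT_AMPLITUDE,
    latency_max_ms: float = LATENCY_MAX_MS,
) -> Odor:
    """Draw one odor: 6-20% of glomeruli, independent uniform onset latencies."""
    lo, hi = _activation_bounds(n_glomeruli)
    k = int(rng.integers(lo, hi + 1))
    ids = np.sort(rng.choice(n_glomeruli, size=k, replace=False))
    lat = rng.uniform(0.0, latency_max_ms, size=k)
    return Odor(glomerulus_ids=ids, onset_latency_ms=lat, amplitude=amplitude)


def generate_panel(
    n: int,
    n_glomeruli: int,
    rng: np.random.Generator | int | None = None,
    similarity_mix: float = 0.2,
    amplitude: float = DEFAULT_AMPLITUDE,
    latency_jitter_ms: float = 20.0,
) -> OdorPanel:
    """Generate the odor panel.

    A fraction ``similarity_mix`` of odors are jittered variants of earlier
    panel members (same glomeruli, perturbed latencies): independent draws
    alone give uniformly low pairwise similarity, while real odor panels span
    low to high similarity.
    """
    if n < 2:
        raise ConfigError("panel needs n >= 2 odors")
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(rng)
    odors: list[Odor] = []
    for i in range(n):
        if i > 0 and rng.uniform() < similarity_mix:
            parent = odors[int(rng.integers(0, i))]
            lat = parent.onset_latency_ms + rng.normal(0.0, latency_jitter_ms,
                                                       size=len(parent.glomerulus_ids))
            lat = np.clip(lat, 0.0, LATENCY_MAX_MS)
            odors.append(Odor(glomerulus_ids=parent.glomerulus_ids.copy(),
                              onset_latency_ms=lat, amplitude=amplitude))
        else:
            odors.append(generate_odor(n_glomeruli, rng, amplitude=amplitude))
    return OdorPanel(odors=odors, n_glomeruli=n_glomeruli, seed=seed,
                     meta={"similarity_mix": similarity_mix})


@dataclass(frozen=True)
class OsnParams:
    """Glomerular input noise model.

    ``noise_sd`` is the total Gaussian SD added to the step during activation;
    ``shared_fraction`` of its variance is common to all MT cells of the same
    glomerulus, the rest is per-cell independent.
    """

    noise_sd: float = 2.0
    shared_fraction: float = 0.5

    @property
    def sd_shared(self) -> float:
        return self.noise_sd * np.sqrt(self.shared_fraction)

    @property
    def sd_indep(self) -> float:
        return self.noise_sd * np.sqrt(1.0 - self.shared_fraction)


def osn_input(
    odor: Odor,
    glomerulus_of_mt: np.ndarray,
    t_ms: float,
    rng: np.random.Generator,
    params: OsnParams = OsnParams(),
) -> np.ndarray:
    """Per-MT glomerular current at a single time point.

    Zero outside each activated glomerulus's [latency, latency + duration)
    window; inside it, amplitude plus shared-within-glomerulus and per-cell
    Gaussian noise.
    """
    n_mt = len(glomerulus_of_mt)
    out = np.zeros(n_mt)
    for g, lat in zip(odor.glomerulus_ids, odor.onset_latency_ms):
        if lat <= t_ms < lat + odor.duration_ms:
            cells = glomerulus_of_mt == g
            shared = rng.normal(0.0, 1.0) * params.sd_shared
            out[cells] = (
                odor.amplitude + shared
                + rng.normal(0.0, params.sd_indep, size=int(cells.sum()))
            )
    return out


def osn_drive(
    odor: Odor,
    glomerulus_of_mt: np.ndarray,
    n_steps: int,
    dt_ms: float,
    rng: np.random.Generator,
    params: OsnParams = OsnParams(),
) -> np.ndarray:
    """Full-trial (n_steps x n_mt) glomerular current with one noise draw.

    Vectorised equivalent of calling :func:`osn_input` at every step.
    """
    n_glom = int(glomerulus_of_mt.max()) + 1
    tmpl = odor.template(n_glom, n_steps, dt_ms)          # steps x glomeruli
    active = tmpl > 0
    shared = np.where(active, rng.normal(0.0, params.sd_shared, size=tmpl.shape), 0.0)
    drive = (tmpl + shared)[:, glomerulus_of_mt]          # steps x n_mt
    on = active[:, glomerulus_of_mt]
    if params.sd_indep > 0 and on.any():
        drive[on] += rng.normal(0.0, params.sd_indep, size=int(on.sum()))
    drive[~on] = 0.0
    return drive


def odor_pairwise_correlation(
    panel: OdorPanel, n_steps: int = 251, dt_ms: float = 1.0
) -> np.ndarray:
    """Pearson correlations between odors' noise-free glomerulus x time templates."""
    if len(panel) == 0:
        raise ConfigError("empty panel")
    flats = np.stack([
        o.template(panel.n_glomeruli, n_steps, dt_ms).ravel() for o in panel.odors
    ])
    return np.corrcoef(flats)
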