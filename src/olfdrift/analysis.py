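"""Representational-drift statistics from spike rasters.

The pipeline mirrors the standard population-vector treatment: spike trains
are binned in 5-ms sliding windows (1-ms stride) over the 251-sample sniff
grid, giving 247 bins; a single PCA eigenspace is fitted on the trial-averaged
responses concatenated over *all* odors and days, so projections from
different days live in one common space; population vectors collapse the
(cells x bins) response to one vector per (odor, trial-or-average, day) —
by time-averaging by default — either in the full ensemble (length = number
of cells) or in the reduced space (length = number of retained components).

Drift metrics: Pearson correlations of population vectors between day pairs
(within-odor and across-odor; same-day values use even- vs odd-trial
averages), cosine similarities with a within-day variability correction, the
drift rate in degrees/day (the slope of day-pair angle versus day
separation), and K-nearest-neighbour decoding of odor identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from ._exceptions import ConfigError, ZeroVarianceError
from .simulator import SpikeRaster

__all__ = [
    "RateTensor",
    "EigenSpace",
    "DriftReport",
    "bin_spikes",
    "pooled_pca",
    "population_vector",
    "ensemble_correlation",
    "cosine_similarity",
    "within_odor_matrix",
    "within_odor_matrix_single_trial",
    "across_odor_matrix",
    "cosine_matrix",
    "drift_rate",
    "max_distance_point",
    "knn_decode",
]

BIN_MS = 5
STRIDE_MS = 1


@dataclass
class RateTensor:
    """Binned firing rates (spikes/s) for one (population, odor, trial, day)
    slice: shape (cells, bins)."""

    rates: np.ndarray
    bin_ms: float = BIN_MS
    stride_ms: float = STRIDE_MS


def bin_spikes(
    raster_or_counts,
    pop: str | None = None,
    bin_ms: float = BIN_MS,
    stride_ms: float = STRIDE_MS,
    dt_ms: float = 1.0,
) -> np.ndarray:
    """Sliding-window firing rates in spikes/s.

    Full windows only: a 251-sample trial grid with 5-sample windows at
    1-sample stride yields 247 bins.
    """
    if isinstance(raster_or_counts, SpikeRaster):
        counts = raster_or_counts.counts(pop, dt_ms=dt_ms)
    else:
        counts = np.asarray(raster_or_counts)
    n_samples = counts.shape[1]
    win = int(round(bin_ms / dt_ms))
    stride = int(round(stride_ms / dt_ms))
    if win > n_samples:
        raise ConfigError(f"bin of {win} samples exceeds trial of {n_samples}")
    cum = np.concatenate(
        [np.zeros((counts.shape[0], 1)), np.cumsum(counts, axis=1)], axis=1
    )
    starts = np.arange(0, n_samples - win + 1, stride)
    window_counts = cum[:, starts + win] - cum[:, starts]
    return window_counts / (bin_ms / 1000.0)


@dataclass
class EigenSpace:
    """Pooled principal components shared by all days.

    ``components`` columns are orthonormal eigenvectors of the response
    covariance, ordered by decreasing eigenvalue.
    """

    mean: np.ndarray                # per-cell mean over bins, odors, days
    components: np.ndarray          # (cells, n_components)
    eigenvalues: np.ndarray         # all eigenvalues, descending
    k_vis: int = 3
    k_analysis: int = 50

    def project(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        """Project (cells x T) responses onto the first k components."""
        k = self.k_analysis if k is None else k
        k = min(k, self.components.shape[1])
        return self.components[:, :k].T @ (X - self.mean[:, None])

    def variance_fraction(self, k: int) -> float:
        tot = self.eigenvalues.sum()
        if tot <= 0:
            raise ZeroVarianceError("eigenspace has zero total variance")
        return float(self.eigenvalues[:k].sum() / tot)


def pooled_pca(X: np.ndarray) -> EigenSpace:
    """Eigendecomposition of the response covariance.

    ``X`` is cells x columns with columns the concatenated (bins x odors x
    days) trial-averaged responses.  Centering subtracts each cell's grand
    mean over all columns, so a single eigenspace serves every day.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] < 2:
        raise ConfigError("pooled_pca needs at least 2 columns")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    if not np.any(Xc):
        raise ZeroVarianceError("pooled_pca on constant input")
    cov = (Xc @ Xc.T) / (X.shape[1] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    return EigenSpace(mean=mean, components=evecs[:, order], eigenvalues=evals)


def population_vector(rates: np.ndarray, mode: str = "time_average") -> np.ndarray:
    """Collapse a (cells-or-components x bins) response to one vector.

    ``time_average`` (default) averages over bins, giving length = rows;
    ``concatenate`` flattens the full matrix.
    """
    rates = np.asarray(rates)
    if mode == "time_average":
        return rates.mean(axis=-1)
    if mode == "concatenate":
        return rates.reshape(*rates.shape[:-2], -1)
    raise ConfigError(f"unknown population_vector mode {mode!r}")


def ensemble_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation between two population vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ConfigError("vectors must have equal length")
    if u.std() == 0 or v.std() == 0:
        raise ZeroVarianceError("correlation of a constant vector")
    return float(np.corrcoef(u, v)[0, 1])


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ZeroVarianceError("cosine of a zero vector")
    return float(np.dot(u, v) / (nu * nv))


# ---------------------------------------------------------------------------
# day-pair drivers (vectorised over odors/trials)
# ---------------------------------------------------------------------------

def _standardize(A: np.ndarray) -> np.ndarray:
    """Rows z-scored and scaled so that dot products are Pearson r (nan if flat)."""
    A = np.asarray(A, dtype=np.float64)
    Az = A - A.mean(axis=-1, keepdims=True)
    sd = np.linalg.norm(Az, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, Az / sd, np.nan)


def within_odor_matrix(
    avg_vecs: np.ndarray, even_vecs: np.ndarray, odd_vecs: np.ndarray
) -> np.ndarray:
    """Day x day within-odor Pearson matrix, averaged over odors.

    ``avg_vecs`` is (days, odors, N).  Off-diagonal entries compare
    trial-averaged responses of the two days; same-day entries compare the
    even- and odd-trial averages.
    """
    D = avg_vecs.shape[0]
    Z = _standardize(avg_vecs)                        # (D, O, N)
    M = np.einsum("ion,jon->ij", np.nan_to_num(Z), np.nan_to_num(Z)) / Z.shape[1]
    Ze = _standardize(even_vecs)
    Zo = _standardize(odd_vecs)
    diag = np.nanmean(np.einsum("ion,ion->io", Ze, Zo), axis=1)
    M[np.arange(D), np.arange(D)] = diag
    return (M + M.T) / 2


def within_odor_matrix_single_trial(trial_vecs: np.ndarray) -> np.ndarray:
    """Day x day within-odor Pearson matrix from single-trial vectors.

    ``trial_vecs`` is (days, odors, trials, N).  Each (i, j) entry averages
    the correlations over all trial pairs (excluding the identical-trial
    pairs on the diagonal)."""
    D, O, T, N = trial_vecs.shape
    Z = np.nan_to_num(_standardize(trial_vecs))
    M = np.zeros((D, D))
    for o in range(O):
        zo = Z[:, o].reshape(D * T, N)
        G = zo @ zo.T
        G = G.reshape(D, T, D, T)
        pair_sum = G.sum(axis=(1, 3))
        cnt = np.full((D, D), T * T, dtype=float)
        diag_self = np.einsum("itit->i", G)            # same-trial terms
        pair_sum[np.arange(D), np.arange(D)] -= diag_self
        cnt[np.arange(D), np.arange(D)] = T * T - T
        M += pair_sum / cnt
    return M / O


def across_odor_matrix(avg_vecs: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Day x day Pearson matrix across fixed odor pairs (symmetrised)."""
    Z = np.nan_to_num(_standardize(avg_vecs))
    a, b = pairs[:, 0], pairs[:, 1]
    M = np.einsum("ipn,jpn->ij", Z[:, a], Z[:, b]) / len(pairs)
    return (M + M.T) / 2


def _unit(A):
    n = np.linalg.norm(A, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, A / n, np.nan)


def cosine_matrix(
    avg_vecs: np.ndarray, even_vecs: np.ndarray, odd_vecs: np.ndarray
) -> np.ndarray:
    """Day x day cosine similarity averaged over odors.

    Same-day entries subtract the within-day variability estimate — the
    cosine deficit between even- and odd-trial averages — from the raw (unit)
    value, i.e. they equal cos(even, odd).
    """
    D = avg_vecs.shape[0]
    U = np.nan_to_num(_unit(avg_vecs))
    M = np.einsum("ion,jon->ij", U, U) / avg_vecs.shape[1]
    Ue, Uo = _unit(even_vecs), _unit(odd_vecs)
    deficit = 1.0 - np.nanmean(np.einsum("ion,ion->io", Ue, Uo), axis=1)
    M[np.arange(D), np.arange(D)] -= deficit
    return (M + M.T) / 2


def drift_rate(day_vectors: np.ndarray, method: str = "slope") -> float:
    """Daily angular change (degrees/day) of reduced-space population vectors.

    ``day_vectors`` is (days, odors, k) of trial-averaged projections.

    ``method="slope"`` (default): the least-squares slope of the mean
    day-pair angle versus the day separation.  Because the trial-averaged
    vectors are noisy estimates, the angle between any two days carries a
    separation-independent noise floor; the free intercept absorbs it and
    the slope isolates the systematic daily rotation.  ``method=
    "consecutive"`` is the literal mean angle between consecutive days
    (noise floor included).  For a noise-free rotation of x degrees per day
    both return x.
    """
    D = day_vectors.shape[0]
    if D < 2:
        raise ConfigError("drift_rate needs at least 2 days")
    U = _unit(day_vectors)
    if method == "consecutive" or D == 2:
        cosines = np.einsum("don,don->do", U[:-1], U[1:])
        ang = np.degrees(np.arccos(np.clip(cosines, -1.0, 1.0)))
        return float(np.nanmean(ang))
    if method != "slope":
        raise ConfigError(f"unknown drift_rate method {method!r}")
    G = np.einsum("don,eon->deo", U, U)                 # day x day x odor cosines
    ang = np.nanmean(np.degrees(np.arccos(np.clip(G, -1.0, 1.0))), axis=-1)
    deltas = np.arange(1, D)
    means = np.array([
        np.mean([ang[i, i + d] for i in range(D - d)]) for d in deltas
    ])
    slope = np.polyfit(deltas, means, 1)[0]
    # pure estimation noise can leave a slightly negative slope
    return float(slope)


def max_distance_point(trajectory: np.ndarray) -> tuple[int, np.ndarray]:
    """Index and coordinates of the trajectory point farthest from the origin.

    ``trajectory`` is (k x T); ties resolve to the earliest time point.
    """
    traj = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if traj.shape[1] == 0:
        raise ConfigError("empty trajectory")
    norms = np.linalg.norm(traj, axis=0)
    idx = int(np.argmax(norms))  # argmax returns the first maximal index
    return idx, traj[:, idx]


def knn_decode(
    X: np.ndarray,
    y: np.ndarray,
    train_ratio: float = 0.9,
    K: int = 3,
    n_repeats: int = 30,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Mean held-out two-odor decoding accuracy of a KNN classifier.

    Euclidean distance, majority vote over K neighbours, averaged over
    ``n_repeats`` random stratified train/test splits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ConfigError("knn_decode expects exactly two odor labels")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_train = int(round(train_ratio * len(y)))
    if K > n_train:
        raise ConfigError(f"K={K} exceeds the training-set size {n_train}")
    accs = []
    for _ in range(n_repeats):
        seed = int(rng.integers(2**31))
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, train_size=train_ratio, stratify=y, random_state=seed
        )
        clf = KNeighborsClassifier(n_neighbors=K).fit(Xtr, ytr)
        accs.append(clf.score(Xte, yte))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------

@dataclass
class DriftReport:
    """All drift statistics of one experiment, per population.

    Matrices are day x day; keys of the per-population dicts are ``"mt"``
    and ``"pc"``.
    """

    days: int
    odors: int
    trials: int
    within_full: dict = field(default_factory=dict)
    within_full_single: dict = field(default_factory=dict)
    within_reduced: dict = field(default_factory=dict)
    within_reduced_single: dict = field(default_factory=dict)
    across_full: dict = field(default_factory=dict)
    across_reduced: dict = field(default_factory=dict)
    cosine_reduced: dict = field(default_factory=dict)
    drift_rate_deg_per_day: dict = field(default_factory=dict)
    decoder_accuracy: dict = field(default_factory=dict)
    variance_fraction: dict = field(default_factory=dict)
    variance_fraction_50: dict = field(default_factory=dict)
    weight_dissimilarity_by_day: list = field(default_factory=list)
    weight_ks_by_day: list = field(default_factory=list)
    odor_pairs: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x
        return {k: conv(v) for k, v in self.__dict__.items()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def matrices_to_csv(self, directory: str | Path) -> None:
        import pandas as pd
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for attr in ("within_full", "within_full_single", "within_reduced",
                     "within_reduced_single", "across_full", "across_reduced",
                     "cosine_reduced"):
            for pop, M in getattr(self, attr).items():
                pd.DataFrame(np.asarray(M)).to_csv(
                    directory / f"{attr}_{pop}.csv", index_label="day"
                )
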