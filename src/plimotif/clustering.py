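"""Grouping interface graphs: SVD reduction, clustering, model selection.

The binary feature matrix is reduced with a truncated singular value
decomposition (rows embedded as U * S), then segmented with one of three
algorithms -- PAM-style k-medoids (default), Ward agglomerative, or
spectral with an RBF affinity -- and scored with the average silhouette
width (default) or the Calinski-Harabasz index.  ``select_model`` sweeps k
and keeps the best-scoring model, breaking ties toward smaller k.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from sklearn.cluster import AgglomerativeClustering, SpectralClustering
from sklearn.metrics import calinski_harabasz_score, silhouette_samples
from scipy.spatial.distance import pdist, squareform

from plimotif.featurization import FeatureMatrix

logger = logging.getLogger(__name__)

ALGORITHMS = ("kmedoids", "agglomerative", "spectral")
METRICS = ("asw", "calinski_harabasz")

#: Sentinel score for degenerate clusterings (fewer than two non-empty
#: groups), below any attainable value of either metric.
DEGENERATE_SCORE = float("-inf")

DEFAULT_ENERGY_FRACTION = 0.9
MAX_DEFAULT_RANK = 100


@dataclass
class Embedding:
    graph_ids: list[str]
    coordinates: np.ndarray  # (n_graphs, retained_rank)
    singular_values: np.ndarray  # all singular values, non-increasing
    retained_rank: int


@dataclass
class ClusterModel:
    algorithm: str
    k: int
    labels: dict[str, int]  # graph_id -> 1-based contiguous group index
    metric: str
    score: float
    seed: int

    @property
    def n_groups(self) -> int:
        return len(set(self.labels.values()))

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for gid, lab in self.labels.items():
            out.setdefault(lab, []).append(gid)
        return out


def svd_reduce(matrix: FeatureMatrix,
               rank: Union[int, float, None] = None) -> Embedding:
    """Embed graphs as U*S truncated to ``rank`` components.

    ``rank`` may be an integer, a fraction in (0, 1) interpreted as the
    squared-singular-value energy to retain, or None (default 90% energy,
    capped at min(n-1, 100)).  Signs are fixed so each component's
    largest-magnitude loading is positive.
    """
    X = matrix.data.to_numpy(dtype=float)
    n, m = X.shape
    if n < 2 or m < 1:
        raise ValueError(f"matrix must have >=2 rows and >=1 column, got {X.shape}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # Deterministic sign convention on the right singular vectors.
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]

    max_rank = len(s)
    if rank is None:
        rank = DEFAULT_ENERGY_FRACTION
        cap = min(n - 1, MAX_DEFAULT_RANK)
    else:
        cap = max_rank
    if isinstance(rank, float) and 0 < rank < 1:
        energy = np.cumsum(s**2)
        total = energy[-1]
        if total == 0:
            r = 1
        else:
            r = int(np.searchsorted(energy, rank * total - 1e-12) + 1)
        r = min(r, cap)
    else:
        r = int(rank)
        if r > max_rank:
            logger.warning("requested rank %d exceeds min(dims)=%d; clamped", r, max_rank)
            r = max_rank
        if r < 1:
            raise ValueError(f"rank must be >= 1, got {r}")
    coords = U[:, :r] * s[:r]
    return Embedding(graph_ids=list(matrix.graph_ids), coordinates=coords,
                     singular_values=s, retained_rank=r)


# --------------------------------------------------------------------------
# Clustering algorithms
# --------------------------------------------------------------------------

def _pam_kmedoids(X: np.ndarray, k: int, rng: np.random.Generator,
                  max_iter: int = 300) -> np.ndarray:
    """PAM (build + swap) k-medoids with Euclidean distances.

    Seed-controlled: the BUILD phase is deterministic greedy, ties broken
    by index; the rng only matters if BUILD cannot distinguish candidates.
    """
    n = X.shape[0]
    D = squareform(pdist(X))
    # BUILD: first medoid minimises total distance; then greedily add the
    # point with the largest reduction.
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(nearest - D[:, c], 0).sum() if c not in medoids else -np.inf
            for c in range(n)
        ])
        best = int(np.argmax(gains))
        if gains[best] <= 0:
            # No reduction possible (duplicate points): pick an unused
            # index, randomly among candidates for seed sensitivity.
            unused = [c for c in range(n) if c not in medoids]
            best = int(rng.choice(unused))
        medoids.append(best)
    # SWAP: hill-climb on total assignment cost.
    def cost(meds):
        return D[:, meds].min(axis=1).sum()

    current = cost(medoids)
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for c in range(n):
                if c in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = c
                tc = cost(trial)
                if tc < current - 1e-12:
                    medoids, current = trial, tc
                    improved = True
        if not improved:
            break
    return np.argmin(D[:, medoids], axis=1)


def run_clustering(embedding: Embedding, algorithm: str, k: int,
                   seed: int = 0) -> dict[str, int]:
    """Cluster the embedded graphs into (up to) k groups.

    Returns a full 1-based contiguous labeling keyed by graph id.
    Degenerate inputs (e.g. identical points) return a valid labeling
    with possibly fewer groups rather than failing.
    """
    n = len(embedding.graph_ids)
    if not (2 <= k <= n - 1):
        raise ValueError(f"k={k} out of range [2, {n - 1}] for {n} graphs")
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    X = embedding.coordinates
    rng = np.random.default_rng(seed)
    if algorithm == "kmedoids":
        raw = _pam_kmedoids(X, k, rng)
    elif algorithm == "agglomerative":
        raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    else:  # spectral
        d = pdist(X)
        med = float(np.median(d)) if len(d) else 0.0
        gamma = 1.0 / (2 * med**2) if med > 0 else 1.0
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                raw = SpectralClustering(
                    n_clusters=k, affinity="rbf", gamma=gamma,
                    random_state=seed, assign_labels="kmeans",
                ).fit_predict(X)
        except Exception as exc:  # fully degenerate affinity
            logger.warning("spectral clustering degenerate (%s); falling back to "
                           "round-robin labels", exc)
            raw = np.arange(n) % k
    # Relabel to contiguous 1-based indices in order of first appearance.
    remap: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels.append(remap[lab])
    return dict(zip(embedding.graph_ids, labels))


# --------------------------------------------------------------------------
# Quality metrics
# --------------------------------------------------------------------------

def score_clustering(embedding: Embedding, labels: dict[str, int],
                     metric: str = "asw") -> float:
    """Average silhouette width or Calinski-Harabasz index.

    Conventions: a per-point silhouette is 0 when max(a, b) = 0 (identical
    points) and 0 for singleton clusters; a labeling with fewer than two
    non-empty groups scores the :data:`DEGENERATE_SCORE` sentinel.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    X = embedding.coordinates
    y = np.array([labels[gid] for gid in embedding.graph_ids])
    if len(set(y)) < 2 or len(set(y)) >= len(y) + 1:
        return DEGENERATE_SCORE
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if metric == "asw":
            if np.allclose(pdist(X), 0):
                return 0.0  # all points coincide: 0/0 := 0 convention
            vals = silhouette_samples(X, y)
            return float(np.nan_to_num(vals, nan=0.0).mean())
        score = calinski_harabasz_score(X, y)
        return float(np.nan_to_num(score, nan=0.0))


def default_k_range(n: int) -> range:
    return range(2, min(15, n - 1) + 1)


def select_model(embedding: Embedding, algorithm: str = "kmedoids",
                 metric: str = "asw",
                 k_range: Union[Sequence[int], None] = None,
                 seed: int = 0) -> ClusterModel:
    """Fit every k in ``k_range`` and keep the best-scoring model.

    Ties break toward smaller k.  Default range: 2..min(15, n-1).
    """
    n = len(embedding.graph_ids)
    if k_range is None:
        k_range = default_k_range(n)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    best = None
    for k in ks:
        if not (2 <= k <= n - 1):
            logger.warning("skipping k=%d (out of range for n=%d)", k, n)
            continue
        labels = run_clustering(embedding, algorithm, k, seed)
        score = score_clustering(embedding, labels, metric)
        if best is None or score > best.score:
            best = ClusterModel(algorithm=algorithm, k=k, labels=labels,
                                metric=metric, score=score, seed=seed)
    if best is None:
        raise ValueError(f"no valid k in {ks} for n={n}")
    return best
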