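"""Resampling-based consensus clustering for molecular subtype discovery.

For each candidate cluster count K, samples are repeatedly subsampled without
replacement, clustered, and the consensus matrix M(i, j) records the fraction
of co-resamples in which samples i and j landed in the same cluster. Final
subgroup assignments come from average-linkage hierarchical clustering of
1 - M, and each cluster k gets a cluster-consensus score

    m(k) = mean of M(i, j) over unordered within-cluster pairs.

The subgroup count is chosen as the *largest* K whose minimum cluster
consensus exceeds a threshold (default 0.8) — when several K qualify, finer
structure is preferred.

The base clusterer is K-means on samples over genes standardized to zero
mean/unit variance (Euclidean distance), with one fixed seed per resample.
Samples are first embedded exactly into the rank-min(N, G) subspace they span
(via SVD), which preserves all pairwise Euclidean distances to machine
precision and keeps per-resample clustering cheap when genes vastly outnumber
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from adsubtypes.errors import ConfigError

logger = logging.getLogger(__name__)

#: Roman labels for discovered subgroups, index 1-based.
ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass
class ConsensusRun:
    """Consensus matrix, assignments and per-cluster consensus for one K."""

    k: int
    sample_ids: list[str]
    consensus: np.ndarray  # (N, N) in [0, 1], symmetric, unit diagonal
    copair_counts: np.ndarray  # (N, N) times i, j were co-resampled
    assignments: pd.Series  # sample id -> cluster int (1..k)
    cluster_consensus: dict[int, float]

    @property
    def min_cluster_consensus(self) -> float:
        return min(self.cluster_consensus.values())


@dataclass
class SelectionTrace:
    """Audit trail of the subgroup-count selection rule."""

    scores: dict[int, dict[int, float]]  # K -> cluster -> m(k)
    threshold: float
    chosen_k: int | None
    rule: str


def _kmeans_clusterer(coords: np.ndarray, k: int, seed: int) -> np.ndarray:
    # A single K-means run with a fresh seeded initialization per resample:
    # consensus clustering relies on run-to-run perturbation to expose
    # over-partitioning, so the base algorithm is executed once per subsample
    # rather than best-of-many-inits.
    km = KMeans(n_clusters=k, n_init=1, random_state=seed)
    return km.fit_predict(coords)


def _hierarchical_clusterer(coords: np.ndarray, k: int, seed: int) -> np.ndarray:
    # deterministic alternative base clusterer (Euclidean, average linkage)
    Zl = linkage(coords, method="average")
    return fcluster(Zl, t=k, criterion="maxclust") - 1


BASE_CLUSTERERS: dict[str, Callable[[np.ndarray, int, int], np.ndarray]] = {
    "kmeans": _kmeans_clusterer,
    "hierarchical": _hierarchical_clusterer,
}


def standardized_embedding(matrix: pd.DataFrame) -> np.ndarray:
    """Samples x rank coordinates with exact pairwise Euclidean distances.

    Genes are standardized (zero mean, unit variance; constant genes are
    dropped) and samples are represented in the row space of the standardized
    matrix via SVD.
    """
    Y = matrix.to_numpy(dtype=float)
    mu = Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    Z = (Y[keep] - mu[keep]) / sd[keep]
    if Z.shape[0] == 0:
        raise ConfigError("no variable genes to cluster on")
    if Z.shape[0] <= Z.shape[1]:
        return Z.T.copy()
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    return Vt.T * s


def consensus_from_memberships(
    memberships: Sequence[tuple[np.ndarray, np.ndarray]],
    n_samples: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Consensus and co-resample count matrices from recorded resamples.

    ``memberships`` is a sequence of ``(sample_positions, cluster_labels)``
    pairs, one per resample. Pairs never co-resampled get consensus 0 (with a
    logged notice). The streaming counters used by :func:`consensus_matrix`
    reduce to exactly this computation.
    """
    conn = np.zeros((n_samples, n_samples))
    copair = np.zeros((n_samples, n_samples))
    for idx, labels in memberships:
        idx = np.asarray(idx)
        labels = np.asarray(labels)
        copair[np.ix_(idx, idx)] += 1
        for lab in np.unique(labels):
            members = idx[labels == lab]
            conn[np.ix_(members, members)] += 1
    never = (copair == 0) & ~np.eye(n_samples, dtype=bool)
    if never.any():
        logger.info("%d sample pair(s) never co-resampled; consensus set to 0", int(never.sum() // 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(copair > 0, conn / np.maximum(copair, 1), 0.0)
    np.fill_diagonal(M, 1.0)
    return M, copair


def consensus_matrix(
    matrix: pd.DataFrame,
    k: int,
    n_resamples: int = 100,
    sample_fraction: float = 0.8,
    seed: int = 0,
    base: str = "kmeans",
    embedding: np.ndarray | None = None,
) -> ConsensusRun:
    """One consensus-clustering run at cluster count ``k``.

    ``matrix`` holds the samples to subtype (genes x samples, typically the
    batch-corrected AD samples). ``embedding`` may pass a precomputed
    :func:`standardized_embedding` to share across K values.
    """
    n = matrix.shape[1]
    if not 2 <= k <= n:
        raise ConfigError(f"need 2 <= K <= n_samples, got K={k}, n={n}")
    if not 0 < sample_fraction <= 1:
        raise ConfigError("sample_fraction must be in (0, 1]")
    if n_resamples < 1:
        raise ConfigError("n_resamples must be >= 1")
    clusterer = BASE_CLUSTERERS.get(base)
    if clusterer is None:
        raise ConfigError(f"unknown base clusterer {base!r}")
    coords = standardized_embedding(matrix) if embedding is None else embedding

    n_draw = int(np.floor(sample_fraction * n))
    if n_draw < k:
        raise ConfigError("sample_fraction too small: resample smaller than K")
    rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
    memberships = []
    for r in range(n_resamples):
        idx = np.sort(rng.choice(n, size=n_draw, replace=False))
        labels = clusterer(coords[idx], k, int(rng.integers(2**31 - 1)))
        memberships.append((idx, labels))
    M, copair = consensus_from_memberships(memberships, n)

    assignments = _assign_from_consensus(M, k)
    run = ConsensusRun(
        k=k,
        sample_ids=list(matrix.columns),
        consensus=M,
        copair_counts=copair,
        assignments=pd.Series(assignments, index=matrix.columns, name="cluster"),
        cluster_consensus={},
    )
    run.cluster_consensus = cluster_consensus_scores(run)
    return run


def _assign_from_consensus(M: np.ndarray, k: int) -> np.ndarray:
    dist = 1.0 - M
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Zl = linkage(condensed, method="average")
    return fcluster(Zl, t=k, criterion="maxclust")


def cluster_consensus_scores(run: ConsensusRun) -> dict[int, float]:
    """m(k): mean consensus over within-cluster pairs (singletons score 1)."""
    scores: dict[int, float] = {}
    labels = run.assignments.to_numpy()
    for lab in np.unique(labels):
        pos = np.flatnonzero(labels == lab)
        if pos.size == 1:
            logger.info("cluster %s is a singleton; consensus defined as 1", lab)
            scores[int(lab)] = 1.0
            continue
        block = run.consensus[np.ix_(pos, pos)]
        iu = np.triu_indices(pos.size, k=1)
        scores[int(lab)] = float(block[iu].mean())
    return scores


def consensus_sweep(
    matrix: pd.DataFrame,
    k_max: int = 10,
    n_resamples: int = 100,
    sample_fraction: float = 0.8,
    seed: int = 0,
    base: str = "kmeans",
) -> dict[int, ConsensusRun]:
    """Consensus runs for K = 2..k_max sharing one embedding."""
    coords = standardized_embedding(matrix)
    k_top = min(k_max, matrix.shape[1])
    return {
        k: consensus_matrix(
            matrix, k, n_resamples, sample_fraction, seed, base, embedding=coords
        )
        for k in range(2, k_top + 1)
    }


def select_cluster_count(
    runs: dict[int, ConsensusRun] | dict[int, dict[int, float]],
    threshold: float = 0.8,
    min_cluster_size: int = 1,
) -> SelectionTrace:
    """Choose the largest K whose minimum cluster consensus exceeds threshold.

    ``min_cluster_size`` optionally disqualifies K values whose final
    assignment contains a cluster smaller than the given size (singletons
    score a consensus of 1 by convention, so without this guard a K that
    merely splits off an outlier can qualify). Sizes are only known when
    full :class:`ConsensusRun` objects are supplied; plain score tables are
    selected on scores alone.

    When no K qualifies, ``chosen_k`` is None and downstream stages refuse to
    run without an explicit override.
    """
    if not runs:
        raise ConfigError("select_cluster_count: no runs supplied")
    scores: dict[int, dict[int, float]] = {}
    sizes_ok: dict[int, bool] = {}
    for k, run in runs.items():
        if isinstance(run, ConsensusRun):
            scores[k] = dict(run.cluster_consensus)
            sizes_ok[k] = bool(
                run.assignments.value_counts().min() >= min_cluster_size
            )
        else:
            scores[k] = dict(run)
            sizes_ok[k] = True
    qualifying = [
        k for k, sc in scores.items() if min(sc.values()) > threshold and sizes_ok[k]
    ]
    chosen = max(qualifying) if qualifying else None
    rule = f"largest K with min cluster consensus > {threshold}"
    if min_cluster_size > 1:
        rule += f" and all cluster sizes >= {min_cluster_size}"
    if chosen is None:
        rule += " (none qualifies)"
    return SelectionTrace(scores=scores, threshold=threshold, chosen_k=chosen, rule=rule)


def label_assignments(run: ConsensusRun) -> pd.Series:
    """Map integer clusters to Roman subgroup labels, largest cluster first.

    Ties in size break by the smallest member position, keeping the labeling
    deterministic.
    """
    labels = run.assignments
    sizes = labels.value_counts()
    order = sorted(
        sizes.index,
        key=lambda lab: (-sizes[lab], int(np.flatnonzero(labels.to_numpy() == lab)[0])),
    )
    mapping = {lab: ROMAN[i] for i, lab in enumerate(order)}
    return labels.map(mapping).rename("subgroup")
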