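"""Per-timestep community detection by consensus clustering.

Each timestep's graph is clustered on its own: the rows of the adjacency
matrix (one connectivity profile per electrode) are repeatedly subsampled
and k-means-clustered, and the runs are combined into a consensus matrix
per candidate K.  The number of communities is selected from the empirical
CDF of the consensus entries.  Two CDF statistics are implemented: the
default is the proportion of ambiguous clustering (PAC — the CDF mass
between 0.1 and 0.9, low when co-clustering is decisive), and the classic
change-in-CDF-area criterion of Monti et al. is available as an
alternative.  The per-K likelihood profile this produces is exactly what
the K-cluster heatmap visualizes; a consensus that is all ones for every
candidate K is the degenerate "one community" case and selects K = 1 with
a flat zero profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .data_io import DynamicNetwork

logger = logging.getLogger(__name__)


@dataclass
class ConsensusParams:
    """Resampling configuration for consensus clustering.

    ``k_min``/``k_max`` bound the candidate number of communities,
    ``n_runs`` is the number of subsampled k-means runs per candidate K,
    ``subsample_fraction`` the fraction of electrodes kept per run, and
    ``identity_epsilon`` the tolerance of the all-ones degeneracy test.
    """

    k_min: int = 2
    k_max: int = 8
    n_runs: int = 50
    subsample_fraction: float = 0.8
    seed: int = 0
    identity_epsilon: float = 1e-6
    statistic: str = "pac"

    def __post_init__(self) -> None:
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.k_max < self.k_min:
            raise ValueError("empty K range")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.statistic not in ("pac", "delta-area"):
            raise ValueError("statistic must be 'pac' or 'delta-area'")

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)


@dataclass
class TimestepClustering:
    """Result of clustering one timestep.

    ``labels`` is a non-overlapping exhaustive partition (one integer in
    ``[0, k)`` per electrode), ``likelihood`` the normalized per-K profile
    feeding the heatmap, and ``consensus`` optionally retains the consensus
    matrices per candidate K.
    """

    labels: np.ndarray
    k: int
    likelihood: dict[int, float]
    consensus: Optional[dict[int, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if self.k != len(uniq) or not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("labels must be 0..K-1 with K distinct values")
        for v in self.likelihood.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("likelihood values must lie in [0, 1]")

    def partition(self, node_ids: list[str]) -> list[set[str]]:
        """Clusters as node-id sets, ordered by label."""
        return [
            {node_ids[i] for i in np.flatnonzero(self.labels == c)}
            for c in range(self.k)
        ]


def _seed_for(params: ConsensusParams, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, *key]))


def consensus_matrix(
    features: np.ndarray,
    k: int,
    params: ConsensusParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Co-clustering frequency matrix over subsampled k-means runs.

    ``M[i, j]`` is the number of runs in which i and j were co-clustered
    divided by the number of runs in which both were subsampled; pairs
    never co-sampled get 0 (with a logged warning).  M is symmetric with
    unit diagonal.

    Indistinguishable inputs — all pairwise feature distances equal, as for
    a uniform complete graph (or identical profiles) — carry no structure
    for k-means to act on, and any split it produced would be an artifact
    of tie-breaking; every node is treated as co-clustered in every run,
    giving the all-ones consensus that drives the degenerate K = 1 rule.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if k > n:
        raise ValueError(f"K={k} exceeds number of nodes {n}")
    d = pdist(features)
    if d.size and d.max() - d.min() <= 1e-9 * max(1.0, float(d.max())):
        logger.info("indistinguishable connectivity profiles; consensus is identity")
        return np.ones((n, n))
    if rng is None:
        rng = _seed_for(params, k)
    m = max(k, int(round(params.subsample_fraction * n)))
    co = np.zeros((n, n))
    both = np.zeros((n, n))
    for _ in range(params.n_runs):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        km_seed = int(rng.integers(2**31))
        labels = KMeans(n_clusters=k, n_init=1, random_state=km_seed).fit_predict(
            features[idx]
        )
        both[np.ix_(idx, idx)] += 1.0
        for c in range(k):
            mem = idx[labels == c]
            if mem.size:
                co[np.ix_(mem, mem)] += 1.0
    never = (both == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        logger.warning(
            "%d node pair(s) never co-sampled; consensus set to 0 — "
            "increase n_runs or subsample_fraction",
            int(never.sum()) // 2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.where(both > 0, co / np.maximum(both, 1e-300), 0.0)
    np.fill_diagonal(mat, 1.0)
    return (mat + mat.T) / 2.0


def cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    n = consensus.shape[0]
    vals = np.sort(consensus[np.triu_indices(n, k=1)])
    m = vals.size
    if m == 0:
        return 0.0
    cdf = np.arange(2, m + 1) / m  # CDF evaluated at each upper entry
    return float(np.sum(np.diff(vals) * cdf))


def pac_score(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: CDF(upper) - CDF(lower).

    The fraction of off-diagonal consensus entries that are neither
    decisively together nor decisively apart; near 0 when the candidate K
    matches the data's block structure.
    """
    n = consensus.shape[0]
    vals = consensus[np.triu_indices(n, k=1)]
    if vals.size == 0:
        return 0.0
    return float((vals <= upper).mean() - (vals <= lower).mean())


def delta_area_profile(consensus_by_k: dict[int, np.ndarray]) -> dict[int, float]:
    """Classic change-in-CDF-area statistic: A(K) for the smallest K, then
    the relative increase (A(K) - A(K-1)) / A(K-1)."""
    ks = sorted(consensus_by_k)
    areas = {k: cdf_area(consensus_by_k[k]) for k in ks}
    delta: dict[int, float] = {}
    for pos, k in enumerate(ks):
        if pos == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[pos - 1]]
            # relative change; absolute fallback when the previous area vanishes
            delta[k] = (areas[k] - prev) / prev if prev > 1e-12 else areas[k]
    return delta


def k_likelihood_profile(
    consensus_by_k: dict[int, np.ndarray], params: ConsensusParams
) -> tuple[dict[int, float], int]:
    """Per-K likelihood from the consensus CDFs, rescaled to [0, 1].

    With the default ``pac`` statistic the raw score per K is 1 - PAC
    (decisiveness of co-clustering); with ``delta-area`` it is the classic
    relative change in CDF area.  Either raw profile is min-max rescaled to
    [0, 1] across the candidate range and the selected K is the argmax
    (ties broken toward smaller K).  If every consensus matrix is all ones
    within ``identity_epsilon``, the nodes are indistinguishable: the whole
    profile is 0 and K = 1 is selected.
    """
    ks = sorted(consensus_by_k)
    if not ks:
        raise ValueError("empty candidate set")
    degenerate = all(
        np.abs(consensus_by_k[k] - 1.0).max() <= params.identity_epsilon for k in ks
    )
    if degenerate:
        return {k: 0.0 for k in ks}, 1

    if params.statistic == "pac":
        raw = {k: 1.0 - pac_score(consensus_by_k[k]) for k in ks}
    else:
        raw = delta_area_profile(consensus_by_k)
    lo = min(raw.values())
    hi = max(raw.values())
    if hi - lo < 1e-15:
        likelihood = {k: 1.0 for k in ks}
    else:
        likelihood = {k: (raw[k] - lo) / (hi - lo) for k in ks}
    selected = max(ks, key=lambda k: (likelihood[k], -k))
    return likelihood, selected


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by descending size, ties by smallest member index."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    order = sorted(
        uniq,
        key=lambda c: (-(labels == c).sum(), int(np.flatnonzero(labels == c)[0])),
    )
    remap = {c: r for r, c in enumerate(order)}
    return np.array([remap[c] for c in labels], dtype=int)


def cluster_timestep(
    net: DynamicNetwork,
    t: int,
    params: ConsensusParams,
    keep_consensus: bool = False,
) -> TimestepClustering:
    """Cluster one timestep: select K, then cut the consensus hierarchy.

    The feature vector of each electrode is its row of the adjacency matrix
    (connectivity profile).  Final labels come from average-linkage
    hierarchical clustering of the distance ``1 - M_K`` cut at the selected
    K; labels are canonicalized by size, then smallest member index.
    """
    if not 0 <= t < net.n_timesteps:
        raise IndexError(f"timestep {t} out of range")
    features = net.adjacency[t]
    n = net.n_nodes
    consensus_by_k = {
        k: consensus_matrix(features, k, params, rng=_seed_for(params, t, k))
        for k in params.k_range
        if k <= n
    }
    if not consensus_by_k:
        raise ValueError("no candidate K fits the number of nodes")
    likelihood, selected = k_likelihood_profile(consensus_by_k, params)
    if selected == 1:
        labels = np.zeros(n, dtype=int)
    else:
        m = consensus_by_k[selected]
        dist = squareform(1.0 - m, checks=False)
        z = linkage(dist, method="average")
        labels = _canonical_labels(fcluster(z, t=selected, criterion="maxclust") - 1)
    k_actual = len(np.unique(labels))
    return TimestepClustering(
        labels=labels,
        k=k_actual,
        likelihood=likelihood,
        consensus=consensus_by_k if keep_consensus else None,
    )


def cluster_all(
    net: DynamicNetwork, params: ConsensusParams, keep_consensus: bool = False
) -> list[TimestepClustering]:
    """Cluster every timestep of a dynamic network independently."""
    return [
        cluster_timestep(net, t, params, keep_consensus=keep_consensus)
        for t in range(net.n_timesteps)
    ]
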