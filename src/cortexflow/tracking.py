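"""Cluster tracking across timesteps and dynamic-community assembly.

Clusters detected independently at consecutive timesteps are matched
either greedily (repeatedly pairing the two clusters that share the
maximum number of electrodes) or globally (the injective assignment that
maximizes the total Jaccard similarity, with similarities below a
threshold θ zeroed out).  Matched clusters inherit a persistent community
identity; unmatched sinks are births and unmatched sources deaths.  The
transition links between consecutive partitions — one per cluster pair
sharing at least one electrode — are what the alluvial view draws as
ribbons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._palettes import DEFAULT_PALETTE, get_palette
from .communities import TimestepClustering

logger = logging.getLogger(__name__)

#: largest per-side cluster count handled by exhaustive enumeration
ENUMERATION_LIMIT = 10


@dataclass(frozen=True)
class ClusterBlock:
    """One cluster at one timestep: a rectangular block of the timeline."""

    t: int
    i: int
    members: frozenset[str]
    persistent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster block must be non-empty")


@dataclass(frozen=True)
class TransitionLink:
    """Electrode flow from a source cluster at t to a sink cluster at t+1."""

    t: int
    source: int
    sink: int
    count: int
    similarity: float


@dataclass
class Matching:
    """Injective pairing of source-cluster to sink-cluster indices."""

    pairs: list[tuple[int, int]]
    unmatched_sources: list[int]
    unmatched_sinks: list[int]

    def __post_init__(self) -> None:
        srcs = [p[0] for p in self.pairs]
        snks = [p[1] for p in self.pairs]
        if len(set(srcs)) != len(srcs) or len(set(snks)) != len(snks):
            raise ValueError("matching must be injective in both coordinates")


@dataclass
class DynamicCommunitySet:
    """Tracked partitions with persistent ids, links and colors.

    ``blocks[t]`` lists the clusters of timestep t; ``links[t]`` the
    transition links between t and t+1 (so ``len(links) == T - 1``).
    """

    node_ids: list[str]
    blocks: list[list[ClusterBlock]]
    links: list[list[TransitionLink]]
    colors: dict[str, str]
    method: str
    theta: float
    k_profiles: Optional[list[tuple[int, dict[int, float]]]] = None

    @property
    def n_timesteps(self) -> int:
        return len(self.blocks)

    def persistent_ids(self) -> list[str]:
        """All persistent ids in order of first appearance."""
        seen: list[str] = []
        for blocks in self.blocks:
            for b in blocks:
                if b.persistent_id is not None and b.persistent_id not in seen:
                    seen.append(b.persistent_id)
        return seen

    def validate(self) -> None:
        all_nodes = set(self.node_ids)
        for t, blocks in enumerate(self.blocks):
            covered: set[str] = set()
            for b in blocks:
                if covered & b.members:
                    raise ValueError(f"overlapping blocks at t={t}")
                covered |= b.members
            if covered != all_nodes:
                raise ValueError(f"blocks at t={t} do not cover the node set")
            pids = [b.persistent_id for b in blocks]
            if len(set(pids)) != len(pids):
                raise ValueError(f"persistent id repeated within t={t}")


# ---------------------------------------------------------------------------
# Similarity and matching
# ---------------------------------------------------------------------------

def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard similarity |A ∩ B| / |A ∪ B| of two non-empty node sets."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("jaccard of an empty set is undefined")
    return len(sa & sb) / len(sa | sb)


def overlap_matrix(p_t: Sequence[set], p_t1: Sequence[set]) -> np.ndarray:
    """Pairwise intersection counts between two partitions."""
    out = np.zeros((len(p_t), len(p_t1)), dtype=int)
    for i, a in enumerate(p_t):
        for j, b in enumerate(p_t1):
            out[i, j] = len(set(a) & set(b))
    return out


def similarity_matrix(p_t: Sequence[set], p_t1: Sequence[set]) -> np.ndarray:
    """Pairwise Jaccard similarities between two partitions."""
    out = np.zeros((len(p_t), len(p_t1)))
    for i, a in enumerate(p_t):
        for j, b in enumerate(p_t1):
            out[i, j] = jaccard(a, b)
    return out


def greedy_match(
    p_t: Sequence[set],
    p_t1: Sequence[set],
    overlaps: Optional[np.ndarray] = None,
) -> Matching:
    """Maximum-overlap greedy matching.

    Iteratively pairs the two unmatched clusters sharing the most
    electrodes, removing both, until no unmatched pair overlaps at all.
    Ties break row-major: smaller source index, then smaller sink index.
    ``overlaps`` may supply a precomputed count matrix (used directly, e.g.
    for worked examples given as counts).
    """
    ov = overlap_matrix(p_t, p_t1) if overlaps is None else np.asarray(overlaps)
    ov = ov.copy()
    pairs: list[tuple[int, int]] = []
    free_src = set(range(ov.shape[0]))
    free_snk = set(range(ov.shape[1]))
    while free_src and free_snk:
        best = None
        best_val = 0
        for i in sorted(free_src):
            for j in sorted(free_snk):
                if ov[i, j] > best_val:
                    best_val = ov[i, j]
                    best = (i, j)
        if best is None:
            break
        pairs.append(best)
        free_src.discard(best[0])
        free_snk.discard(best[1])
    return Matching(pairs, sorted(free_src), sorted(free_snk))


def _enumerate_best(sims: np.ndarray) -> list[tuple[int, int]]:
    """Exhaustive search for the max-total-similarity injective matching."""
    rows, cols = sims.shape
    transposed = rows > cols
    m = sims.T if transposed else sims
    r, c = m.shape
    best_score = -1.0
    best_pairs: Optional[list[tuple[int, int]]] = None
    for perm in permutations(range(c), r):
        score = sum(m[i, perm[i]] for i in range(r))
        if score < best_score:
            continue
        pairs = [
            (perm[i], i) if transposed else (i, perm[i])
            for i in range(r)
            if m[i, perm[i]] > 0
        ]
        pairs.sort()
        if score > best_score + 1e-12 or (
            abs(score - best_score) <= 1e-12
            and (best_pairs is None or pairs < best_pairs)
        ):
            best_score = score
            best_pairs = pairs
    return best_pairs or []


def optimal_match(
    p_t: Sequence[set],
    p_t1: Sequence[set],
    theta: float = 0.1,
    similarities: Optional[np.ndarray] = None,
    engine: Literal["enumerate", "solver"] = "enumerate",
) -> Matching:
    """Globally optimal matching by total Jaccard similarity.

    Similarities below θ are zeroed before optimization; zero-similarity
    pairings are left unmatched rather than emitted.  The reference
    semantics enumerates every injective assignment (tractable for the
    handful of clusters per timestep this data has); ``engine="solver"``
    uses a linear-assignment solver instead and is required above
    ``ENUMERATION_LIMIT`` clusters per side.
    """
    sims = (
        similarity_matrix(p_t, p_t1) if similarities is None else np.asarray(similarities, float)
    )
    sims = np.where(sims < theta, 0.0, sims)
    rows, cols = sims.shape
    if engine == "enumerate":
        if min(rows, cols) > ENUMERATION_LIMIT:
            raise ValueError(
                f"{min(rows, cols)} clusters per side exceeds the enumeration "
                f"limit ({ENUMERATION_LIMIT}); use engine='solver'"
            )
        pairs = _enumerate_best(sims)
    elif engine == "solver":
        ri, ci = linear_sum_assignment(-sims)
        pairs = sorted((int(i), int(j)) for i, j in zip(ri, ci) if sims[i, j] > 0)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    matched_src = {p[0] for p in pairs}
    matched_snk = {p[1] for p in pairs}
    return Matching(
        pairs,
        [i for i in range(rows) if i not in matched_src],
        [j for j in range(cols) if j not in matched_snk],
    )


def matching_objective(matching: Matching, sims: np.ndarray, theta: float = 0.0) -> float:
    """Sum of thresholded similarities over a matching's pairs."""
    s = np.where(np.asarray(sims, float) < theta, 0.0, np.asarray(sims, float))
    return float(sum(s[i, j] for i, j in matching.pairs))


def transition_links(p_t: Sequence[set], p_t1: Sequence[set], t: int = 0) -> list[TransitionLink]:
    """All electrode flows between two consecutive partitions.

    One link per cluster pair with at least one shared electrode; per
    source block the link counts sum to the block size, and likewise per
    sink block (partitions are exhaustive).
    """
    links = []
    for i, a in enumerate(p_t):
        sa = set(a)
        for j, b in enumerate(p_t1):
            inter = len(sa & set(b))
            if inter >= 1:
                links.append(
                    TransitionLink(
                        t=t,
                        source=i,
                        sink=j,
                        count=inter,
                        similarity=inter / len(sa | set(b)),
                    )
                )
    return links


# ---------------------------------------------------------------------------
# Dynamic-community assembly
# ---------------------------------------------------------------------------

def track_communities(
    clusterings: Sequence[TimestepClustering],
    node_ids: Sequence[str],
    method: Literal["greedy", "optimal"] = "optimal",
    theta: float = 0.1,
    palette: str = DEFAULT_PALETTE,
    engine: Literal["enumerate", "solver"] = "enumerate",
) -> DynamicCommunitySet:
    """Track per-timestep clusterings into persistent dynamic communities.

    A matched sink inherits its source's persistent id; an unmatched sink
    is a birth (fresh id) and an unmatched source a death.  Ids are
    allocated in order of first appearance (``dc0``, ``dc1``, ...).
    """
    if len(clusterings) < 1:
        raise ValueError("need at least one timestep")
    node_ids = [str(n) for n in node_ids]
    partitions = [c.partition(node_ids) for c in clusterings]

    next_id = 0

    def fresh() -> str:
        nonlocal next_id
        pid = f"dc{next_id}"
        next_id += 1
        return pid

    pids: list[list[str]] = [[fresh() for _ in partitions[0]]]
    all_links: list[list[TransitionLink]] = []
    for t in range(len(partitions) - 1):
        p_t, p_t1 = partitions[t], partitions[t + 1]
        if method == "greedy":
            matching = greedy_match(p_t, p_t1)
        elif method == "optimal":
            matching = optimal_match(p_t, p_t1, theta=theta, engine=engine)
        else:
            raise ValueError(f"unknown tracking method {method!r}")
        inherit = {j: pids[t][i] for i, j in matching.pairs}
        pids.append(
            [inherit.get(j, None) or fresh() for j in range(len(p_t1))]
        )
        all_links.append(transition_links(p_t, p_t1, t=t))

    blocks = [
        [
            ClusterBlock(t=t, i=i, members=frozenset(cluster), persistent_id=pids[t][i])
            for i, cluster in enumerate(partition)
        ]
        for t, partition in enumerate(partitions)
    ]
    dcs = DynamicCommunitySet(
        node_ids=node_ids,
        blocks=blocks,
        links=all_links,
        colors={},
        method=method,
        theta=theta,
        k_profiles=[(c.k, dict(c.likelihood)) for c in clusterings],
    )
    dcs.colors = assign_colors(dcs, palette)
    dcs.validate()
    return dcs


def assign_colors(dcs: DynamicCommunitySet, palette_name: str = DEFAULT_PALETTE) -> dict[str, str]:
    """Color persistent ids in order of first appearance.

    Beyond the palette size colors recycle (with a logged warning); one
    persistent id keeps one color for its whole lifetime.
    """
    palette = get_palette(palette_name)
    ids = dcs.persistent_ids()
    if len(ids) > len(palette):
        logger.warning(
            "%d dynamic communities exceed palette %s size %d; colors recycle",
            len(ids),
            palette_name,
            len(palette),
        )
    return {pid: palette[k % len(palette)] for k, pid in enumerate(ids)}
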