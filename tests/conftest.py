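"""Shared fixtures: small planted datasets and random tracked instances."""

from __future__ import annotations

import numpy as np
import pytest

import cortexflow as cf
from cortexflow.communities import TimestepClustering, _canonical_labels
from cortexflow.tracking import track_communities


def clustering_from_labels(labels: np.ndarray) -> TimestepClustering:
    """Wrap raw per-node labels as a TimestepClustering (flat likelihood)."""
    lab = _canonical_labels(np.asarray(labels))
    k = len(np.unique(lab))
    return TimestepClustering(labels=lab, k=k, likelihood={k: 1.0})


def dcs_from_label_matrix(labels: np.ndarray, method: str = "optimal", theta: float = 0.1):
    """Tracked community set built directly from a (N, T) label matrix."""
    n = labels.shape[0]
    node_ids = [f"e{i}" for i in range(n)]
    clusterings = [clustering_from_labels(labels[:, t]) for t in range(labels.shape[1])]
    return track_communities(clusterings, node_ids, method=method, theta=theta)


def random_partition(rng: np.random.Generator, node_ids: list[str], max_k: int) -> list[set[str]]:
    """Random exhaustive partition with between 1 and max_k non-empty parts."""
    k = int(rng.integers(1, max_k + 1))
    labels = rng.integers(0, k, size=len(node_ids))
    labels[rng.permutation(len(node_ids))[:k]] = np.arange(k)  # no empty part
    return [
        {node_ids[i] for i in np.flatnonzero(labels == c)} for c in range(k)
    ]


def random_dcs(rng: np.random.Generator, n_nodes: int = 12, n_timesteps: int = 4, max_k: int = 4):
    """Random tracked community set for ordering/rendering property tests."""
    node_ids = [f"e{i}" for i in range(n_nodes)]
    labels = np.empty((n_nodes, n_timesteps), dtype=int)
    for t in range(n_timesteps):
        parts = random_partition(rng, node_ids, max_k)
        for c, part in enumerate(parts):
            for n in part:
                labels[node_ids.index(n), t] = c
    return dcs_from_label_matrix(labels)


@pytest.fixture(scope="session")
def default_synthetic():
    """The default planted dataset: 54 electrodes, 30 timesteps."""
    return cf.generate(cf.SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def small_tracked():
    """Cheap tracked set + activation from planted labels (no consensus runs)."""
    spec = cf.SyntheticSpec(
        n_electrodes=12,
        n_timesteps=6,
        schedule=[((0, 3), "stable"), ((3, 6), "random")],
        seed=3,
    )
    net, act, layout, truth = cf.generate(spec)
    dcs = dcs_from_label_matrix(truth.labels)
    return dcs, act, layout, truth
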