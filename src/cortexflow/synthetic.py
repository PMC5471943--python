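"""Controlled synthetic dynamic networks with planted community schedules.

The default configuration is the controlled case study the package's test
surfaces are built around: 54 electrodes on a 9x6 grid over 30 timesteps,
three planted communities of three known activation modes (0.9, 0.6, 0.3),
stable over timesteps [0, 10) and [20, 30) and randomly reassigned per
electrode per timestep over [10, 20).  The correlation network is
materialized from the planted labels by a two-level weight model
(within-community weight 0.9, between 0.05) plus small truncated Gaussian
noise, which makes the planted structure cleanly recoverable by consensus
clustering during the stable intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .data_io import ActivationSeries, DynamicNetwork, ElectrodeLayout

Assignment = Literal["stable", "random"]


def default_schedule() -> list[tuple[tuple[int, int], Assignment]]:
    return [((0, 10), "stable"), ((10, 20), "random"), ((20, 30), "stable")]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-community generator."""

    n_electrodes: int = 54
    n_timesteps: int = 30
    n_communities: int = 3
    activation_modes: list[float] = field(default_factory=lambda: [0.9, 0.6, 0.3])
    schedule: list[tuple[tuple[int, int], Assignment]] = field(
        default_factory=default_schedule
    )
    within_weight: float = 0.9
    between_weight: float = 0.05
    noise_sd: float = 0.02
    contiguous: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.activation_modes) != self.n_communities:
            raise ValueError("one activation mode per community is required")
        for m in self.activation_modes:
            if not 0.0 <= m <= 1.0:
                raise ValueError("activation modes must lie in [0, 1]")
        if not self.within_weight > self.between_weight:
            raise ValueError("within_weight must exceed between_weight")
        spans = sorted(iv for iv, _ in self.schedule)
        cursor = 0
        for a, b in spans:
            if a != cursor or b <= a:
                raise ValueError(
                    f"schedule intervals must partition [0, {self.n_timesteps})"
                )
            cursor = b
        if cursor != self.n_timesteps:
            raise ValueError(
                f"schedule intervals must partition [0, {self.n_timesteps})"
            )


@dataclass
class GroundTruth:
    """Planted labels and activations, per electrode per timestep."""

    labels: np.ndarray  # (N, T) int
    activation: np.ndarray  # (N, T) float
    schedule: list[tuple[tuple[int, int], Assignment]]


def grid_layout(n_electrodes: int, spacing: float = 10.0) -> ElectrodeLayout:
    """Near-square grid of electrode coordinates (row-major ids e0, e1, ...)."""
    n_cols = int(math.ceil(math.sqrt(n_electrodes)))
    while n_electrodes % n_cols != 0 and n_cols < n_electrodes:
        n_cols += 1
    coords = {
        f"e{k}": (spacing * (k % n_cols), spacing * (k // n_cols))
        for k in range(n_electrodes)
    }
    return ElectrodeLayout(coords)


def _planted_partition(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Fixed community of each electrode during stable intervals.

    Electrodes split as evenly as possible; contiguous chunks in row-major
    grid order (spatially coherent bands) unless ``contiguous`` is off, in
    which case the even split is randomly permuted once.
    """
    n, k = spec.n_electrodes, spec.n_communities
    base = np.repeat(np.arange(k), n // k)
    base = np.concatenate([base, np.arange(n - base.size) % k]).astype(int)
    base.sort()
    if not spec.contiguous:
        base = base[rng.permutation(n)]
    return base


def _adjacency_from_labels(
    labels_t: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    n = labels_t.size
    same = labels_t[:, None] == labels_t[None, :]
    a = np.where(same, spec.within_weight, spec.between_weight).astype(float)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=(n, n))
        noise = (noise + noise.T) / 2.0
        a = np.maximum(a + noise, 0.0)
    np.fill_diagonal(a, 0.0)
    return a


def generate(
    spec: Optional[SyntheticSpec] = None,
) -> tuple[DynamicNetwork, ActivationSeries, ElectrodeLayout, GroundTruth]:
    """Generate the planted dynamic network, activations, layout and truth.

    Stable intervals reuse the fixed planted partition; random intervals
    draw an independent uniform community per electrode per timestep (and a
    uniformly drawn activation mode).  During stable intervals every
    electrode's activation is exactly its community's mode level.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0]))
    n, t_total, k = spec.n_electrodes, spec.n_timesteps, spec.n_communities
    planted = _planted_partition(spec, rng)

    labels = np.empty((n, t_total), dtype=int)
    activation = np.empty((n, t_total), dtype=float)
    modes = np.asarray(spec.activation_modes)
    for (a, b), kind in spec.schedule:
        for t in range(a, b):
            if kind == "stable":
                labels[:, t] = planted
                activation[:, t] = modes[planted]
            elif kind == "random":
                labels[:, t] = rng.integers(0, k, size=n)
                activation[:, t] = modes[rng.integers(0, k, size=n)]
            else:
                raise ValueError(f"unknown assignment kind {kind!r}")

    adjacency = np.stack(
        [_adjacency_from_labels(labels[:, t], spec, rng) for t in range(t_total)]
    )
    layout = grid_layout(n)
    node_ids = [f"e{i}" for i in range(n)]
    net = DynamicNetwork(node_ids, adjacency)
    truth = GroundTruth(labels=labels, activation=activation, schedule=list(spec.schedule))
    return net, ActivationSeries(activation), layout, truth


def generate_seizure_like(
    spec: Optional[SyntheticSpec] = None,
    focus: str = "e0",
    spread_rate: float = 0.0,
) -> tuple[DynamicNetwork, ActivationSeries, ElectrodeLayout, GroundTruth]:
    """Variant with a focal community spreading outward from one electrode.

    Demo generator loosely emulating focal-onset dynamics: a disc of radius
    ``spread_rate * t`` (grid units) around the focus electrode joins
    community 0 with activation ramping toward 1, while electrodes outside
    the disc keep the baseline planted structure.  ``spread_rate = 0``
    reduces exactly to :func:`generate`.
    """
    spec = spec or SyntheticSpec()
    net, act, layout, truth = generate(spec)
    if focus not in layout.coordinates:
        raise ValueError(f"focus electrode {focus!r} not in layout")
    if spread_rate == 0.0:
        return net, act, layout, truth
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5E]))
    node_ids = [f"e{i}" for i in range(spec.n_electrodes)]
    pos = np.asarray([layout.coordinates[nid] for nid in node_ids])
    fx, fy = layout.coordinates[focus]
    dist = np.hypot(pos[:, 0] - fx, pos[:, 1] - fy)

    labels = truth.labels.copy()
    activation = truth.activation.copy()
    t_total = spec.n_timesteps
    for t in range(t_total):
        captured = dist < spread_rate * t
        labels[captured, t] = 0
        ramp = min(1.0, 0.6 + 0.4 * t / max(t_total - 1, 1))
        activation[captured, t] = ramp
    adjacency = np.stack(
        [_adjacency_from_labels(labels[:, t], spec, rng) for t in range(t_total)]
    )
    net = DynamicNetwork(node_ids, adjacency)
    truth = GroundTruth(labels=labels, activation=activation, schedule=list(spec.schedule))
    return net, ActivationSeries(activation), layout, truth
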