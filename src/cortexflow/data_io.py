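"""Domain types and I/O for dynamic electrode correlation networks.

A *dynamic network* is an ordered sequence of symmetric, nonnegative
weighted adjacency matrices over one fixed electrode set — one matrix per
analysis timestep.  Weights are correlation magnitudes between electrode
signals.  This module provides the container types, text/HDF5 readers and
writers, construction of windowed correlation networks from raw
multichannel recordings, and the per-electrode activation statistic that
drives glyph opacity in the spatial views.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tolerance for accepting (and averaging away) input asymmetries
ASYMMETRY_TOL = 1e-6
#: tolerance used when validating stored matrices
SYMMETRY_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


class FormatError(ValueError):
    """Raised when a file's structure cannot be interpreted."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DynamicNetwork:
    """Sequence of weighted electrode graphs sharing one node set.

    Parameters
    ----------
    node_ids
        Ordered electrode identifiers; row/column order of every matrix.
    adjacency
        Array of shape ``(T, N, N)``; symmetric, nonnegative, zero diagonal.
    timestep_duration_ms
        Optional duration of one timestep, metadata only.
    """

    node_ids: list[str]
    adjacency: np.ndarray
    timestep_duration_ms: Optional[float] = None

    def __post_init__(self) -> None:
        self.node_ids = [str(n) for n in self.node_ids]
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_timesteps(self) -> int:
        return self.adjacency.shape[0]

    def validate(self) -> None:
        a = self.adjacency
        if a.ndim != 3:
            raise ValidationError("adjacency must be a T x N x N array")
        t, n, m = a.shape
        if t < 1:
            raise ValidationError("need at least one timestep")
        if n != m or n != len(self.node_ids):
            raise ValidationError(
                f"adjacency dimension {n}x{m} does not match "
                f"{len(self.node_ids)} node ids"
            )
        if len(set(self.node_ids)) != n:
            raise ValidationError("duplicate node ids")
        if not np.isfinite(a).all():
            raise ValidationError("non-finite weights")
        if (a < 0).any():
            raise ValidationError("negative edge weights")
        asym = np.abs(a - a.transpose(0, 2, 1)).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(f"adjacency asymmetry {asym:g} > {SYMMETRY_TOL}")
        diag = np.abs(a[:, np.arange(n), np.arange(n)]).max() if n else 0.0
        if diag > SYMMETRY_TOL:
            raise ValidationError("adjacency diagonal must be zero")


@dataclass
class ElectrodeLayout:
    """2-D electrode positions plus optional raster underlay/crop."""

    coordinates: dict[str, tuple[float, float]]
    background_image: Optional[str] = None
    crop_region: Optional[tuple[float, float, float, float]] = None  # xmin,ymin,xmax,ymax

    def __post_init__(self) -> None:
        self.coordinates = {
            str(k): (float(v[0]), float(v[1])) for k, v in self.coordinates.items()
        }
        for nid, (x, y) in self.coordinates.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValidationError(f"non-finite coordinate for electrode {nid}")

    def check_covers(self, node_ids: Sequence[str]) -> None:
        missing = [n for n in node_ids if n not in self.coordinates]
        if missing:
            raise ValidationError(f"missing coordinates for electrodes: {missing}")


@dataclass
class ActivationSeries:
    """Per-electrode, per-timestep activation level in [0, 1].

    ``values`` has shape ``(N, T)`` matching a :class:`DynamicNetwork`.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("activation values must be N x T")
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite activation")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValidationError("activation outside [0, 1]")

    def check_matches(self, net: DynamicNetwork) -> None:
        if self.values.shape != (net.n_nodes, net.n_timesteps):
            raise ValidationError(
                f"activation shape {self.values.shape} does not match network "
                f"({net.n_nodes}, {net.n_timesteps})"
            )


@dataclass
class SignalRecording:
    """Raw multichannel recording: ``samples`` is electrodes x time samples."""

    samples: np.ndarray
    sampling_rate: float
    window_length: int
    node_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be electrodes x samples")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.window_length < 2:
            raise ValidationError("window_length must be >= 2")
        if self.node_ids is not None:
            self.node_ids = [str(n) for n in self.node_ids]
            if len(self.node_ids) != self.samples.shape[0]:
                raise ValidationError("node_ids length does not match channels")

    def ids(self) -> list[str]:
        if self.node_ids is not None:
            return list(self.node_ids)
        return [f"e{i}" for i in range(self.samples.shape[0])]


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def window_starts(n_samples: int, window_length: int, overlap_fraction: float) -> list[int]:
    """Half-open analysis windows ``[s, s + window_length)``.

    The hop is ``round(window_length * (1 - overlap_fraction))`` samples,
    at least one.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValidationError("overlap_fraction must be in [0, 1)")
    if window_length > n_samples:
        raise ValidationError(
            f"window_length {window_length} exceeds recording length {n_samples}"
        )
    hop = max(1, int(round(window_length * (1.0 - overlap_fraction))))
    return list(range(0, n_samples - window_length + 1, hop))


def build_correlation_network(
    rec: SignalRecording, overlap_fraction: float = 0.0
) -> DynamicNetwork:
    """Build a dynamic network of absolute Pearson correlations.

    One timestep per (possibly overlapping) window; the edge weight between
    channels i and j is ``|r|`` of their windowed signals.  Constant
    channels within a window get weight 0 against every partner (a warning
    is logged): connectivity strength, not sign, is what downstream
    clustering consumes.
    """
    x = rec.samples
    starts = window_starts(x.shape[1], rec.window_length, overlap_fraction)
    n = x.shape[0]
    mats = np.zeros((len(starts), n, n))
    for t, s in enumerate(starts):
        w = x[:, s : s + rec.window_length]
        sd = w.std(axis=1)
        constant = sd == 0
        if constant.any():
            logger.warning(
                "window %d: %d constant channel(s) set to zero correlation",
                t,
                int(constant.sum()),
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(w)
        r = np.nan_to_num(r, nan=0.0)
        r[constant, :] = 0.0
        r[:, constant] = 0.0
        a = np.abs(r)
        a = np.clip((a + a.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(a, 0.0)
        mats[t] = a
    duration = rec.window_length / rec.sampling_rate * 1000.0
    return DynamicNetwork(rec.ids(), mats, timestep_duration_ms=duration)


def compute_activation(
    rec: SignalRecording,
    overlap_fraction: float = 0.0,
    mode: Literal["mean-abs", "rms"] = "mean-abs",
) -> ActivationSeries:
    """Per-electrode, per-window activation, min-max rescaled to [0, 1].

    The per-window statistic is either the mean absolute amplitude or the
    RMS amplitude; the rescaling is global over the whole recording so
    levels are comparable across electrodes and timesteps.  A constant
    recording maps to all zeros.
    """
    x = rec.samples
    starts = window_starts(x.shape[1], rec.window_length, overlap_fraction)
    stat = np.empty((x.shape[0], len(starts)))
    for t, s in enumerate(starts):
        w = x[:, s : s + rec.window_length]
        if mode == "mean-abs":
            stat[:, t] = np.abs(w).mean(axis=1)
        elif mode == "rms":
            stat[:, t] = np.sqrt((w**2).mean(axis=1))
        else:
            raise ValueError(f"unknown activation mode {mode!r}")
    lo, hi = stat.min(), stat.max()
    if hi - lo == 0:
        return ActivationSeries(np.zeros_like(stat))
    return ActivationSeries((stat - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# Network readers / writers
# ---------------------------------------------------------------------------

def read_dynamic_network(
    path: str | Path,
    format: Literal["long-edge-list", "adjacency-stack"],
    node_ids: Optional[Sequence[str]] = None,
    n_timesteps: Optional[int] = None,
) -> DynamicNetwork:
    """Read a dynamic network from disk.

    ``long-edge-list`` is delimited text with header ``t,i,j,w``; missing
    edges are weight 0 and a timestep with no rows is the empty graph.
    ``adjacency-stack`` is an HDF5 file with datasets ``adjacency``
    (T x N x N) and ``node_ids``.  Input asymmetries up to 1e-6 are
    symmetrized by averaging; larger ones, negative weights and unknown
    node ids are errors.  ``n_timesteps`` may extend the edge list with
    trailing empty timesteps beyond the largest t present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "adjacency-stack":
        with h5py.File(path, "r") as f:
            if "adjacency" not in f or "node_ids" not in f:
                raise FormatError("HDF5 stack needs 'adjacency' and 'node_ids'")
            adj = np.asarray(f["adjacency"], dtype=float)
            ids = [
                s.decode() if isinstance(s, bytes) else str(s) for s in f["node_ids"][()]
            ]
            duration = f.attrs.get("timestep_duration_ms", None)
        return DynamicNetwork(ids, adj, timestep_duration_ms=duration)
    if format != "long-edge-list":
        raise ValueError(f"unknown format {format!r}")

    df = pd.read_csv(path, dtype={"i": str, "j": str})
    expected = ["t", "i", "j", "w"]
    if list(df.columns[:4]) != expected:
        raise FormatError(f"edge list must have header {expected}, got {list(df.columns)}")
    if len(df) == 0:
        raise FormatError("edge list has no rows")
    if (df["w"] < 0).any():
        raise ValidationError("negative edge weight in edge list")
    if node_ids is None:
        ids = sorted(set(df["i"]) | set(df["j"]))
    else:
        ids = [str(n) for n in node_ids]
        unknown = (set(df["i"]) | set(df["j"])) - set(ids)
        if unknown:
            raise FormatError(f"unknown node id(s) in edge list: {sorted(unknown)}")
    index = {n: k for k, n in enumerate(ids)}
    n = len(ids)
    t_max = int(df["t"].max())
    t_total = max(t_max + 1, n_timesteps or 0)
    mats = np.zeros((t_total, n, n))
    seen: dict[tuple[int, int, int], float] = {}
    for t, i, j, w in df[["t", "i", "j", "w"]].itertuples(index=False):
        t = int(t)
        a, b = index[i], index[j]
        if a == b:
            if w != 0:
                raise ValidationError(f"self-loop with nonzero weight at t={t}, node {i}")
            continue
        direction = (t, a, b)
        if direction in seen:
            raise FormatError(f"duplicate edge row t={t}, {i}->{j}")
        seen[direction] = float(w)
        rev = (t, b, a)
        if rev in seen:
            other = seen[rev]
            if abs(other - w) > ASYMMETRY_TOL:
                raise ValidationError(
                    f"asymmetric weights for edge ({i},{j}) at t={t}: "
                    f"{other} vs {w}"
                )
            w = (other + w) / 2.0
        mats[t, a, b] = w
        mats[t, b, a] = w
    return DynamicNetwork(ids, mats)


def write_dynamic_network(
    net: DynamicNetwork,
    path: str | Path,
    format: Literal["long-edge-list", "adjacency-stack"],
) -> None:
    """Write a dynamic network in one of the two supported formats.

    Note the edge-list format drops isolated nodes; pass ``node_ids`` when
    re-reading if the node set must be preserved exactly.
    """
    path = Path(path)
    if format == "adjacency-stack":
        with h5py.File(path, "w") as f:
            f.create_dataset("adjacency", data=net.adjacency)
            f.create_dataset(
                "node_ids",
                data=np.array(net.node_ids, dtype=h5py.string_dtype()),
            )
            if net.timestep_duration_ms is not None:
                f.attrs["timestep_duration_ms"] = net.timestep_duration_ms
        return
    if format != "long-edge-list":
        raise ValueError(f"unknown format {format!r}")
    rows = []
    n = net.n_nodes
    for t in range(net.n_timesteps):
        a = net.adjacency[t]
        for i in range(n):
            for j in range(i + 1, n):
                if a[i, j] != 0:
                    rows.append((t, net.node_ids[i], net.node_ids[j], a[i, j]))
    pd.DataFrame(rows, columns=["t", "i", "j", "w"]).to_csv(path, index=False)


def read_layout(path: str | Path) -> ElectrodeLayout:
    """Read electrode coordinates from delimited text with header ``id,x,y``."""
    df = pd.read_csv(path, dtype={"id": str})
    if list(df.columns[:3]) != ["id", "x", "y"]:
        raise FormatError("layout file must have header id,x,y")
    return ElectrodeLayout({r.id: (r.x, r.y) for r in df.itertuples(index=False)})


def write_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    rows = [(nid, x, y) for nid, (x, y) in layout.coordinates.items()]
    pd.DataFrame(rows, columns=["id", "x", "y"]).to_csv(path, index=False)


def read_activation(path: str | Path) -> tuple[list[str], ActivationSeries]:
    """Read an activation table (rows = electrodes, columns = timesteps)."""
    df = pd.read_csv(path, index_col=0)
    return [str(i) for i in df.index], ActivationSeries(df.to_numpy(dtype=float))


def write_activation(
    node_ids: Sequence[str], activation: ActivationSeries, path: str | Path
) -> None:
    pd.DataFrame(
        activation.values,
        index=list(node_ids),
        columns=[str(t) for t in range(activation.values.shape[1])],
    ).to_csv(path)


# ---------------------------------------------------------------------------
# Dynamic-community JSON document
# ---------------------------------------------------------------------------

SCHEMA_TAG = "cortexflow-dynamic-communities/1"


def write_dynamic_communities(dcs, path: str | Path) -> None:
    """Serialize a tracked :class:`~cortexflow.tracking.DynamicCommunitySet`.

    The JSON document carries per-timestep partitions with persistent
    community ids, the transition links (electrode counts + Jaccard
    similarity), the color map and, when present, the per-timestep
    K-likelihood profiles.  ``read_dynamic_communities`` inverts it.
    """
    doc = {
        "schema": SCHEMA_TAG,
        "node_ids": list(dcs.node_ids),
        "method": dcs.method,
        "theta": dcs.theta,
        "timesteps": [
            {
                "t": t,
                "blocks": [
                    {
                        "i": b.i,
                        "persistent_id": b.persistent_id,
                        "members": sorted(b.members),
                    }
                    for b in blocks
                ],
            }
            for t, blocks in enumerate(dcs.blocks)
        ],
        "links": [
            {
                "t": t,
                "source": lk.source,
                "sink": lk.sink,
                "count": lk.count,
                "similarity": lk.similarity,
            }
            for t, links in enumerate(dcs.links)
            for lk in links
        ],
        "colors": dict(dcs.colors),
        "k_profiles": [
            {"t": t, "selected_k": k, "likelihood": {str(kk): v for kk, v in prof.items()}}
            for t, (k, prof) in enumerate(dcs.k_profiles)
        ]
        if dcs.k_profiles is not None
        else None,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_dynamic_communities(path: str | Path):
    """Read back a dynamic-community JSON document written by this module."""
    from .tracking import ClusterBlock, DynamicCommunitySet, TransitionLink

    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != SCHEMA_TAG:
        raise FormatError(f"unexpected schema tag {doc.get('schema')!r}")
    t_entries = sorted(doc["timesteps"], key=lambda e: e["t"])
    blocks = [
        [
            ClusterBlock(
                t=entry["t"],
                i=b["i"],
                members=frozenset(b["members"]),
                persistent_id=b["persistent_id"],
            )
            for b in entry["blocks"]
        ]
        for entry in t_entries
    ]
    links: list[list[TransitionLink]] = [[] for _ in range(max(len(blocks) - 1, 0))]
    for lk in doc["links"]:
        links[lk["t"]].append(
            TransitionLink(
                t=lk["t"],
                source=lk["source"],
                sink=lk["sink"],
                count=lk["count"],
                similarity=lk["similarity"],
            )
        )
    for ls in links:
        ls.sort(key=lambda lk: (lk.source, lk.sink))
    profiles = None
    if doc.get("k_profiles") is not None:
        profiles = [
            (e["selected_k"], {int(k): v for k, v in e["likelihood"].items()})
            for e in sorted(doc["k_profiles"], key=lambda e: e["t"])
        ]
    return DynamicCommunitySet(
        node_ids=list(doc["node_ids"]),
        blocks=blocks,
        links=links,
        colors=dict(doc["colors"]),
        method=doc["method"],
        theta=doc["theta"],
        k_profiles=profiles,
    )
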