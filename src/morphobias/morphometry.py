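"""The six morphological features and their pooling across neurons.

Three features summarise the whole arbor — the number of branch points, the
total dendritic length, and the *global angle* (how much each edge points
away from the soma) — and three are node- or segment-local: the branch
angle between sibling edges at a branch point, the arc length of segments
between consecutive critical nodes, and the *local angle* at pass-through
nodes (pi for a perfectly straight neurite). Angles are in radians in
[0, pi], lengths in micrometers.

Features are computed on the dendritic tree after equidistant resampling
(10 µm by default), so node-wise features are comparable across
reconstructions traced at different native resolutions; raw-tree
computation is available via ``resample_tree=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import ResampleSpec, iter_segments, resample, select_dendrites
from .swc_io import ROOT_PARENT, NeuronMorphology

__all__ = [
    "FEATURES",
    "GRANULARITY",
    "COVERAGE_FEATURES",
    "ANGLE_FEATURES",
    "FeatureSample",
    "FeatureTable",
    "count_branch_points",
    "total_length",
    "global_angles",
    "branch_angles",
    "segment_lengths",
    "local_angles",
    "extract_all",
    "pool",
]

#: the six features, in the order they are reported
FEATURES = (
    "n_branch_points",
    "total_length",
    "global_angle",
    "branch_angle",
    "segment_length",
    "local_angle",
)

GRANULARITY = {
    "n_branch_points": "per_neuron",
    "total_length": "per_neuron",
    "global_angle": "per_node",
    "branch_angle": "per_node",
    "segment_length": "per_segment",
    "local_angle": "per_node",
}

#: features measuring how much of the dendritic tree is covered
COVERAGE_FEATURES = ("n_branch_points", "total_length", "segment_length")
#: features measuring local/global geometry of the tree
ANGLE_FEATURES = ("global_angle", "branch_angle", "local_angle")


@dataclass
class FeatureSample:
    """Values of one feature together with the neuron each value came from."""

    feature: str
    granularity: str
    values: np.ndarray
    neuron_ids: np.ndarray  # parallel to values, dtype=object/str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=object)
        if self.values.shape != self.neuron_ids.shape:
            raise ValueError("values and neuron_ids must be parallel")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_neurons(self) -> int:
        return len(set(self.neuron_ids.tolist()))

    @staticmethod
    def concat(samples: Sequence["FeatureSample"]) -> "FeatureSample":
        if not samples:
            raise ValueError("cannot concatenate zero samples")
        feats = {s.feature for s in samples}
        if len(feats) != 1:
            raise ValueError(f"mixed features: {feats}")
        return FeatureSample(
            feature=samples[0].feature,
            granularity=samples[0].granularity,
            values=np.concatenate([s.values for s in samples]),
            neuron_ids=np.concatenate([s.neuron_ids for s in samples]),
        )


def _angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Row-wise angle between two stacks of vectors, clipped into [0, pi]."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = nu * nv
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...i,...i->...", u, v) / denom
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def count_branch_points(m: NeuronMorphology) -> int:
    """Number of non-root nodes with two or more children.

    A k-furcation counts once; stems emanating from the soma are not
    dendritic branching events, so the root never counts.
    """
    nc = m.n_children()
    nc[m.root] = 0
    return int(np.sum(nc >= 2))


def total_length(m: NeuronMorphology) -> float:
    """Sum of Euclidean edge lengths over the whole tree, in micrometers."""
    return float(m.edge_lengths().sum())


def global_angles(m: NeuronMorphology) -> FeatureSample:
    """Angle between each edge and the soma direction, one value per edge.

    For a node c with parent p the edge direction is pos(c) - pos(p) and
    the soma direction is soma - pos(p): pi means the edge grows radially
    away from the soma. Edges where either vector vanishes (e.g. the
    soma's own stems) contribute nothing.
    """
    soma = m.soma_position
    nonroot = np.flatnonzero(m.parent != ROOT_PARENT)
    p = m.parent[nonroot]
    u = m.xyz[nonroot] - m.xyz[p]
    v = soma[None, :] - m.xyz[p]
    ok = (np.linalg.norm(u, axis=1) > 0) & (np.linalg.norm(v, axis=1) > 0)
    vals = _angle(u[ok], v[ok])
    return FeatureSample(
        "global_angle", "per_node", vals, np.full(len(vals), m.source_id, dtype=object)
    )


def branch_angles(m: NeuronMorphology) -> FeatureSample:
    """Angles between sibling edges at each branch point.

    A k-furcation contributes all C(k, 2) child pairs; the root is never a
    branch point.
    """
    kids = m.children()
    vals = []
    for b in range(m.n_nodes):
        if b == m.root or len(kids[b]) < 2:
            continue
        ch = kids[b]
        for i in range(len(ch)):
            for j in range(i + 1, len(ch)):
                u = m.xyz[ch[i]] - m.xyz[b]
                v = m.xyz[ch[j]] - m.xyz[b]
                if np.linalg.norm(u) > 0 and np.linalg.norm(v) > 0:
                    vals.append(float(_angle(u, v)))
    arr = np.array(vals, dtype=float)
    return FeatureSample(
        "branch_angle", "per_node", arr, np.full(len(arr), m.source_id, dtype=object)
    )


def segment_lengths(m: NeuronMorphology) -> FeatureSample:
    """Arc length of each critical-to-critical segment.

    Segments partition the tree's edges, so these values sum to
    ``total_length`` exactly.
    """
    vals = []
    for path in iter_segments(m):
        pts = m.xyz[path]
        vals.append(float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()))
    arr = np.array(vals, dtype=float)
    return FeatureSample(
        "segment_length", "per_segment", arr, np.full(len(arr), m.source_id, dtype=object)
    )


def local_angles(m: NeuronMorphology) -> FeatureSample:
    """Angle at each pass-through node between its parent and child edges.

    Only nodes with a parent and exactly one child contribute; pi means the
    neurite runs perfectly straight through the node.
    """
    kids = m.children()
    nc = m.n_children()
    vals = []
    for n in range(m.n_nodes):
        if n == m.root or nc[n] != 1:
            continue
        p, c = m.parent[n], kids[n][0]
        u = m.xyz[p] - m.xyz[n]
        v = m.xyz[c] - m.xyz[n]
        if np.linalg.norm(u) > 0 and np.linalg.norm(v) > 0:
            vals.append(float(_angle(u, v)))
    arr = np.array(vals, dtype=float)
    return FeatureSample(
        "local_angle", "per_node", arr, np.full(len(arr), m.source_id, dtype=object)
    )


def extract_all(
    m: NeuronMorphology,
    spec: ResampleSpec = ResampleSpec(),
    resample_tree: bool = True,
) -> dict[str, FeatureSample]:
    """Select dendrites, resample, and compute all six features.

    Per-neuron features come back as singleton samples tagged with the
    neuron's source_id.
    """
    t = select_dendrites(m)
    if resample_tree:
        t = resample(t, spec)
    sid = np.array([m.source_id], dtype=object)
    return {
        "n_branch_points": FeatureSample(
            "n_branch_points", "per_neuron", np.array([count_branch_points(t)], dtype=float), sid
        ),
        "total_length": FeatureSample(
            "total_length", "per_neuron", np.array([total_length(t)]), sid
        ),
        "global_angle": global_angles(t),
        "branch_angle": branch_angles(t),
        "segment_length": segment_lengths(t),
        "local_angle": local_angles(t),
    }


class FeatureTable:
    """Extracted feature values for a set of neurons, keyed by source_id.

    Internally a dict ``(source_id, feature) -> ndarray`` for fast pooling,
    with CSV round-tripping (columns: source_id, feature, value) for the
    on-disk contract.
    """

    def __init__(self) -> None:
        self._data: dict[tuple[str, str], np.ndarray] = {}

    @classmethod
    def from_morphologies(
        cls,
        morphologies: Iterable[NeuronMorphology],
        spec: ResampleSpec = ResampleSpec(),
        resample_tree: bool = True,
    ) -> "FeatureTable":
        table = cls()
        for m in morphologies:
            table.add_neuron(m.source_id, extract_all(m, spec, resample_tree))
        return table

    def add_neuron(self, source_id: str, samples: Mapping[str, FeatureSample]) -> None:
        for feature, sample in samples.items():
            self._data[(source_id, feature)] = np.asarray(sample.values, dtype=float)

    @property
    def source_ids(self) -> list[str]:
        return sorted({sid for sid, _ in self._data})

    def values(self, source_id: str, feature: str) -> np.ndarray:
        return self._data[(source_id, feature)]

    def has_neuron(self, source_id: str) -> bool:
        return any(sid == source_id for sid, _ in self._data)

    def pool_neurons(self, source_ids: Sequence[str], feature: str) -> FeatureSample:
        """Concatenate one feature over the given neurons (pooled sample)."""
        if not len(source_ids):
            raise ValueError("empty neuron selection")
        parts, ids = [], []
        for sid in source_ids:
            v = self._data[(sid, feature)]
            parts.append(v)
            ids.append(np.full(len(v), sid, dtype=object))
        return FeatureSample(
            feature,
            GRANULARITY[feature],
            np.concatenate(parts) if parts else np.empty(0),
            np.concatenate(ids) if ids else np.empty(0, dtype=object),
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (sid, feature), vals in sorted(self._data.items()):
            for v in vals:
                rows.append((sid, feature, v))
        return pd.DataFrame(rows, columns=["source_id", "feature", "value"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, dtype={"source_id": str, "feature": str})
        table = cls()
        for (sid, feature), sub in df.groupby(["source_id", "feature"], sort=True):
            table._data[(sid, feature)] = sub["value"].to_numpy(dtype=float)
        # a neuron with no values for some feature (e.g. no pass-through
        # nodes, hence no local angles) has no rows; restore empties
        for sid in {s for s, _ in table._data}:
            for feature in FEATURES:
                table._data.setdefault((sid, feature), np.empty(0))
        return table


def pool(group, feature: str, method: str, table: FeatureTable) -> FeatureSample:
    """Pool one feature over all of a matched group's neurons with ``method``.

    Raises on an empty selection (method absent from the group).
    """
    members = group.members.get(method, ())
    if not members:
        raise ValueError(f"group {group.key}: no neurons with staining method {method!r}")
    return table.pool_neurons(list(members), feature)
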