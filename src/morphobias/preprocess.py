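"""Dendrite selection and equidistant arc-length resampling.

Reconstructed morphologies come with node spacings that depend on the
tracing software, which would leak into node-wise (per-node, per-segment)
features. Before feature extraction the dendritic tree is therefore
normalised: branch points and terminals are preserved exactly, and interior
nodes are re-placed on the original polyline at fixed arc-length steps
(10 micrometers by default), suppressing the last interior candidate of a
segment when it falls within one step of the downstream branch point or
terminal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .swc_io import DENDRITE_TYPES, ROOT_PARENT, NeuronMorphology

__all__ = [
    "ResampleSpec",
    "EmptyTreeError",
    "select_dendrites",
    "resample",
    "critical_nodes",
    "iter_segments",
]


class EmptyTreeError(ValueError):
    """The morphology has no dendrite points to analyse."""


@dataclass(frozen=True)
class ResampleSpec:
    """Equidistant resampling parameters.

    spacing : target arc-length distance between consecutive nodes, in
        micrometers. The community-standard normalisation step is 10 µm.
    """

    spacing: float = 10.0

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")


def select_dendrites(m: NeuronMorphology) -> NeuronMorphology:
    """Keep the soma/root and the basal+apical dendritic arbor.

    Axon and 'other' subtrees are dropped. Nodes on the path from a
    dendrite point up to the root are retained regardless of their own type,
    so the result is always a single rooted tree.

    Raises EmptyTreeError when no dendrite points exist.
    """
    is_dendrite = np.isin(m.structure, [int(t) for t in DENDRITE_TYPES])
    if not np.any(is_dendrite):
        raise EmptyTreeError(f"{m.source_id or 'morphology'}: no dendrite points")
    keep = is_dendrite.copy()
    keep[m.root] = True
    # propagate the keep mark to ancestors (children are ordered after parents)
    for i in range(m.n_nodes - 1, -1, -1):
        if keep[i] and m.parent[i] != ROOT_PARENT:
            keep[m.parent[i]] = True
    idx = np.flatnonzero(keep)
    rank = np.full(m.n_nodes, -1, dtype=np.int64)
    rank[idx] = np.arange(len(idx))
    new_parent = np.where(
        m.parent[idx] == ROOT_PARENT, ROOT_PARENT, rank[np.maximum(m.parent[idx], 0)]
    )
    return NeuronMorphology(
        ids=m.ids[idx],
        structure=m.structure[idx],
        xyz=m.xyz[idx],
        radius=m.radius[idx],
        parent=new_parent,
        source_id=m.source_id,
        soma_position_override=None
        if m.soma_position_override is None
        else m.soma_position_override.copy(),
    )


def critical_nodes(m: NeuronMorphology) -> np.ndarray:
    """Boolean mask of root, branch nodes (>=2 children) and terminals."""
    nc = m.n_children()
    mask = (nc >= 2) | (nc == 0)
    mask[m.root] = True
    return mask


def iter_segments(m: NeuronMorphology):
    """Yield each critical-to-critical segment as a list of node indices.

    A segment runs from one critical node (root, branch node) down through
    pass-through nodes to the next critical node (branch node or terminal).
    The first and last index of each yielded path are critical nodes.
    """
    kids = m.children()
    crit = critical_nodes(m)
    stack = [m.root]
    while stack:
        top = stack.pop()
        for child in reversed(kids[top]):
            path = [top, child]
            node = child
            while not crit[node]:
                node = kids[node][0]
                path.append(node)
            yield path
            stack.append(node)


def _arc_positions(xyz: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def resample(m: NeuronMorphology, spec: ResampleSpec = ResampleSpec()) -> NeuronMorphology:
    """Resample every segment to equidistant nodes along its polyline.

    Critical nodes (root, branch nodes, terminals) keep their exact
    coordinates. Interior nodes are placed on the original polyline at arc
    lengths ``spacing, 2*spacing, ...`` measured from the upstream critical
    node; the last candidate is suppressed when it lies within ``spacing``
    of the downstream critical node. Radii of interior nodes are linearly
    interpolated along arc length.
    """
    if not isinstance(spec, ResampleSpec):
        spec = ResampleSpec(float(spec))
    spacing = spec.spacing

    # output arrays built in topological order; root first
    out_xyz: list[np.ndarray] = [m.xyz[m.root].copy()]
    out_radius: list[float] = [float(m.radius[m.root])]
    out_structure: list[int] = [int(m.structure[m.root])]
    out_parent: list[int] = [ROOT_PARENT]
    # map original critical node -> output index (root seeded)
    out_index = {int(m.root): 0}

    for path in iter_segments(m):
        upstream, downstream = path[0], path[-1]
        pts = m.xyz[path]
        rad = m.radius[path]
        arc = _arc_positions(pts)
        total = float(arc[-1])

        interior = np.arange(spacing, total, spacing) if total > spacing else np.empty(0)
        # drop candidates coinciding with the downstream node (exact multiple)
        interior = interior[interior < total - 1e-9]
        if len(interior) and total - interior[-1] < spacing - 1e-9:
            interior = interior[:-1]

        parent_out = out_index[int(upstream)]
        seg_structure = int(m.structure[downstream])
        for s in interior:
            k = int(np.searchsorted(arc, s, side="right") - 1)
            k = min(k, len(arc) - 2)
            span = arc[k + 1] - arc[k]
            t = 0.0 if span <= 0 else (s - arc[k]) / span
            out_xyz.append(pts[k] * (1 - t) + pts[k + 1] * t)
            out_radius.append(float(rad[k] * (1 - t) + rad[k + 1] * t))
            out_structure.append(seg_structure)
            out_parent.append(parent_out)
            parent_out = len(out_xyz) - 1
        out_xyz.append(pts[-1].copy())
        out_radius.append(float(rad[-1]))
        out_structure.append(seg_structure)
        out_parent.append(parent_out)
        out_index[int(downstream)] = len(out_xyz) - 1

    n = len(out_xyz)
    return NeuronMorphology(
        ids=np.arange(1, n + 1, dtype=np.int64),
        structure=np.array(out_structure, dtype=np.int8),
        xyz=np.array(out_xyz, dtype=float),
        radius=np.array(out_radius, dtype=float),
        parent=np.array(out_parent, dtype=np.int64),
        source_id=m.source_id,
        soma_position_override=None
        if m.soma_position_override is None
        else m.soma_position_override.copy(),
    )
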