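"""Shared fixtures: hand-built toy trees and random-tree helpers."""

from __future__ import annotations

import numpy as np
import pytest

from morphobias.swc_io import NeuronMetadata, NeuronMorphology, Structure


def make_record(sid: str, **overrides) -> NeuronMetadata:
    """A fully labelled control/complete metadata record, overridable."""
    base = dict(
        source_id=sid,
        species="mouse",
        sex="male",
        age_class="adult",
        region_primary="hippocampus",
        region_secondary="CA1",
        region_tertiary="",
        celltype_primary="principal cell",
        celltype_secondary="pyramidal",
        celltype_tertiary="",
        staining_method="Golgi",
        integrity="complete",
        condition="control",
    )
    base.update(overrides)
    return NeuronMetadata(**base)


def build_tree(points, source_id="toy") -> NeuronMorphology:
    """Build a morphology from (structure, (x, y, z), radius, parent_row)
    tuples; parent_row is the 0-based row of the parent, -1 for the root."""
    return NeuronMorphology(
        ids=np.arange(1, len(points) + 1),
        structure=np.array([int(p[0]) for p in points], dtype=np.int8),
        xyz=np.array([p[1] for p in points], dtype=float),
        radius=np.array([p[2] for p in points], dtype=float),
        parent=np.array([p[3] for p in points], dtype=np.int64),
        source_id=source_id,
    )


D = Structure.BASAL_DENDRITE
S = Structure.SOMA


@pytest.fixture
def straight_path():
    """Soma plus a straight dendrite along +x, nodes every 10 µm (30 µm)."""
    return build_tree(
        [
            (S, (0, 0, 0), 5.0, -1),
            (D, (10, 0, 0), 0.5, 0),
            (D, (20, 0, 0), 0.5, 1),
            (D, (30, 0, 0), 0.5, 2),
        ]
    )


@pytest.fixture
def y_tree():
    """15 µm stem along +x to a bifurcation with two 10 µm branches."""
    return build_tree(
        [
            (S, (0, 0, 0), 5.0, -1),
            (D, (15, 0, 0), 0.5, 0),
            (D, (15 + 10 / np.sqrt(2), 10 / np.sqrt(2), 0), 0.5, 1),
            (D, (15 + 10 / np.sqrt(2), -10 / np.sqrt(2), 0), 0.5, 1),
        ]
    )


def random_dendrite_tree(rng: np.random.Generator, n_nodes: int = 40) -> NeuronMorphology:
    """A random rooted dendritic tree with irregular edge lengths.

    Built independently of the synthetic generator: each node attaches to
    a uniformly chosen earlier node, at a random offset.
    """
    pts = [(S, (0.0, 0.0, 0.0), 5.0, -1)]
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, i))
        off = rng.normal(scale=8.0, size=3)
        while np.linalg.norm(off) < 1e-3:
            off = rng.normal(scale=8.0, size=3)
        pos = tuple(np.asarray(pts[parent][1], dtype=float) + off)
        pts.append((D, pos, float(rng.uniform(0.2, 1.0)), parent))
    return build_tree(pts, source_id=f"rand{rng.integers(1 << 30)}")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q


def transform(m: NeuronMorphology, rotation=None, translation=None, scale=1.0):
    """Similarity-transform a morphology (rotate/translate/scale about the
    origin), returning a new tree."""
    xyz = m.xyz * scale
    if rotation is not None:
        xyz = xyz @ rotation.T
    if translation is not None:
        xyz = xyz + np.asarray(translation, dtype=float)
    return NeuronMorphology(
        ids=m.ids.copy(),
        structure=m.structure.copy(),
        xyz=xyz,
        radius=m.radius * scale,
        parent=m.parent.copy(),
        source_id=m.source_id,
    )
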