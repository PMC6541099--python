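"""Synthetic dendritic cohorts with known ground truth.

Trees are grown as a capped branching process from a soma at the origin: a
random number of dendritic stems, each carrying a bifurcating scaffold of
straight segments (bifurcation planes alternate with depth inside a
randomly rotated tree frame), with segments built from fixed-size steps
whose observed directions are the scaffold directions plus independent
per-edge von Mises-Fisher tracing noise. Step counts per segment are
shifted-Poisson, so the expected number of segments, branch points, the
expected total dendritic length and the expected local-angle cosine all
have closed forms — the features the pipeline measures can be checked
against the generative model.

Staining bias is modelled as a transform applied per staining label:
subtree pruning distal to branch points (partial labelling), uniform
coordinate scaling about the soma (differential tissue shrinkage), and
directional jitter (tracing noise). Pruning and scaling move the coverage
features (total length, branch counts, segment lengths); pure scaling
leaves all angle features untouched, mirroring the contrast the analysis
is designed to detect.

A generated cohort is a set of SWC trees plus a metadata table that the
cohort module reconstructs into exactly the planted matched groups, and a
ground-truth record of the planted per-method expectations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .swc_io import (
    ROOT_PARENT,
    NeuronMetadata,
    NeuronMorphology,
    Structure,
    write_metadata,
    write_swc,
)

__all__ = [
    "TreeModel",
    "BiasSpec",
    "GroupSpec",
    "CohortSpec",
    "Cohort",
    "generate_tree",
    "apply_bias",
    "generate_cohort",
    "default_cohort_spec",
]


@dataclass(frozen=True)
class TreeModel:
    """Parameters of the random dendritic-tree growth model.

    Trees are built on a branching *scaffold* of straight segments whose
    orientation pattern is deterministic within a randomly rotated tree
    frame (bifurcation planes alternate with depth, like an espaliered
    arbor); the observed node-to-node directions are the scaffold
    directions corrupted by independent per-edge tracing noise. Keeping
    the node-level noise independent across edges matters: pooled
    node-level rank tests assume weak between-neuron correlation, and a
    model with strong shared within-tree randomness (e.g. heavily random
    topology or accumulated meander) would violate their nominal level
    regardless of implementation.

    branch_prob : probability that a segment ends in a bifurcation (below
        the depth cap); expected offspring per segment is 2*branch_prob.
        The default 1 gives every tree the same topology: a full binary
        arbor to the depth cap.
    mean_segment_length : mean segment arc length in µm. Segments are
        ``1 + Poisson(mean/step - 1)`` steps of ``step_size`` µm, so the
        mean must be at least one step.
    step_size : µm between consecutive nodes as grown (equal to the
        standard resampling spacing, so unbiased trees are fixed points
        of the resampler).
    step_concentration : von Mises-Fisher concentration of each scaffold
        step about the previous one; the near-straight default keeps the
        scaffold free of accumulated meander.
    tracing_concentration : von Mises-Fisher concentration of each
        *observed* edge direction about its scaffold direction —
        independent per edge. For two consecutive edges the expected
        cosine of the local angle's deviation has the closed form
        A(k_tr)^2 * A(k_step) with A(k) = coth(k) - 1/k, used for
        calibration.
    branch_angle_mean / branch_angle_sd : radians; at a bifurcation each
        child's scaffold deviates from the parent direction by about half
        the mean, on opposite sides of the depth's bifurcation plane.
    max_depth : branching generations after which segments always
        terminate (guarantees a finite tree).
    n_stems : dendritic stems leaving the soma — a fixed count or an
        inclusive (lo, hi) range sampled uniformly per tree (at most 6;
        stem directions are fixed in the tree frame). Stems are iid
        subtrees with identical node-value profiles, so a random stem
        count gives per-neuron features (total length, branch count)
        genuine between-neuron variance without correlating the pooled
        node-level values.
    """

    branch_prob: float = 1.0
    mean_segment_length: float = 40.0
    step_size: float = 10.0
    step_concentration: float = 10_000.0
    tracing_concentration: float = 40.0
    branch_angle_mean: float = 1.0
    branch_angle_sd: float = 0.1
    max_depth: int = 2
    n_stems: int | tuple[int, int] = (2, 4)
    node_radius: float = 0.5
    soma_radius: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.branch_prob <= 1:
            raise ValueError(f"branch_prob must be in [0, 1], got {self.branch_prob}")
        if self.mean_segment_length < self.step_size:
            raise ValueError("mean_segment_length must be at least one step")
        if self.step_size <= 0 or self.step_concentration <= 0:
            raise ValueError("step_size and step_concentration must be positive")
        if self.tracing_concentration <= 0:
            raise ValueError("tracing_concentration must be positive")
        lo, hi = self.stem_range
        if self.max_depth < 0 or not 1 <= lo <= hi <= 6:
            raise ValueError("max_depth must be >= 0 and n_stems in 1..6")
        if 2 * self.branch_prob >= 1 and self.max_depth > 25:
            raise ValueError(
                "supercritical branching with a deep cap would explode "
                f"(2*branch_prob={2 * self.branch_prob}, max_depth={self.max_depth})"
            )

    # -- closed-form expectations used for calibration and testing -------

    @property
    def stem_range(self) -> tuple[int, int]:
        if isinstance(self.n_stems, tuple):
            return self.n_stems
        return (self.n_stems, self.n_stems)

    @property
    def mean_stems(self) -> float:
        lo, hi = self.stem_range
        return (lo + hi) / 2.0

    def expected_segment_count(self) -> float:
        """E[#segments] = E[n_stems] * sum_{d=0}^{max_depth} (2 p)^d."""
        r = 2.0 * self.branch_prob
        if r == 1.0:
            s = self.max_depth + 1
        else:
            s = (1 - r ** (self.max_depth + 1)) / (1 - r)
        return self.mean_stems * s

    def expected_branch_points(self) -> float:
        """E[#branch points] = p * E[segments that may still branch]."""
        r = 2.0 * self.branch_prob
        if r == 1.0:
            s = self.max_depth
        else:
            s = (1 - r**self.max_depth) / (1 - r)
        return self.branch_prob * self.mean_stems * s

    def expected_total_length(self) -> float:
        """E[total length] = E[#segments] * mean segment length (exact:
        step counts are independent of the branching structure)."""
        return self.expected_segment_count() * self.mean_segment_length

    def expected_local_angle_cosine(self) -> float:
        """Exact E[cos(pi - local angle)] at interior scaffold nodes.

        The two edges meeting at a pass-through node are independent vMF
        draws about consecutive scaffold directions, themselves one vMF
        step apart, so by iterated expectation the expected dot product is
        A(k_tr)^2 * A(k_step) with A(k) = coth(k) - 1/k.
        """

        def a(k: float) -> float:
            return 1 / math.tanh(k) - 1 / k

        return a(self.tracing_concentration) ** 2 * a(self.step_concentration)

    def expected_local_angle(self) -> float:
        """First-order mean local angle: pi - arccos of the expected
        deviation cosine (the calibration level of neurite straightness)."""
        return math.pi - math.acos(min(1.0, self.expected_local_angle_cosine()))


@dataclass(frozen=True)
class BiasSpec:
    """Per-staining-label measurement-bias transform.

    length_scale : multiplies all coordinates about the soma (models
        differential tissue shrinkage).
    prune_prob : probability of dropping each subtree distal to a branch
        point (models partial labelling).
    angle_jitter : sd (radians, small-angle) of direction noise added to
        every edge (models tracing noise); lengths are preserved.
    """

    length_scale: float = 1.0
    prune_prob: float = 0.0
    angle_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not self.length_scale > 0:
            raise ValueError(f"length_scale must be positive, got {self.length_scale}")
        if not 0 <= self.prune_prob < 1:
            raise ValueError(f"prune_prob must be in [0, 1), got {self.prune_prob}")
        if self.angle_jitter < 0:
            raise ValueError(f"angle_jitter must be >= 0, got {self.angle_jitter}")

    @property
    def is_identity(self) -> bool:
        return self.length_scale == 1.0 and self.prune_prob == 0.0 and self.angle_jitter == 0.0


def _sample_vmf(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One draw from the 3-D von Mises-Fisher distribution around mu.

    Uses the closed-form inverse CDF of the cosine in 3-D:
    w = 1 + log(u + (1-u) e^{-2 kappa}) / kappa.
    """
    u = max(rng.random(), 1e-300)
    w = 1.0 + math.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
    w = max(-1.0, min(1.0, w))
    # orthonormal basis perpendicular to mu
    helper = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    s = math.sqrt(max(0.0, 1.0 - w * w))
    return w * mu + s * (math.cos(theta) * e1 + math.sin(theta) * e2)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * float(np.dot(axis, v)) * (1.0 - math.cos(angle))
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A (Haar-distributed) random orthonormal frame via QR."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q


def generate_tree(
    model: TreeModel, seed: int | np.random.Generator | None = None, source_id: str = ""
) -> NeuronMorphology:
    """Grow one random dendritic tree; reproducible per seed.

    The soma (type 1) sits at the origin; all other nodes are basal
    dendrite (type 3) with constant radius, consecutive nodes one step
    apart. Stem directions and bifurcation planes are deterministic in a
    randomly rotated tree frame; randomness enters through the frame,
    segment step counts, branch-angle draws, scaffold meander and the
    per-edge tracing noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = model.mean_segment_length / model.step_size - 1.0

    frame = _random_rotation(rng)  # columns: tree-frame axes
    stem_dirs = [
        frame[:, 2], -frame[:, 2], frame[:, 0], -frame[:, 0], frame[:, 1], -frame[:, 1]
    ]

    xyz = [np.zeros(3)]
    radius = [model.soma_radius]
    structure = [int(Structure.SOMA)]
    parent = [ROOT_PARENT]

    lo, hi = model.stem_range
    n_stems = int(rng.integers(lo, hi + 1))
    # stack of (parent index, scaffold direction, depth)
    stack = [(0, stem_dirs[i], 0) for i in range(n_stems)]
    while stack:
        par, direction, depth = stack.pop()
        n_steps = 1 + int(rng.poisson(lam))
        for _ in range(n_steps):
            direction = _sample_vmf(direction, model.step_concentration, rng)
            observed = _sample_vmf(direction, model.tracing_concentration, rng)
            xyz.append(xyz[par] + model.step_size * observed)
            radius.append(model.node_radius)
            structure.append(int(Structure.BASAL_DENDRITE))
            parent.append(par)
            par = len(xyz) - 1
        if depth < model.max_depth and rng.random() < model.branch_prob:
            # bifurcation plane: spanned by the parent direction and the
            # depth-alternating frame axis (projected perpendicular)
            ref = frame[:, depth % 3]
            axis = np.cross(direction, ref)
            norm = np.linalg.norm(axis)
            if norm < 1e-6:  # scaffold happens to align with the axis
                axis = np.cross(direction, frame[:, (depth + 1) % 3])
                norm = np.linalg.norm(axis)
            axis /= norm
            half = model.branch_angle_mean / 2.0
            for sign_ in (1.0, -1.0):
                delta = abs(rng.normal(half, model.branch_angle_sd / math.sqrt(2.0)))
                child_dir = _rotate_about(direction, axis, sign_ * delta)
                child_dir /= np.linalg.norm(child_dir)
                stack.append((par, child_dir, depth + 1))

    n = len(xyz)
    return NeuronMorphology(
        ids=np.arange(1, n + 1, dtype=np.int64),
        structure=np.array(structure, dtype=np.int8),
        xyz=np.array(xyz, dtype=float),
        radius=np.array(radius, dtype=float),
        parent=np.array(parent, dtype=np.int64),
        source_id=source_id,
    )


def apply_bias(
    m: NeuronMorphology,
    bias: BiasSpec,
    seed: int | np.random.Generator | None = None,
) -> NeuronMorphology:
    """Apply a staining-bias transform: prune, jitter, then scale.

    With the identity bias the input is returned unchanged (same
    coordinates). Pruning drops each subtree hanging off a branch point
    independently with ``prune_prob`` (stems always survive, so the result
    is a valid tree); jitter perturbs each edge direction while preserving
    edge lengths; scaling multiplies all coordinates about the soma.
    """
    if bias.is_identity:
        return m.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = m.copy()

    if bias.prune_prob > 0:
        nc = out.n_children()
        keep = np.ones(out.n_nodes, dtype=bool)
        for i in range(out.n_nodes):
            p = out.parent[i]
            if p == ROOT_PARENT:
                continue
            if not keep[p]:
                keep[i] = False
                continue
            # child of a branch point: candidate pruning site
            if p != out.root and nc[p] >= 2 and rng.random() < bias.prune_prob:
                keep[i] = False
        idx = np.flatnonzero(keep)
        rank = np.full(out.n_nodes, -1, dtype=np.int64)
        rank[idx] = np.arange(len(idx))
        new_parent = np.where(
            out.parent[idx] == ROOT_PARENT, ROOT_PARENT, rank[np.maximum(out.parent[idx], 0)]
        )
        out = NeuronMorphology(
            ids=out.ids[idx],
            structure=out.structure[idx],
            xyz=out.xyz[idx],
            radius=out.radius[idx],
            parent=new_parent,
            source_id=out.source_id,
        )

    if bias.angle_jitter > 0:
        xyz = out.xyz.copy()
        for i in range(out.n_nodes):
            p = out.parent[i]
            if p == ROOT_PARENT:
                continue
            e = out.xyz[i] - out.xyz[p]
            norm = np.linalg.norm(e)
            if norm == 0:
                xyz[i] = xyz[p]
                continue
            d = e / norm + bias.angle_jitter * rng.standard_normal(3)
            d /= np.linalg.norm(d)
            xyz[i] = xyz[p] + norm * d
        out = NeuronMorphology(
            ids=out.ids,
            structure=out.structure,
            xyz=xyz,
            radius=out.radius,
            parent=out.parent,
            source_id=out.source_id,
        )

    if bias.length_scale != 1.0:
        soma = out.xyz[out.root].copy()
        xyz = soma + bias.length_scale * (out.xyz - soma)
        out = NeuronMorphology(
            ids=out.ids,
            structure=out.structure,
            xyz=xyz,
            radius=out.radius,
            parent=out.parent,
            source_id=out.source_id,
        )
    return out


def pruned_expected_length_factor(model: TreeModel, prune_prob: float) -> float:
    """E[total length after pruning] / E[total length before].

    A segment at branching depth d survives pruning iff all d branch-child
    edges above it survive, each independently with probability 1-q, so the
    expected surviving length replaces (2p)^d by (2p(1-q))^d in the
    branching-process sum.
    """
    p, q, dmax = model.branch_prob, prune_prob, model.max_depth

    def geom(r: float, top: int) -> float:
        return top + 1 if r == 1.0 else (1 - r ** (top + 1)) / (1 - r)

    return geom(2 * p * (1 - q), dmax) / geom(2 * p, dmax)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

_DEFAULT_KEY = {
    "species": "mouse",
    "sex": "male",
    "age_class": "adult",
    "region_primary": "hippocampus",
    "region_secondary": "CA1",
    "region_tertiary": "",
    "celltype_primary": "principal cell",
    "celltype_secondary": "pyramidal",
    "celltype_tertiary": "",
}


@dataclass(frozen=True)
class GroupSpec:
    """One planted matched group: a metadata key, methods with sizes, a
    tree model, and a bias per method."""

    key: Mapping[str, str]
    methods: Mapping[str, int]  # staining method -> n neurons
    tree_model: TreeModel = TreeModel()
    biases: Mapping[str, BiasSpec] = field(default_factory=dict)
    strain: str | None = None

    def bias_for(self, method: str) -> BiasSpec:
        return self.biases.get(method, BiasSpec())


@dataclass(frozen=True)
class CohortSpec:
    """A full synthetic study: groups plus the master seed."""

    groups: Sequence[GroupSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.groups:
            if any(n < 1 for n in g.methods.values()):
                raise ValueError("every method needs at least one neuron")


@dataclass
class Cohort:
    """Generated cohort: morphologies keyed by source_id, metadata records,
    and the planted ground truth."""

    morphologies: dict
    metadata: list
    truth: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        swc_dir = out / "swc"
        swc_dir.mkdir(exist_ok=True)
        for sid, m in self.morphologies.items():
            write_swc(m, swc_dir / f"{sid}.swc")
        write_metadata(self.metadata, out / "metadata.csv")
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))


def default_cohort_spec(
    n_groups: int = 2,
    n_per_method: int = 10,
    methods: Sequence[str] = ("Golgi", "biocytin"),
    biases: Mapping[str, BiasSpec] | None = None,
    tree_model: TreeModel = TreeModel(),
    seed: int = 0,
) -> CohortSpec:
    """A compact study design: ``n_groups`` matched groups distinguished by
    brain region, each comparing the same staining methods at equal n.

    With ``biases=None`` every method is unbiased (a null cohort).
    """
    regions = [
        ("hippocampus", "CA1"),
        ("hippocampus", "CA3"),
        ("neocortex", "somatosensory"),
        ("neocortex", "primary visual"),
        ("main olfactory bulb", "granule layer"),
        ("amygdala", "basolateral amygdala"),
    ]
    groups = []
    for gi in range(n_groups):
        rp, rs = regions[gi % len(regions)]
        key = dict(_DEFAULT_KEY)
        key["region_primary"], key["region_secondary"] = rp, rs
        if gi >= len(regions):
            key["age_class"] = "young"
        groups.append(
            GroupSpec(
                key=key,
                methods={m: n_per_method for m in methods},
                tree_model=tree_model,
                biases=dict(biases) if biases else {},
            )
        )
    return CohortSpec(groups=groups, seed=seed)


def generate_cohort(spec: CohortSpec, out_dir=None) -> Cohort:
    """Generate all trees and metadata for a cohort spec.

    Neuron seeds derive from (spec seed, group index, method index, neuron
    index), so any single neuron is reproducible independently of
    generation order. The ground-truth record stores each method's bias
    parameters and planted expectations, and each method pair's expected
    total-length difference, keyed per group.
    """
    morphologies: dict[str, NeuronMorphology] = {}
    metadata: list[NeuronMetadata] = []
    truth: dict = {"seed": spec.seed, "groups": []}

    for gi, group in enumerate(spec.groups):
        model = group.tree_model
        methods = sorted(group.methods)
        group_truth = {
            "index": gi,
            "key": dict(group.key),
            "methods": {},
            "expected_total_length_diff": {},
        }
        for mi, method in enumerate(methods):
            bias = group.bias_for(method)
            expected_length = (
                model.expected_total_length()
                * bias.length_scale
                * pruned_expected_length_factor(model, bias.prune_prob)
            )
            group_truth["methods"][method] = {
                "n": group.methods[method],
                "length_scale": bias.length_scale,
                "prune_prob": bias.prune_prob,
                "angle_jitter": bias.angle_jitter,
                "expected_total_length": expected_length,
            }
            for ni in range(group.methods[method]):
                sid = f"g{gi}_{method.replace(' ', '-')}_{ni:03d}"
                rng = np.random.default_rng([spec.seed, gi, mi, ni])
                tree = generate_tree(model, rng, source_id=sid)
                tree = apply_bias(tree, bias, rng)
                tree.source_id = sid
                morphologies[sid] = tree
                metadata.append(
                    NeuronMetadata(
                        source_id=sid,
                        species=group.key["species"],
                        sex=group.key["sex"],
                        age_class=group.key["age_class"],
                        region_primary=group.key["region_primary"],
                        region_secondary=group.key["region_secondary"],
                        region_tertiary=group.key.get("region_tertiary", ""),
                        celltype_primary=group.key["celltype_primary"],
                        celltype_secondary=group.key["celltype_secondary"],
                        celltype_tertiary=group.key.get("celltype_tertiary", ""),
                        staining_method=method,
                        integrity="complete",
                        condition="control",
                        strain=group.strain,
                        archive="synthetic",
                    )
                )
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                a, b = methods[i], methods[j]
                group_truth["expected_total_length_diff"][f"{a} vs {b}"] = (
                    group_truth["methods"][b]["expected_total_length"]
                    - group_truth["methods"][a]["expected_total_length"]
                )
        truth["groups"].append(group_truth)

    cohort = Cohort(morphologies=morphologies, metadata=metadata, truth=truth)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
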