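"""Reading, validating and writing SWC neuron reconstructions and metadata.

The SWC format describes a neuron as a rooted tree: one whitespace-delimited
data line per point with columns ``id type x y z radius parent``, ``#``
starting comment lines, and parent ``-1`` marking the root. Coordinates and
radii are in micrometers (the neuromorpho.org convention). Structure type
codes 1-4 are soma, axon, basal dendrite and apical dendrite; anything else
is kept as ``other`` and filtered later by preprocessing.

Morphologies are held column-wise in numpy arrays, ordered parent-before-
child, with parents stored as positional indices (-1 for the root).
"""

from __future__ import annotations

import io
import math
from collections import deque
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

ROOT_PARENT = -1

__all__ = [
    "Structure",
    "MorphPoint",
    "NeuronMorphology",
    "NeuronMetadata",
    "SWCError",
    "SWCParseError",
    "SWCStructureError",
    "MetadataError",
    "read_swc",
    "write_swc",
    "read_metadata",
    "write_metadata",
    "staining_class_of",
    "STAINING_CLASSES",
    "MATCHING_ATTRIBUTES",
    "METADATA_COLUMNS",
]


class SWCError(ValueError):
    """Base class for SWC reading problems."""


class SWCParseError(SWCError):
    """A data line could not be parsed (reported with its line number)."""


class SWCStructureError(SWCError):
    """The point set does not form a single valid rooted tree."""


class MetadataError(ValueError):
    """The metadata table violates its contract."""


class Structure(IntEnum):
    """SWC structure codes; codes above 4 collapse to OTHER."""

    SOMA = 1
    AXON = 2
    BASAL_DENDRITE = 3
    APICAL_DENDRITE = 4
    OTHER = 5

    @classmethod
    def from_code(cls, code: int) -> "Structure":
        return cls(code) if code in (1, 2, 3, 4) else cls.OTHER


DENDRITE_TYPES = (Structure.BASAL_DENDRITE, Structure.APICAL_DENDRITE)


@dataclass(frozen=True)
class MorphPoint:
    """One reconstruction point: position/radius in micrometers."""

    id: int
    structure: Structure
    position: np.ndarray  # shape (3,)
    radius: float
    parent_id: int  # original id of the parent, or -1

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise SWCStructureError(f"point {self.id}: position must be a finite 3-vector")
        if not math.isfinite(self.radius) or self.radius < 0:
            raise SWCStructureError(f"point {self.id}: radius must be finite and >= 0")
        object.__setattr__(self, "position", pos)


@dataclass
class NeuronMorphology:
    """A single-rooted reconstruction tree stored column-wise.

    ``parent`` holds positional indices into the arrays (root gets -1) and
    nodes are ordered so every parent precedes its children. ``ids`` keeps
    the original SWC node identifiers for round-tripping.
    """

    ids: np.ndarray  # (n,) int
    structure: np.ndarray  # (n,) int, Structure values
    xyz: np.ndarray  # (n, 3) float, micrometers
    radius: np.ndarray  # (n,) float, micrometers
    parent: np.ndarray  # (n,) int positional index, -1 at root
    source_id: str = ""
    soma_position_override: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.structure = np.asarray(self.structure, dtype=np.int8)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.validate()

    # -- basic structure -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == ROOT_PARENT)[0])

    @property
    def soma_position(self) -> np.ndarray:
        """Soma reference point for the global angle.

        The root position, or (for a multi-point soma collapsed on read)
        the centroid of the original type-1 points.
        """
        if self.soma_position_override is not None:
            return self.soma_position_override
        return self.xyz[self.root]

    def children(self) -> list[list[int]]:
        """Per-node child index lists."""
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p != ROOT_PARENT:
                kids[p].append(i)
        return kids

    def n_children(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(counts, self.parent[self.parent != ROOT_PARENT], 1)
        return counts

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of each non-root node's edge to its parent."""
        nonroot = np.flatnonzero(self.parent != ROOT_PARENT)
        return np.linalg.norm(self.xyz[nonroot] - self.xyz[self.parent[nonroot]], axis=1)

    def points(self) -> Iterator[MorphPoint]:
        for i in range(self.n_nodes):
            pid = ROOT_PARENT if self.parent[i] == ROOT_PARENT else int(self.ids[self.parent[i]])
            yield MorphPoint(
                id=int(self.ids[i]),
                structure=Structure.from_code(int(self.structure[i])),
                position=self.xyz[i].copy(),
                radius=float(self.radius[i]),
                parent_id=pid,
            )

    def validate(self) -> None:
        n = self.n_nodes
        if n == 0:
            raise SWCStructureError("empty morphology")
        if self.xyz.shape != (n, 3):
            raise SWCStructureError("xyz must have shape (n, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise SWCStructureError("non-finite coordinates")
        if np.any(self.radius < 0) or not np.all(np.isfinite(self.radius)):
            raise SWCStructureError("radii must be finite and non-negative")
        roots = np.flatnonzero(self.parent == ROOT_PARENT)
        if len(roots) != 1:
            raise SWCStructureError(f"expected exactly one root, found {len(roots)}")
        nonroot = self.parent != ROOT_PARENT
        bad = nonroot & ((self.parent < 0) | (self.parent >= n))
        if np.any(bad):
            raise SWCStructureError("parent index out of range")
        # parent-before-child ordering rules out cycles and disconnection
        if np.any(self.parent[nonroot] >= np.flatnonzero(nonroot)):
            raise SWCStructureError("nodes are not ordered parent-before-child")

    def copy(self) -> "NeuronMorphology":
        return NeuronMorphology(
            ids=self.ids.copy(),
            structure=self.structure.copy(),
            xyz=self.xyz.copy(),
            radius=self.radius.copy(),
            parent=self.parent.copy(),
            source_id=self.source_id,
            soma_position_override=None
            if self.soma_position_override is None
            else self.soma_position_override.copy(),
        )


# ---------------------------------------------------------------------------
# SWC reading
# ---------------------------------------------------------------------------


def _as_text_lines(source) -> list[str]:
    if isinstance(source, Path):
        return source.read_text().splitlines()
    if isinstance(source, str):
        if "\n" not in source and Path(source).is_file():
            return Path(source).read_text().splitlines()
        return source.splitlines()
    return source.read().splitlines()


def read_swc(source, source_id: str = "") -> NeuronMorphology:
    """Parse an SWC text stream, path or string into a validated morphology.

    Node ids are preserved; node order is normalised to parent-before-child.
    Multi-point somata (several contiguous type-1 points) are collapsed to a
    single root at their centroid, with their dendritic children reparented
    to that root; the centroid is kept as the soma reference position.

    Raises
    ------
    SWCParseError
        A malformed data line (reported with its 1-based line number).
    SWCStructureError
        Orphan parent ids, multiple roots, cycles, or duplicate ids.
    """
    rows = []
    for lineno, raw in enumerate(_as_text_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            rows.append(
                (
                    int(parts[0]),
                    int(parts[1]),
                    float(parts[2]),
                    float(parts[3]),
                    float(parts[4]),
                    float(parts[5]),
                    int(parts[6]),
                )
            )
        except ValueError as exc:
            raise SWCParseError(f"line {lineno}: {exc}") from None
    if not rows:
        raise SWCParseError("no data lines found")

    ids = np.array([r[0] for r in rows], dtype=np.int64)
    codes = np.array([r[1] for r in rows], dtype=np.int64)
    xyz = np.array([[r[2], r[3], r[4]] for r in rows], dtype=float)
    radius = np.array([r[5] for r in rows], dtype=float)
    parent_ids = np.array([r[6] for r in rows], dtype=np.int64)

    if len(np.unique(ids)) != len(ids):
        raise SWCStructureError("duplicate node ids")
    id_to_idx = {int(i): k for k, i in enumerate(ids)}

    structure = np.array([Structure.from_code(int(c)) for c in codes], dtype=np.int8)

    # collapse a multi-point soma to one root point at the centroid
    soma_override = None
    soma_idx = np.flatnonzero(structure == Structure.SOMA)
    if len(soma_idx) > 1:
        centroid = xyz[soma_idx].mean(axis=0)
        mean_radius = float(radius[soma_idx].mean())
        keep = int(soma_idx[0])
        soma_id_set = {int(ids[i]) for i in soma_idx}
        xyz = xyz.copy()
        xyz[keep] = centroid
        radius = radius.copy()
        radius[keep] = mean_radius
        parent_ids = parent_ids.copy()
        parent_ids[keep] = ROOT_PARENT
        # reparent every child of any soma point onto the kept root
        for k in range(len(ids)):
            if k in soma_idx:
                continue
            if int(parent_ids[k]) in soma_id_set:
                parent_ids[k] = ids[keep]
        mask = np.ones(len(ids), dtype=bool)
        mask[soma_idx[1:]] = False
        ids, structure, xyz, radius, parent_ids = (
            ids[mask],
            structure[mask],
            xyz[mask],
            radius[mask],
            parent_ids[mask],
        )
        id_to_idx = {int(i): k for k, i in enumerate(ids)}
        soma_override = centroid

    parent = np.empty(len(ids), dtype=np.int64)
    for k, pid in enumerate(parent_ids):
        if pid == ROOT_PARENT:
            parent[k] = ROOT_PARENT
        else:
            if int(pid) not in id_to_idx:
                raise SWCStructureError(f"node {int(ids[k])}: parent id {int(pid)} does not exist")
            if int(pid) == int(ids[k]):
                raise SWCStructureError(f"node {int(ids[k])}: self-parenting cycle")
            parent[k] = id_to_idx[int(pid)]

    roots = np.flatnonzero(parent == ROOT_PARENT)
    if len(roots) == 0:
        raise SWCStructureError("no root node (parent -1) found")
    if len(roots) > 1:
        raise SWCStructureError(f"multiple roots: nodes {[int(ids[r]) for r in roots]}")

    order = _topological_order(parent, int(roots[0]), ids)
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    new_parent = np.where(parent[order] == ROOT_PARENT, ROOT_PARENT, rank[parent[order]])
    return NeuronMorphology(
        ids=ids[order],
        structure=structure[order],
        xyz=xyz[order],
        radius=radius[order],
        parent=new_parent,
        source_id=source_id,
        soma_position_override=soma_override,
    )


def _topological_order(parent: np.ndarray, root: int, ids: np.ndarray) -> np.ndarray:
    n = len(parent)
    kids: list[list[int]] = [[] for _ in range(n)]
    for i, p in enumerate(parent):
        if p != ROOT_PARENT:
            kids[p].append(i)
    order = np.empty(n, dtype=np.int64)
    queue = deque([root])
    k = 0
    while queue:
        node = queue.popleft()
        order[k] = node
        k += 1
        queue.extend(kids[node])
    if k != n:
        unreachable = sorted(set(range(n)) - set(order[:k].tolist()))
        raise SWCStructureError(
            f"cycle or disconnected component involving node ids "
            f"{[int(ids[i]) for i in unreachable[:5]]}"
        )
    return order


def write_swc(m: NeuronMorphology, sink=None) -> str | None:
    """Emit standard 7-column SWC; ids renumbered contiguously from 1.

    ``sink`` may be a path, a text stream, or None (return the text).
    """
    lines = ["# id type x y z radius parent"]
    for i in range(m.n_nodes):
        pid = -1 if m.parent[i] == ROOT_PARENT else int(m.parent[i]) + 1
        x, y, z = m.xyz[i]
        lines.append(
            f"{i + 1} {int(m.structure[i])} {x:.6f} {y:.6f} {z:.6f} {m.radius[i]:.6f} {pid}"
        )
    text = "\n".join(lines) + "\n"
    if sink is None:
        return text
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
        return None
    sink.write(text)
    return None


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

#: staining methods grouped into the three method classes
STAINING_CLASSES: dict[str, str] = {
    # heavy metals
    "golgi": "heavy_metal",
    "golgi-cox": "heavy_metal",
    "rapid golgi": "heavy_metal",
    "golgi-kopsch": "heavy_metal",
    # genetic markers
    "green fluorescent protein": "genetic_marker",
    "red fluorescent protein": "genetic_marker",
    "enhanced green fluorescent protein": "genetic_marker",
    "tag red fluorescent protein": "genetic_marker",
    # immunostaining and direct injection
    "immunostaining": "immuno_or_injection",
    "horseradish peroxidase": "immuno_or_injection",
    "neurobiotin": "immuno_or_injection",
    "biocytin": "immuno_or_injection",
    "biocytin & betaiv-spectrin": "immuno_or_injection",
    "alexa fluor 488": "immuno_or_injection",
    "alexa 647-dextrane": "immuno_or_injection",
    "alexa fluor 594": "immuno_or_injection",
    "ogb-1": "immuno_or_injection",
    "biotinylated dextran amine": "immuno_or_injection",
    "lucifer yellow": "immuno_or_injection",
}

MATCHING_ATTRIBUTES = (
    "species",
    "sex",
    "age_class",
    "region_primary",
    "region_secondary",
    "region_tertiary",
    "celltype_primary",
    "celltype_secondary",
    "celltype_tertiary",
)

METADATA_COLUMNS = (
    "source_id",
    "species",
    "sex",
    "age_months",
    "age_class",
    "region_primary",
    "region_secondary",
    "region_tertiary",
    "celltype_primary",
    "celltype_secondary",
    "celltype_tertiary",
    "staining_method",
    "integrity",
    "condition",
    "strain",
    "archive",
)

REQUIRED_COLUMNS = tuple(c for c in METADATA_COLUMNS if c not in ("age_months", "age_class", "strain", "archive"))


def staining_class_of(staining_method: str, unknown: str = "error") -> str:
    """Map a staining label to heavy_metal / genetic_marker / immuno_or_injection.

    ``unknown='other'`` returns 'other' for unrecognised labels instead of
    raising.
    """
    cls = STAINING_CLASSES.get(staining_method.strip().lower())
    if cls is None:
        if unknown == "other":
            return "other"
        raise MetadataError(f"unknown staining method: {staining_method!r}")
    return cls


@dataclass(frozen=True)
class NeuronMetadata:
    """Biological attributes and staining label of one deposited neuron.

    The matching attributes (species, sex, age class, the region and
    cell-type hierarchies, optionally strain) define the blocking variable of
    the comparison; ``staining_method`` is the treatment label.
    """

    source_id: str
    species: str
    sex: str
    age_class: str | None
    region_primary: str
    region_secondary: str
    region_tertiary: str
    celltype_primary: str
    celltype_secondary: str
    celltype_tertiary: str
    staining_method: str
    integrity: str
    condition: str
    age_months: float | None = None
    strain: str | None = None
    archive: str | None = None
    staining_class: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "staining_class", staining_class_of(self.staining_method, unknown="other")
        )

    def matching_key(self, include_strain: bool = False) -> tuple:
        key = tuple(getattr(self, a) or "" for a in MATCHING_ATTRIBUTES)
        if include_strain:
            key = key + (self.strain or "",)
        return key


def _clean(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return str(value).strip()


def read_metadata(source, unknown_staining: str = "error") -> list[NeuronMetadata]:
    """Read the per-neuron metadata CSV into NeuronMetadata records.

    The CSV must carry the standard column names (see METADATA_COLUMNS);
    ``age_months`` or ``age_class`` may be empty per row (both empty means
    the record is later dropped by cohort filtering). ``staining_class`` is
    derived from ``staining_method``. Missing age_class values are filled
    from age_months using the young / young-adult / adult boundaries.
    """
    from .cohort import assign_age_class  # late import: avoids a cycle

    if isinstance(source, (str, Path)) and "\n" not in str(source):
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    elif isinstance(source, str):
        df = pd.read_csv(io.StringIO(source), dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata is missing required columns: {missing}")
    dupes = df["source_id"][df["source_id"].duplicated()].unique()
    if len(dupes):
        raise MetadataError(f"duplicate source_id values: {list(dupes[:5])}")

    records = []
    for _, row in df.iterrows():
        age_months = None
        if "age_months" in df.columns and _clean(row.get("age_months")):
            age_months = float(row["age_months"])
        age_class = _clean(row.get("age_class")) or None
        if age_class is None and age_months is not None:
            age_class = assign_age_class(age_months)
        # force the derived staining class through the configured policy
        staining_class_of(_clean(row["staining_method"]), unknown=unknown_staining)
        records.append(
            NeuronMetadata(
                source_id=_clean(row["source_id"]),
                species=_clean(row["species"]),
                sex=_clean(row["sex"]),
                age_months=age_months,
                age_class=age_class,
                region_primary=_clean(row["region_primary"]),
                region_secondary=_clean(row["region_secondary"]),
                region_tertiary=_clean(row["region_tertiary"]),
                celltype_primary=_clean(row["celltype_primary"]),
                celltype_secondary=_clean(row["celltype_secondary"]),
                celltype_tertiary=_clean(row["celltype_tertiary"]),
                staining_method=_clean(row["staining_method"]),
                integrity=_clean(row["integrity"]),
                condition=_clean(row["condition"]),
                strain=_clean(row.get("strain")) or None,
                archive=_clean(row.get("archive")) or None,
            )
        )
    return records


def write_metadata(records: Sequence[NeuronMetadata], sink) -> None:
    """Write records back to CSV with the standard columns."""
    rows = []
    for r in records:
        rows.append(
            {
                "source_id": r.source_id,
                "species": r.species,
                "sex": r.sex,
                "age_months": "" if r.age_months is None else r.age_months,
                "age_class": r.age_class or "",
                "region_primary": r.region_primary,
                "region_secondary": r.region_secondary,
                "region_tertiary": r.region_tertiary,
                "celltype_primary": r.celltype_primary,
                "celltype_secondary": r.celltype_secondary,
                "celltype_tertiary": r.celltype_tertiary,
                "staining_method": r.staining_method,
                "integrity": r.integrity,
                "condition": r.condition,
                "strain": r.strain or "",
                "archive": r.archive or "",
            }
        )
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(sink, index=False)
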