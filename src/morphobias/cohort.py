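"""Filtering neurons and assembling matched comparison groups.

A matched group collects neurons identical on species, sex (male, female,
or the mixed male/female deposition class), age class, the brain-region
hierarchy and the cell-type hierarchy — optionally also rodent strain — and
partitions them by staining method. Groups with at least two staining
methods of at least five neurons each are eligible for comparison; within
such a group any systematic morphological difference between staining
methods cannot be explained by the matched biological attributes.

Age classes: young = [1, 2) months, young adult = [2, 6] months (upper
bound inclusive), adult = (6, inf); animals under one month are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .swc_io import MATCHING_ATTRIBUTES, NeuronMetadata

__all__ = [
    "MatchedGroup",
    "assign_age_class",
    "filter_neurons",
    "build_groups",
]

VALID_SPECIES = ("mouse", "rat")
VALID_SEX = ("male", "female", "male/female")

#: matching attributes that must be reported for a record to be usable;
#: tertiary region/cell-type levels may be legitimately absent and then
#: match only records that also lack them.
_REQUIRED_FOR_MATCHING = (
    "species",
    "sex",
    "age_class",
    "region_primary",
    "region_secondary",
    "celltype_primary",
    "celltype_secondary",
)


def assign_age_class(age_months: float) -> str | None:
    """Map an age in months to young / young_adult / adult.

    Returns None for animals younger than one month (excluded from
    analysis). The 6-month boundary belongs to young_adult.
    """
    if age_months < 0:
        raise ValueError(f"age must be non-negative, got {age_months}")
    if age_months < 1:
        return None
    if age_months < 2:
        return "young"
    if age_months <= 6:
        return "young_adult"
    return "adult"


def filter_neurons(meta: Sequence[NeuronMetadata]) -> list[NeuronMetadata]:
    """Keep complete, control-condition rodent records with full labels.

    Drops records with incomplete dendritic reconstructions, non-control
    experimental conditions, non-rodent species, and records missing any
    required matching attribute (unreported labels cannot be matched on).
    """
    kept = []
    for r in meta:
        if r.integrity != "complete" or r.condition != "control":
            continue
        if r.species not in VALID_SPECIES or r.sex not in VALID_SEX:
            continue
        if any(not getattr(r, a) for a in _REQUIRED_FOR_MATCHING):
            continue
        kept.append(r)
    return kept


@dataclass(frozen=True)
class MatchedGroup:
    """One level of the matching variable: a key plus members per method."""

    key: tuple
    key_attributes: tuple[str, ...]
    members: dict  # staining_method -> tuple of source_ids

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))

    @property
    def n_neurons(self) -> int:
        return sum(len(v) for v in self.members.values())

    def method_pairs(self) -> list[tuple[str, str]]:
        """All unordered method pairs present in the group, lexicographic."""
        return list(combinations(self.methods, 2))

    def describe(self) -> dict:
        d = dict(zip(self.key_attributes, self.key))
        d["members"] = {m: list(v) for m, v in self.members.items()}
        return d


def build_groups(
    meta: Sequence[NeuronMetadata],
    match_strain: bool = False,
    min_samples: int = 5,
    min_methods: int = 2,
) -> list[MatchedGroup]:
    """Partition filtered records by the full matching key and keep the
    eligible groups.

    Within each candidate group, staining methods with fewer than
    ``min_samples`` neurons are dropped; the group is eligible when at
    least ``min_methods`` methods survive. Groups and methods come back in
    deterministic lexicographic order.
    """
    key_attrs = MATCHING_ATTRIBUTES + (("strain",) if match_strain else ())
    buckets: dict[tuple, dict[str, list[str]]] = {}
    for r in meta:
        key = r.matching_key(include_strain=match_strain)
        buckets.setdefault(key, {}).setdefault(r.staining_method, []).append(r.source_id)

    groups = []
    for key in sorted(buckets):
        methods = {
            m: tuple(sorted(ids))
            for m, ids in buckets[key].items()
            if len(ids) >= min_samples
        }
        if len(methods) >= min_methods:
            groups.append(MatchedGroup(key=key, key_attributes=key_attrs, members=methods))
    return groups
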