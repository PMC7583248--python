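"""Partition family members into phylogenetic groups from pairwise distances.

Agglomerative clustering (average linkage by default) cut at a distance
threshold; group ids are renumbered by decreasing size (ties by smallest
member id) so reports are stable and human-readable. A group can later be
split at a tighter cutoff into subgroups labelled ``Na``, ``Nb``, ...
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .alignment import DistanceMatrix
from .errors import GroupingError, ValidationError

logger = logging.getLogger(__name__)

LINKAGES = ("average", "single", "complete")


@dataclass(frozen=True)
class FamilyGrouping:
    """A partition of member ids into named groups.

    Keys are strings; the initial clustering produces dense integer labels
    "1".."k", and :func:`split_group` introduces letter-suffixed labels.
    """

    groups: Mapping[str, frozenset]
    method_params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for gid, members in self.groups.items():
            if not members:
                raise ValidationError(f"group {gid!r} is empty")
            overlap = seen & set(members)
            if overlap:
                raise ValidationError(
                    f"member(s) {sorted(overlap)} appear in more than one group"
                )
            seen |= set(members)

    @property
    def member_ids(self) -> frozenset:
        return frozenset().union(*self.groups.values())

    def group_of(self) -> dict:
        """Flat member_id -> group_id mapping."""
        return {m: gid for gid, members in self.groups.items() for m in members}

    def sizes(self) -> dict:
        return {gid: len(members) for gid, members in self.groups.items()}


def _renumber(clusters: list) -> dict:
    """Number clusters by decreasing size, ties by smallest member id."""
    ordered = sorted(clusters, key=lambda ms: (-len(ms), min(ms)))
    return {str(k): frozenset(ms) for k, ms in enumerate(ordered, start=1)}


def cluster_family(
    dm: DistanceMatrix, cutoff: float, linkage: str = "average"
) -> FamilyGrouping:
    """Cut an agglomerative dendrogram of ``dm`` at distance ``cutoff``.

    Deterministic: ids are sorted lexicographically before linkage so
    equal-distance ties do not depend on input order. Singleton groups are
    permitted.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise GroupingError(f"cutoff must be in [0, 1], got {cutoff}")
    if linkage not in LINKAGES:
        raise GroupingError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    params = {"linkage": linkage, "cutoff": cutoff}
    order = sorted(range(len(dm.ids)), key=lambda k: dm.ids[k])
    ids = [dm.ids[k] for k in order]
    if len(ids) == 1:
        return FamilyGrouping({"1": frozenset(ids)}, params)
    d = dm.d[np.ix_(order, order)]
    Z = scipy_linkage(squareform(d, checks=False), method=linkage)
    labels = fcluster(Z, t=cutoff, criterion="distance")
    clusters = {}
    for rid, lab in zip(ids, labels):
        clusters.setdefault(int(lab), []).append(rid)
    return FamilyGrouping(_renumber(list(clusters.values())), params)


def split_group(
    grouping: FamilyGrouping,
    group_id: str,
    dm: DistanceMatrix,
    cutoff2: float,
) -> FamilyGrouping:
    """Re-cluster one group at a tighter cutoff, relabelling as Na, Nb, ...

    All other groups are untouched; membership is conserved. If ``cutoff2``
    is not tighter than the original cutoff (or the group does not split),
    the input grouping is returned with a warning.
    """
    group_id = str(group_id)
    if group_id not in grouping.groups:
        raise GroupingError(f"unknown group id {group_id!r}")
    original_cutoff = grouping.method_params.get("cutoff")
    if original_cutoff is not None and cutoff2 >= original_cutoff:
        logger.warning(
            "split cutoff %.3g is not tighter than original %.3g; no split",
            cutoff2,
            original_cutoff,
        )
        return grouping
    members = sorted(grouping.groups[group_id])
    sub = cluster_family(
        dm.subset(members),
        cutoff2,
        str(grouping.method_params.get("linkage", "average")),
    )
    if len(sub.groups) == 1:
        logger.warning("group %s did not separate at cutoff %.3g", group_id, cutoff2)
        return grouping
    new_groups = {g: m for g, m in grouping.groups.items() if g != group_id}
    # subgroup letters follow the size-ordered numbering of the re-clustering
    for sub_id, sub_members in sorted(sub.groups.items(), key=lambda kv: int(kv[0])):
        letter = string.ascii_lowercase[int(sub_id) - 1]
        new_groups[f"{group_id}{letter}"] = sub_members
    params = dict(grouping.method_params)
    params.setdefault("splits", {})
    params["splits"] = {**params["splits"], group_id: cutoff2}
    return FamilyGrouping(new_groups, params)
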