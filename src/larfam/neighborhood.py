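"""Per-group gene-context association: which COGs co-occur with the family.

A member contributes at most one count per COG regardless of how many times
the label occurs in its flank (presence semantics — association fractions
read as "fraction of neighborhoods", robust to tandem duplicates). Strand is
ignored. The biosynthesis-partner labels can be excluded so that the filter
surfaces novel functional partners only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import AssociationError
from .grouping import FamilyGrouping
from .io_formats import NeighborhoodRecord

logger = logging.getLogger(__name__)

#: Labels of the cofactor-biosynthesis partner genes, excluded by default
#: when hunting for substrate-related context.
DEFAULT_EXCLUDE = frozenset({"larB", "larC", "larE"})

#: Association threshold: a COG is a candidate functional partner of a group
#: when strictly more than this fraction of the group's neighborhoods
#: contain it.
DEFAULT_ASSOC_THRESHOLD = 0.30


@dataclass(frozen=True)
class AssociationTable:
    """Counts and fractions of COG presence per group."""

    counts: Mapping[tuple, int]  # (group_id, cog) -> member count
    group_sizes: Mapping[str, int]

    def __post_init__(self):
        for (gid, cog), count in self.counts.items():
            size = self.group_sizes.get(gid, 0)
            if not 0 <= count <= size:
                raise AssociationError(
                    f"count {count} for ({gid!r}, {cog!r}) exceeds group size {size}"
                )

    def fraction(self, group_id: str, cog: str) -> float:
        return self.counts.get((group_id, cog), 0) / self.group_sizes[group_id]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "group_id": gid,
                "cog": cog,
                "count": count,
                "group_size": self.group_sizes[gid],
                "fraction": count / self.group_sizes[gid],
            }
            for (gid, cog), count in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["group_id", "cog", "count", "group_size", "fraction"]
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None):
        payload = {
            "group_sizes": dict(sorted(self.group_sizes.items())),
            "associations": [
                {"group_id": gid, "cog": cog, "count": c}
                for (gid, cog), c in sorted(self.counts.items())
            ],
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def associate(
    grouping: FamilyGrouping,
    neighborhoods: Sequence[NeighborhoodRecord],
    window: int = 3,
    exclude: Optional[Iterable[str]] = DEFAULT_EXCLUDE,
) -> AssociationTable:
    """Count, per (group, COG), the members whose flank contains the COG.

    Members without a neighborhood record still count toward the group size
    (logged). The window is re-applied defensively even if the reader already
    filtered, and excluded COGs are omitted from the output entirely —
    removing a COG never changes any other COG's fraction.
    """
    if window <= 0:
        raise AssociationError(f"window must be positive, got {window}")
    exclude = frozenset(exclude or ())
    by_member = {}
    for rec in neighborhoods:
        by_member.setdefault(rec.anchor_gene_id, rec)
    counts = {}
    sizes = {}
    for gid, members in grouping.groups.items():
        sizes[gid] = len(members)
        missing = sorted(m for m in members if m not in by_member)
        if missing:
            logger.warning(
                "group %s: %d member(s) lack a neighborhood record: %s",
                gid,
                len(missing),
                ", ".join(missing[:5]) + ("..." if len(missing) > 5 else ""),
            )
        for member in members:
            rec = by_member.get(member)
            if rec is None:
                continue
            for cog in rec.within(window).cogs():
                if cog in exclude:
                    continue
                counts[(gid, cog)] = counts.get((gid, cog), 0) + 1
    return AssociationTable(counts, sizes)


def top_associations(
    table: AssociationTable, threshold: float = DEFAULT_ASSOC_THRESHOLD
) -> dict:
    """Per group, the COGs whose fraction is STRICTLY greater than ``threshold``.

    Returned as ``{group_id: [(cog, fraction), ...]}`` sorted by descending
    fraction (ties by COG label); groups with nothing above threshold map to
    an empty list so "no candidate partner" is explicit in reports.
    """
    if not 0.0 <= threshold <= 1.0:
        raise AssociationError(f"threshold must be in [0, 1], got {threshold}")
    result = {gid: [] for gid in table.group_sizes}
    for (gid, cog), count in table.counts.items():
        fraction = count / table.group_sizes[gid]
        if fraction > threshold:
            result[gid].append((cog, fraction))
    for gid in result:
        result[gid].sort(key=lambda item: (-item[1], item[0]))
    return result
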