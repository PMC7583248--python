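"""Readers and writers for the pipeline's external representations.

Formats handled here:

* protein sequences — plain FASTA (header token before the first whitespace
  is the record id; the remainder is kept verbatim as the species/description
  and never parsed for semantics);
* gene neighborhoods — flat TSV, one flanking gene per row, with columns
  ``genome_id / anchor_gene_id / offset / cog`` (``strand`` optional and
  carried through untouched);
* anchor configuration — YAML mapping a reference sequence id to 1-based
  positions, expected residues and functional categories;
* kinetics measurements — CSV with columns ``S / I / v / replicate`` plus a
  commented metadata header.

All readers validate and raise typed errors; none silently truncates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    AnchorConfigError,
    DuplicateIdError,
    FormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, the only residue alphabet accepted anywhere.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Residue categories recognised in anchor configurations.
ANCHOR_CATEGORIES = ("catalytic", "npn_binding", "substrate", "other")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One family member: an ungapped amino-acid sequence plus metadata."""

    id: str
    sequence: str
    species: str = ""
    group_label: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValidationError("protein record id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: illegal character(s) "
                f"{sorted(bad)!r}; allowed alphabet is {AMINO_ACIDS}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_group(self, label: str) -> "ProteinRecord":
        return replace(self, group_label=label)


@dataclass(frozen=True)
class NeighborhoodRecord:
    """Genes flanking one family member's gene.

    ``flank`` is an ordered tuple of ``(offset, cog)`` pairs; offsets are
    signed gene-order distances from the anchor gene (never 0) and unique
    within a record.
    """

    genome_id: str
    anchor_gene_id: str
    flank: tuple  # tuple[tuple[int, str], ...]

    def __post_init__(self):
        offsets = [o for o, _ in self.flank]
        if any(o == 0 for o in offsets):
            raise ValidationError(
                f"neighborhood {self.anchor_gene_id!r}: "
                "anchor cannot be its own neighbor (offset 0)"
            )
        if len(set(offsets)) != len(offsets):
            raise ValidationError(
                f"neighborhood {self.anchor_gene_id!r}: duplicate offsets"
            )

    def cogs(self) -> frozenset:
        """Set of COG labels present in the flank (presence semantics)."""
        return frozenset(c for _, c in self.flank)

    def within(self, window: int) -> "NeighborhoodRecord":
        """Restrict the flank to offsets with ``|offset| <= window``."""
        kept = tuple((o, c) for o, c in self.flank if abs(o) <= window)
        return NeighborhoodRecord(self.genome_id, self.anchor_gene_id, kept)


@dataclass(frozen=True)
class Anchor:
    """One reference-numbered anchor residue."""

    position: int  # 1-based index into the ungapped reference sequence
    ref_residue: str
    category: str

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError(f"anchor position must be >= 1, got {self.position}")
        if self.ref_residue not in _AA_SET:
            raise ValidationError(f"anchor residue {self.ref_residue!r} not an amino acid")
        if self.category not in ANCHOR_CATEGORIES:
            raise ValidationError(
                f"anchor category {self.category!r} not in {ANCHOR_CATEGORIES}"
            )


@dataclass(frozen=True)
class AnchorConfig:
    """Reference id + ordered anchor list + named substrate-recognition regions.

    Regions map a region name (``loop``, ``helix_a11``, ``helix_a14``, ...)
    to the tuple of anchor positions it spans, in sequence order.
    """

    reference_id: str
    anchors: tuple  # tuple[Anchor, ...]
    regions: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        positions = [a.position for a in self.anchors]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise AnchorConfigError("anchor positions must be strictly increasing")
        known = set(positions)
        for name, pos in self.regions.items():
            missing = [p for p in pos if p not in known]
            if missing:
                raise AnchorConfigError(
                    f"region {name!r} references non-anchor positions {missing}"
                )

    @property
    def positions(self) -> tuple:
        return tuple(a.position for a in self.anchors)

    def by_category(self, *categories: str) -> tuple:
        return tuple(a for a in self.anchors if a.category in categories)

    def anchor_at(self, position: int) -> Anchor:
        for a in self.anchors:
            if a.position == position:
                return a
        raise KeyError(position)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the id; the rest of
    the header line is stored as ``species``. Sequences are uppercased before
    alphabet validation so lowercase input is accepted.
    """
    path = Path(path)
    records = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise DuplicateIdError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        desc = entry.description
        species = desc[len(entry.id):].strip() if desc.startswith(entry.id) else desc
        records.append(
            ProteinRecord(id=entry.id, sequence=str(entry.seq).upper(), species=species)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records as FASTA; inverse of :func:`read_fasta` on ids/sequences."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.species)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(entries)


# ---------------------------------------------------------------------------
# Neighborhood TSV
# ---------------------------------------------------------------------------

_NEIGHBOR_COLUMNS = ("genome_id", "anchor_gene_id", "offset", "cog")


def read_neighborhoods(path, window: int = 3) -> list:
    """Read a flat neighborhood TSV into :class:`NeighborhoodRecord` objects.

    Rows are grouped by ``(genome_id, anchor_gene_id)``; rows with
    ``|offset| > window`` are dropped with a logged warning, offset 0 is a
    hard error.
    """
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _NEIGHBOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        return []
    try:
        offsets = df["offset"].astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-integer offset: {exc}") from exc
    if (offsets == 0).any():
        bad = df.loc[offsets == 0, "anchor_gene_id"].iloc[0]
        raise FormatError(
            f"{path}: anchor cannot be its own neighbor (offset 0, gene {bad!r})"
        )
    df = df.assign(offset=offsets)
    out_of_window = df[df["offset"].abs() > window]
    if not out_of_window.empty:
        logger.warning(
            "%s: dropping %d row(s) with |offset| > %d",
            path,
            len(out_of_window),
            window,
        )
        df = df[df["offset"].abs() <= window]

    records = []
    for (genome_id, gene_id), sub in df.groupby(
        ["genome_id", "anchor_gene_id"], sort=True
    ):
        flank = tuple(
            (int(row.offset), str(row.cog))
            for row in sub.sort_values("offset").itertuples()
        )
        records.append(NeighborhoodRecord(str(genome_id), str(gene_id), flank))
    return records


def write_neighborhoods(records: Iterable[NeighborhoodRecord], path) -> None:
    rows = [
        {
            "genome_id": r.genome_id,
            "anchor_gene_id": r.anchor_gene_id,
            "offset": offset,
            "cog": cog,
        }
        for r in records
        for offset, cog in r.flank
    ]
    pd.DataFrame(rows, columns=list(_NEIGHBOR_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Anchor configuration
# ---------------------------------------------------------------------------

#: Default anchor set: the 20 reference positions of the nickel-dependent
#: racemase family's reference protein, with the four catalytic residues,
#: the three cofactor-binding residues, and the substrate-recognition set.
DEFAULT_ANCHOR_SPECS = (
    (72, "D", "catalytic"),
    (75, "R", "npn_binding"),
    (108, "H", "catalytic"),
    (174, "H", "catalytic"),
    (175, "F", "substrate"),
    (176, "F", "substrate"),
    (184, "K", "npn_binding"),
    (200, "H", "npn_binding"),
    (220, "I", "other"),
    (294, "Y", "other"),
    (295, "Q", "other"),
    (297, "V", "substrate"),
    (298, "K", "catalytic"),
    (353, "T", "other"),
    (355, "P", "other"),
    (356, "D", "other"),
    (358, "W", "substrate"),
    (359, "T", "other"),
    (360, "A", "other"),
    (362, "I", "other"),
)

#: Substrate-recognition regions anchored on the catalytic core: ``loop`` is
#: the two residues directly after the second catalytic histidine,
#: ``helix_a11`` the residue before the catalytic lysine, ``helix_a14`` the
#: residue facing the substrate side chain.
DEFAULT_REGIONS = {
    "loop": (175, 176),
    "helix_a11": (297,),
    "helix_a14": (358,),
}


def default_anchors() -> tuple:
    return tuple(Anchor(p, r, c) for p, r, c in DEFAULT_ANCHOR_SPECS)


def default_anchor_config(reference_id: str) -> AnchorConfig:
    return AnchorConfig(
        reference_id=reference_id,
        anchors=default_anchors(),
        regions=dict(DEFAULT_REGIONS),
    )


def validate_anchor_config(config: AnchorConfig, reference: ProteinRecord) -> None:
    """Check every declared residue against the reference sequence.

    All mismatches are collected and reported together.
    """
    if config.reference_id != reference.id:
        raise AnchorConfigError(
            f"config reference_id {config.reference_id!r} != record id {reference.id!r}"
        )
    mismatches = []
    for a in config.anchors:
        if a.position > len(reference.sequence):
            raise AnchorConfigError(
                f"anchor position {a.position} beyond reference length "
                f"{len(reference.sequence)}"
            )
        actual = reference.sequence[a.position - 1]
        if actual != a.ref_residue:
            mismatches.append(
                f"position {a.position}: declared {a.ref_residue}, reference has {actual}"
            )
    if mismatches:
        raise AnchorConfigError(
            "anchor residues do not match reference sequence: "
            + "; ".join(mismatches)
        )


def load_anchor_config(path, reference: ProteinRecord) -> AnchorConfig:
    """Load and validate a YAML anchor configuration against ``reference``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "anchors" not in raw:
        raise FormatError(f"{path}: expected a mapping with an 'anchors' list")
    anchors = []
    for item in raw["anchors"]:
        try:
            anchors.append(
                Anchor(
                    position=int(item["position"]),
                    ref_residue=str(item["residue"]),
                    category=str(item["category"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed anchor entry {item!r}: {exc}") from exc
    regions = {
        str(name): tuple(int(p) for p in pos)
        for name, pos in (raw.get("regions") or {}).items()
    }
    config = AnchorConfig(
        reference_id=str(raw.get("reference_id", reference.id)),
        anchors=tuple(anchors),
        regions=regions,
    )
    validate_anchor_config(config, reference)
    return config


def write_anchor_config(config: AnchorConfig, path) -> None:
    payload = {
        "reference_id": config.reference_id,
        "anchors": [
            {"position": a.position, "residue": a.ref_residue, "category": a.category}
            for a in config.anchors
        ],
        "regions": {name: list(pos) for name, pos in config.regions.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Kinetics CSV
# ---------------------------------------------------------------------------


def read_kinetics_csv(path):
    """Read a kinetics CSV into a :class:`~larfam.kinetics.KineticsDataset`.

    Layout: comment lines ``# key = value`` carrying metadata
    (``enzyme_conc`` in µM is required), then columns ``S,I,v,replicate``
    with ``I`` empty when no inhibitor was present.
    """
    from .kinetics import KineticsDataset, KineticsPoint

    path = Path(path)
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    for col in ("S", "v"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "enzyme_conc" not in meta:
        raise FormatError(f"{path}: missing '# enzyme_conc = <µM>' metadata line")
    points = []
    for row in df.itertuples():
        inhibitor = getattr(row, "I", None)
        if inhibitor is not None and pd.isna(inhibitor):
            inhibitor = None
        points.append(
            KineticsPoint(
                S=float(row.S),
                I=None if inhibitor is None else float(inhibitor),
                v=float(row.v),
                replicate=int(getattr(row, "replicate", 0)),
            )
        )
    return KineticsDataset(
        points=tuple(points),
        enzyme_conc=float(meta["enzyme_conc"]),
        substrate=meta.get("substrate", ""),
        inhibitor=meta.get("inhibitor") or None,
    )


def write_kinetics_csv(dataset, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# enzyme_conc = {dataset.enzyme_conc!r}\n")
        if dataset.substrate:
            fh.write(f"# substrate = {dataset.substrate}\n")
        if dataset.inhibitor:
            fh.write(f"# inhibitor = {dataset.inhibitor}\n")
        fh.write("S,I,v,replicate\n")
        for p in dataset.points:
            i_txt = "" if p.I is None else repr(p.I)
            fh.write(f"{p.S!r},{i_txt},{p.v!r},{p.replicate}\n")


# ---------------------------------------------------------------------------
# Grouping / truth TSV
# ---------------------------------------------------------------------------


def read_grouping_tsv(path) -> dict:
    """Read a two-column ``member_id<TAB>group_id`` file into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("member_id", "group_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["member_id"].duplicated().any():
        dup = df.loc[df["member_id"].duplicated(), "member_id"].iloc[0]
        raise DuplicateIdError(f"{path}: member {dup!r} listed twice")
    return dict(zip(df["member_id"], df["group_id"]))


def write_grouping_tsv(assignment: Mapping[str, str], path) -> None:
    pd.DataFrame(
        sorted(assignment.items()), columns=["member_id", "group_id"]
    ).to_csv(path, sep="\t", index=False)
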