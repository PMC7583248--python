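"""Structure-anchored signature profiles and rule-based activity calls.

The reference protein's anchor residues are mapped through the alignment to
columns; per-group residue frequencies at those columns give a signature
profile (the input of a sequence logo), scored in information bits with the
standard small-sample correction. Categories color each anchor the way the
family's signature figures do:

* ``green``  — catalytic anchors (always, conservation flagged separately);
* ``blue``   — cofactor-binding anchors (likewise);
* ``yellow`` — substrate anchors conserved and equal to the reference;
* ``red``    — substrate anchors conserved but differing from the reference;
* ``black``  — substrate anchors not conserved within the group.

Activity classification requires every catalytic and cofactor-binding anchor
to be conserved with the reference residue (otherwise the group is excluded
as a likely non-member of the superfamily), then matches the dominant
residues of the substrate-recognition regions (loop / helix α11 / helix α14)
against a table of per-activity allowed residue strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .alignment import Msa
from .errors import SignatureError
from .io_formats import AMINO_ACIDS, AnchorConfig

#: Dominant-residue frequency at or above which a column counts as conserved.
DEFAULT_CONSERVATION_THRESHOLD = 0.7

MAX_BITS = math.log2(20)

COLORS = ("green", "blue", "yellow", "red", "black")

_CATEGORY_FIXED_COLOR = {"catalytic": "green", "npn_binding": "blue"}


# ---------------------------------------------------------------------------
# Column profiles and information content
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnProfile:
    """Residue frequencies of one group at one alignment column.

    Frequencies are over non-gap residues only and sum to 1; rows gapped at
    the column contribute to ``gap_fraction`` but not to ``n_effective``.
    ``n_effective == 0`` flags an all-gap column: information is undefined
    there and reported as missing, never as zero.
    """

    freqs: Mapping[str, float]
    gap_fraction: float
    n_effective: int

    @property
    def is_empty(self) -> bool:
        return self.n_effective == 0

    @property
    def dominant_residue(self) -> Optional[str]:
        """Most frequent residue; ties broken to the lexicographic smallest."""
        if self.is_empty:
            return None
        return min(self.freqs, key=lambda aa: (-self.freqs[aa], aa))

    @property
    def dominant_frequency(self) -> float:
        if self.is_empty:
            return 0.0
        return self.freqs[self.dominant_residue]


def column_profile(msa: Msa, member_ids: Iterable[str], column: int) -> ColumnProfile:
    """Frequency profile of ``member_ids`` at ``column`` of ``msa``."""
    members = list(member_ids)
    if not members:
        raise SignatureError("column_profile requires a non-empty member set")
    residues = [msa.row(m)[column] for m in members]
    non_gap = [r for r in residues if r != Msa.GAP]
    gap_fraction = 1.0 - len(non_gap) / len(residues)
    if not non_gap:
        return ColumnProfile(freqs={}, gap_fraction=1.0, n_effective=0)
    freqs = {}
    for r in non_gap:
        freqs[r] = freqs.get(r, 0) + 1
    total = len(non_gap)
    return ColumnProfile(
        freqs={aa: c / total for aa, c in sorted(freqs.items())},
        gap_fraction=gap_fraction,
        n_effective=total,
    )


def information_content(
    freqs: Mapping[str, float],
    n_effective: int,
    small_sample_correction: bool = True,
) -> float:
    """Sequence-logo column height in bits.

    ``R = log2(20) - (H + e_n)`` with ``H = -sum f log2 f`` and the
    small-sample correction ``e_n = (s - 1) / (2 ln 2 n)`` for ``s = 20``
    symbols; clamped at 0.
    """
    if n_effective < 1:
        raise SignatureError("information undefined for an empty column")
    h = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
    e_n = (20 - 1) / (2 * math.log(2) * n_effective) if small_sample_correction else 0.0
    return max(0.0, MAX_BITS - (h + e_n))


# ---------------------------------------------------------------------------
# Anchor mapping and per-group profiles
# ---------------------------------------------------------------------------


def map_anchor_columns(msa: Msa, config: AnchorConfig) -> dict:
    """Map each anchor position (1-based, on the reference) to its column."""
    if config.reference_id not in msa.ids:
        raise SignatureError(
            f"reference {config.reference_id!r} is not a row of the alignment"
        )
    mapping = {}
    for anchor in config.anchors:
        mapping[anchor.position] = msa.col_of(config.reference_id, anchor.position)
    if len(set(mapping.values())) != len(mapping):
        raise SignatureError("anchor->column mapping is not injective")
    return mapping


@dataclass(frozen=True)
class AnchorStats:
    """Everything reported about one anchor of one group."""

    position: int
    ref_residue: str
    category: str
    profile: ColumnProfile
    information_bits: Optional[float]
    conserved: bool
    category_color: str


@dataclass(frozen=True)
class SignatureProfile:
    """Per-group signature: one :class:`AnchorStats` per anchor position."""

    group_id: str
    anchors: Mapping[int, AnchorStats]
    conservation_threshold: float

    def dominant(self, position: int) -> Optional[str]:
        return self.anchors[position].profile.dominant_residue

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pos in sorted(self.anchors):
            st = self.anchors[pos]
            rows.append(
                {
                    "position": pos,
                    "ref_residue": st.ref_residue,
                    "category": st.category,
                    "dominant": st.profile.dominant_residue or "",
                    "dominant_frequency": round(st.profile.dominant_frequency, 6),
                    "gap_fraction": round(st.profile.gap_fraction, 6),
                    "n_effective": st.profile.n_effective,
                    "information_bits": (
                        "" if st.information_bits is None
                        else round(st.information_bits, 6)
                    ),
                    "conserved": st.conserved,
                    "color": st.category_color,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def assign_category_color(
    category: str,
    profile: ColumnProfile,
    ref_residue: str,
    conservation_threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
) -> str:
    """Color rule for one anchor (see module docstring for the palette)."""
    fixed = _CATEGORY_FIXED_COLOR.get(category)
    if fixed is not None:
        return fixed
    conserved = (
        not profile.is_empty and profile.dominant_frequency >= conservation_threshold
    )
    if not conserved:
        return "black"
    return "yellow" if profile.dominant_residue == ref_residue else "red"


def build_group_profile(
    msa: Msa,
    group_id: str,
    member_ids: Iterable[str],
    config: AnchorConfig,
    conservation_threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
    small_sample_correction: bool = True,
) -> SignatureProfile:
    """Profile every anchor column for one group of alignment rows."""
    members = list(member_ids)
    columns = map_anchor_columns(msa, config)
    anchors = {}
    for anchor in config.anchors:
        prof = column_profile(msa, members, columns[anchor.position])
        bits = (
            None
            if prof.is_empty
            else information_content(
                prof.freqs, prof.n_effective, small_sample_correction
            )
        )
        conserved = (
            not prof.is_empty
            and prof.dominant_frequency >= conservation_threshold
        )
        anchors[anchor.position] = AnchorStats(
            position=anchor.position,
            ref_residue=anchor.ref_residue,
            category=anchor.category,
            profile=prof,
            information_bits=bits,
            conserved=conserved,
            category_color=assign_category_color(
                anchor.category, prof, anchor.ref_residue, conservation_threshold
            ),
        )
    return SignatureProfile(
        group_id=str(group_id),
        anchors=anchors,
        conservation_threshold=conservation_threshold,
    )


# ---------------------------------------------------------------------------
# Activity signatures and group classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivitySignature:
    """Allowed residue strings per substrate-recognition region for one activity.

    Region values are concatenated residues in sequence order (e.g. a
    two-residue loop constraint ``"FF"``); multiple alternatives model the
    slash notation of signature tables (``{"LM", "FM"}``).
    """

    name: str
    regions: Mapping[str, frozenset]

    def __post_init__(self):
        if not self.regions:
            raise SignatureError(
                f"activity {self.name!r} must constrain at least one region"
            )
        for region, allowed in self.regions.items():
            lengths = {len(s) for s in allowed}
            if len(lengths) != 1:
                raise SignatureError(
                    f"activity {self.name!r}, region {region!r}: "
                    "alternatives must share one length"
                )
            for s in allowed:
                bad = set(s) - set(AMINO_ACIDS)
                if bad:
                    raise SignatureError(
                        f"activity {self.name!r}: illegal residues {sorted(bad)}"
                    )


def builtin_activity_signatures() -> tuple:
    """The shipped activity table for the nickel-dependent racemase family.

    LAR: double-Phe loop, Val before the catalytic Lys, Trp in helix α14.
    SAR: Leu/Phe + Met loop (smaller loop residues, broader substrates).
    MAR: Tyr/Gln/His + Lys loop with Gln in α11 and Lys in α14.
    HGR: Asn-Gln loop with Thr in α11.
    GntE: Glu + Val/Ser loop; α11 and α14 admit the observed variants.
    """
    return (
        ActivitySignature(
            "LAR",
            {
                "loop": frozenset({"FF"}),
                "helix_a11": frozenset({"V"}),
                "helix_a14": frozenset({"W"}),
            },
        ),
        ActivitySignature(
            "SAR",
            {"loop": frozenset({"LM", "FM"})},
        ),
        ActivitySignature(
            "MAR",
            {
                "loop": frozenset({"YK", "QK", "HK", "GK"}),
                "helix_a11": frozenset({"Q"}),
                "helix_a14": frozenset({"K"}),
            },
        ),
        ActivitySignature(
            "HGR",
            {
                "loop": frozenset({"NQ"}),
                "helix_a11": frozenset({"T"}),
            },
        ),
        ActivitySignature(
            "GntE",
            {
                "loop": frozenset({"EV", "ES"}),
                "helix_a11": frozenset({"W", "G"}),
                "helix_a14": frozenset({"A", "V", "N"}),
            },
        ),
    )


def load_activity_signatures(path) -> tuple:
    """Load a user-supplied activity table (YAML: name -> region -> [strings])."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = []
    for name, regions in raw.items():
        out.append(
            ActivitySignature(
                str(name),
                {
                    str(region): frozenset(str(s) for s in allowed)
                    for region, allowed in regions.items()
                },
            )
        )
    return tuple(out)


@dataclass(frozen=True)
class GroupClassification:
    """Outcome of the conserved-motif rules for one group."""

    group_id: str
    is_family_member: bool  # catalytic + cofactor anchors all conserved
    missing_required: tuple  # anchor positions failing the requirement
    predicted_activity: str  # activity name or "unknown"
    match_scores: Mapping[str, float]  # activity -> matched/constrained regions
    candidates: tuple  # activities ranked by score (desc, then name)

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "is_family_member": self.is_family_member,
            "missing_required": list(self.missing_required),
            "predicted_activity": self.predicted_activity,
            "match_scores": dict(sorted(self.match_scores.items())),
            "candidates": list(self.candidates),
        }


def _region_string(profile: SignatureProfile, positions: Sequence[int]) -> Optional[str]:
    """Concatenated dominant residues over region positions.

    ``None`` when any position is not conserved (a non-conserved region can
    never match an activity constraint).
    """
    out = []
    for pos in positions:
        stats = profile.anchors.get(pos)
        if stats is None:
            raise SignatureError(f"profile lacks anchor position {pos}")
        if not stats.conserved or stats.profile.dominant_residue is None:
            return None
        out.append(stats.profile.dominant_residue)
    return "".join(out)


def classify_group(
    profile: SignatureProfile,
    config: AnchorConfig,
    signatures: Optional[Sequence[ActivitySignature]] = None,
    conservation_threshold: Optional[float] = None,
) -> GroupClassification:
    """Apply the exclusion rule, then match substrate-region signatures.

    A group is a family member only if every catalytic and cofactor-binding
    anchor is conserved with dominant residue equal to the reference residue.
    An activity is called only on a unique perfect match (score 1 over all
    constrained regions); otherwise the prediction is "unknown" with ranked
    candidates reported.
    """
    signatures = tuple(signatures) if signatures is not None else builtin_activity_signatures()
    required = config.by_category("catalytic", "npn_binding")
    missing = []
    for anchor in required:
        stats = profile.anchors.get(anchor.position)
        if stats is None:
            raise SignatureError(
                f"group {profile.group_id}: no profile for anchor {anchor.position}"
            )
        ok = (
            stats.conserved
            and stats.profile.dominant_residue == anchor.ref_residue
        )
        if not ok:
            missing.append(anchor.position)
    is_member = not missing

    region_values = {
        region: _region_string(profile, positions)
        for region, positions in config.regions.items()
    }
    scores = {}
    for sig in signatures:
        matched = 0
        for region, allowed in sig.regions.items():
            if region not in region_values:
                raise SignatureError(
                    f"activity {sig.name!r} constrains unknown region {region!r}"
                )
            value = region_values[region]
            if value is not None and value in allowed:
                matched += 1
        scores[sig.name] = matched / len(sig.regions)
    ranked = tuple(
        name for name, _ in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    predicted = "unknown"
    if is_member and ranked:
        top = [name for name in ranked if scores[name] == 1.0]
        if len(top) == 1:
            predicted = top[0]
    return GroupClassification(
        group_id=profile.group_id,
        is_family_member=is_member,
        missing_required=tuple(missing),
        predicted_activity=predicted,
        match_scores=scores,
        candidates=ranked,
    )


# ---------------------------------------------------------------------------
# Text logo
# ---------------------------------------------------------------------------


def text_logo(profile: SignatureProfile, height: int = 8) -> str:
    """Terminal-friendly logo: one stack per anchor, scaled by bits."""
    positions = sorted(profile.anchors)
    stacks = []
    for pos in positions:
        st = profile.anchors[pos]
        prof = st.profile
        if prof.is_empty or not st.information_bits:
            stacks.append([" "] * height)
            continue
        total = st.information_bits / MAX_BITS * height
        column = []
        for aa in sorted(prof.freqs, key=lambda a: (-prof.freqs[a], a)):
            n = max(0, round(prof.freqs[aa] * total))
            column.extend([aa] * n)
        column = (column[:height] + [" "] * height)[:height]
        stacks.append(column[::-1])
    lines = []
    for level in range(height):
        lines.append(" ".join(stack[level] for stack in stacks))
    footer = " ".join(profile.anchors[p].category_color[0] for p in positions)
    header = " ".join(profile.anchors[p].ref_residue for p in positions)
    return "\n".join(lines + [header, footer])
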