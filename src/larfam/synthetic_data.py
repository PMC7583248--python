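"""Synthetic families, neighborhoods, and kinetics with planted ground truth.

Every generator is a pure function of (config, seed): the same config run
twice yields byte-identical output. Families are built from a random
reference sequence carrying fixed catalytic/cofactor residues and
group-specific substrate-recognition residues at the anchor positions;
background substitutions and indels never touch anchors, and the
reference-position -> member-position map for every anchor is emitted so
downstream alignment can be checked against construction truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import SimulationError
from .io_formats import (
    AMINO_ACIDS,
    Anchor,
    AnchorConfig,
    ProteinRecord,
    default_anchors,
    DEFAULT_REGIONS,
)
from .kinetics import KineticsDataset, KineticsPoint

_AA = np.array(list(AMINO_ACIDS))

#: Planted activities of the default five-group family, keyed by group label.
DEFAULT_GROUP_ACTIVITIES = {"1": "LAR", "2": "SAR", "3": "MAR", "4": "HGR", "5": "GntE"}

#: Default substrate-region residues per group (anchor position -> residue);
#: each entry realises one shipped activity signature.
DEFAULT_GROUP_SIGNATURES = {
    "1": {175: "F", 176: "F", 297: "V", 358: "W"},  # LAR
    "2": {175: "L", 176: "M", 297: "V", 358: "W"},  # SAR
    "3": {175: "Y", 176: "K", 297: "Q", 358: "K"},  # MAR
    "4": {175: "N", 176: "Q", 297: "T", 358: "I"},  # HGR
    "5": {175: "E", 176: "S", 297: "W", 358: "A"},  # GntE
}


def _default_conserved_map(anchors: Sequence[Anchor]) -> dict:
    return {
        a.position: a.ref_residue
        for a in anchors
        if a.category in ("catalytic", "npn_binding")
    }


@dataclass(frozen=True)
class FamilySimConfig:
    """Ground-truth description of a synthetic protein family."""

    n_groups: int = 5
    members_per_group: int = 10
    reference_length: int = 400
    anchors: tuple = field(default_factory=default_anchors)
    group_signatures: Mapping[str, Mapping[int, str]] = field(
        default_factory=lambda: {
            g: dict(s) for g, s in DEFAULT_GROUP_SIGNATURES.items()
        }
    )
    conserved_map: Optional[Mapping[int, str]] = None
    background_mutation_rate: float = 0.05
    #: substitutions applied once per group to its ancestor, so groups are
    #: separable by overall similarity (within-group distance << between)
    group_divergence_rate: float = 0.3
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 1 or self.members_per_group < 1:
            raise SimulationError("n_groups and members_per_group must be >= 1")
        if not 0 <= self.background_mutation_rate <= 1:
            raise SimulationError("background_mutation_rate must be in [0, 1]")
        if not 0 <= self.group_divergence_rate <= 1:
            raise SimulationError("group_divergence_rate must be in [0, 1]")
        if not 0 <= self.indel_rate <= 1:
            raise SimulationError("indel_rate must be in [0, 1]")
        positions = {a.position for a in self.anchors}
        if max(positions, default=0) > self.reference_length:
            raise SimulationError("anchor positions exceed reference length")
        labels = self.group_labels
        missing = [g for g in labels if g not in self.group_signatures]
        if missing:
            raise SimulationError(f"no signature for group(s) {missing}")
        by_cat = {a.position: a.category for a in self.anchors}
        for g in labels:
            for pos, res in self.group_signatures[g].items():
                if pos not in positions:
                    raise SimulationError(
                        f"group {g}: signature position {pos} is not an anchor"
                    )
                if by_cat[pos] in ("catalytic", "npn_binding"):
                    raise SimulationError(
                        f"group {g}: position {pos} is {by_cat[pos]}, "
                        "signatures may only vary substrate/other anchors"
                    )
                if res not in AMINO_ACIDS:
                    raise SimulationError(f"group {g}: bad residue {res!r}")
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                if dict(self.group_signatures[a]) == dict(self.group_signatures[b]):
                    raise SimulationError(
                        f"groups {a} and {b} share an identical signature; "
                        "they are indistinguishable by construction"
                    )
        conserved = self.effective_conserved_map()
        required = {
            a.position
            for a in self.anchors
            if a.category in ("catalytic", "npn_binding")
        }
        uncovered = required - set(conserved)
        if uncovered:
            raise SimulationError(
                f"conserved_map must cover catalytic/cofactor anchors {sorted(uncovered)}"
            )

    @property
    def group_labels(self) -> list:
        return [str(g) for g in range(1, self.n_groups + 1)]

    def effective_conserved_map(self) -> dict:
        if self.conserved_map is not None:
            return dict(self.conserved_map)
        return _default_conserved_map(self.anchors)

    def anchor_config(self, reference_id: str) -> AnchorConfig:
        regions = {
            name: tuple(p for p in pos)
            for name, pos in DEFAULT_REGIONS.items()
            if all(p in {a.position for a in self.anchors} for p in pos)
        }
        return AnchorConfig(
            reference_id=reference_id, anchors=tuple(self.anchors), regions=regions
        )


@dataclass(frozen=True)
class FamilySimResult:
    """Simulated family plus construction truth."""

    records: tuple  # tuple[ProteinRecord, ...]
    truth: Mapping[str, str]  # member id -> group label
    reference: ProteinRecord
    anchor_maps: Mapping[str, Mapping[int, int]]  # id -> {ref_pos: member_pos}
    config: FamilySimConfig


def _substitute(rng, residues: list, mutable: np.ndarray, rate: float) -> None:
    """In-place uniform substitutions over the 19 alternative residues."""
    if rate <= 0:
        return
    hits = np.nonzero(rng.random(len(residues)) < rate)[0]
    for i in hits:
        if not mutable[i]:
            continue
        current = residues[i]
        choices = [aa for aa in AMINO_ACIDS if aa != current]
        residues[i] = choices[rng.integers(0, 19)]


def _apply_indels(rng, tokens: list, anchor_set: frozenset, rate: float) -> list:
    """Deletions then insertions, never touching anchor positions.

    ``tokens`` is a list of (ref_pos | None, residue); indel runs have
    geometric length with mean 2 so anchors stay alignable while gaps are
    nontrivial.
    """
    if rate <= 0:
        return tokens
    half = rate / 2.0
    # deletions: scan left to right, a hit removes a run of non-anchor tokens
    out = []
    i = 0
    while i < len(tokens):
        ref_pos, _ = tokens[i]
        deletable = ref_pos not in anchor_set
        if deletable and rng.random() < half:
            run = int(rng.geometric(0.5))
            removed = 0
            while i < len(tokens) and removed < run and tokens[i][0] not in anchor_set:
                i += 1
                removed += 1
            continue
        out.append(tokens[i])
        i += 1
    tokens = out
    # insertions: only at junctions whose flanking residues are non-anchor,
    # so adjacent anchors (e.g. a two-residue loop) are never separated
    result = []
    n = len(tokens)
    for i in range(n + 1):
        left_ok = i == 0 or tokens[i - 1][0] not in anchor_set
        right_ok = i == n or tokens[i][0] not in anchor_set
        if left_ok and right_ok and rng.random() < half:
            run = int(rng.geometric(0.5))
            for _ in range(run):
                result.append((None, str(_AA[rng.integers(0, 20)])))
        if i < n:
            result.append(tokens[i])
    return result


def simulate_family(config: FamilySimConfig) -> FamilySimResult:
    """Generate a protein family with planted group signatures.

    The reference carries the conserved catalytic/cofactor residues and the
    group-1 signature. Each group derives an ancestor from the reference
    (its signature plus group-level substitutions); each member then applies
    background substitutions (never at anchors) and indels (never removing
    or splitting anchors). Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    L = config.reference_length
    anchor_positions = frozenset(a.position for a in config.anchors)
    conserved = config.effective_conserved_map()
    by_pos = {a.position: a for a in config.anchors}

    reference = list(_AA[rng.integers(0, 20, size=L)])
    first_sig = config.group_signatures[config.group_labels[0]]
    for pos, anchor in by_pos.items():
        if pos in conserved:
            reference[pos - 1] = conserved[pos]
        elif pos in first_sig:
            reference[pos - 1] = first_sig[pos]
        else:
            reference[pos - 1] = anchor.ref_residue

    mutable = np.array([p + 1 not in anchor_positions for p in range(L)])
    records = []
    truth = {}
    anchor_maps = {}
    for g in config.group_labels:
        sig = config.group_signatures[g]
        ancestor = list(reference)
        for pos, res in sig.items():
            ancestor[pos - 1] = res
        _substitute(rng, ancestor, mutable, config.group_divergence_rate)
        for m in range(1, config.members_per_group + 1):
            member_id = f"G{g}_M{m:02d}"
            residues = list(ancestor)
            _substitute(rng, residues, mutable, config.background_mutation_rate)
            tokens = [(p + 1, residues[p]) for p in range(L)]
            tokens = _apply_indels(rng, tokens, anchor_positions, config.indel_rate)
            sequence = "".join(res for _, res in tokens)
            pos_map = {
                ref_pos: k + 1
                for k, (ref_pos, _) in enumerate(tokens)
                if ref_pos in anchor_positions
            }
            records.append(
                ProteinRecord(
                    id=member_id, sequence=sequence, species="synthetic", group_label=g
                )
            )
            truth[member_id] = g
            anchor_maps[member_id] = pos_map
    ref_record = ProteinRecord(
        id="REF", sequence="".join(reference), species="synthetic reference"
    )
    return FamilySimResult(
        records=tuple(records),
        truth=truth,
        reference=ref_record,
        anchor_maps=anchor_maps,
        config=config,
    )


# ---------------------------------------------------------------------------
# Neighborhoods
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeighborhoodSimConfig:
    """Planted gene-context co-occurrence probabilities per group."""

    group_partners: Mapping[str, Mapping[str, float]]
    background_cogs: tuple  # tuple[(cog, weight), ...]
    window: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.window < 1:
            raise SimulationError("window must be >= 1")
        if not self.background_cogs:
            raise SimulationError("at least one background COG is required")
        for cog, weight in self.background_cogs:
            if weight < 0:
                raise SimulationError(f"background weight for {cog!r} must be >= 0")
        if sum(w for _, w in self.background_cogs) <= 0:
            raise SimulationError("background weights must not all be zero")
        for g, partners in self.group_partners.items():
            for cog, p in partners.items():
                if not 0 <= p <= 1:
                    raise SimulationError(
                        f"group {g}: probability for {cog!r} must be in [0, 1]"
                    )
            if len(partners) > 2 * self.window:
                raise SimulationError(
                    f"group {g}: {len(partners)} signature COGs exceed the "
                    f"{2 * self.window} neighborhood slots"
                )


def simulate_neighborhoods(truth: Mapping[str, str], config: NeighborhoodSimConfig):
    """One neighborhood per member: planted partners + background filler.

    Each signature COG of the member's group is present independently with
    its planted probability; the remaining slots (of exactly ``2 * window``)
    are filled by weighted sampling from the background pool. Offsets are a
    random permutation of ±1..±window. Deterministic given ``config.seed``.
    """
    from .io_formats import NeighborhoodRecord

    rng = np.random.default_rng(config.seed)
    bg_labels = [c for c, _ in config.background_cogs]
    weights = np.array([w for _, w in config.background_cogs], dtype=float)
    weights = weights / weights.sum()
    offsets = [o for o in range(-config.window, config.window + 1) if o != 0]
    records = []
    for member in sorted(truth):
        group = truth[member]
        partners = config.group_partners.get(group, {})
        included = [
            cog for cog, p in sorted(partners.items()) if rng.random() < p
        ]
        n_fill = 2 * config.window - len(included)
        fill = [
            bg_labels[k] for k in rng.choice(len(bg_labels), size=n_fill, p=weights)
        ]
        cogs = included + fill
        order = rng.permutation(len(offsets))
        flank = tuple(
            sorted((offsets[k], cogs[i]) for i, k in enumerate(order))
        )
        records.append(
            NeighborhoodRecord(
                genome_id=f"genome_{member}", anchor_gene_id=member, flank=flank
            )
        )
    return records


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticsSimConfig:
    """Planted rate-law parameters and a measurement design."""

    true_km: float  # mM
    true_kcat: float  # s^-1
    enzyme_conc: float  # µM
    substrate_grid: tuple  # mM values
    inhibitor_grid: Optional[tuple] = None  # mM values (may include 0)
    true_ki: Optional[float] = None  # mM, required with inhibitor_grid
    noise_cv: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.true_km <= 0 or self.true_kcat <= 0 or self.enzyme_conc <= 0:
            raise SimulationError("km, kcat and enzyme concentration must be > 0")
        if not self.substrate_grid or any(s <= 0 for s in self.substrate_grid):
            raise SimulationError("substrate grid must be non-empty and positive")
        if self.inhibitor_grid is not None:
            if self.true_ki is None or self.true_ki <= 0:
                raise SimulationError("inhibitor grid requires true_ki > 0")
            if any(i < 0 for i in self.inhibitor_grid):
                raise SimulationError("inhibitor concentrations must be >= 0")
        if self.noise_cv < 0:
            raise SimulationError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise SimulationError("replicates must be >= 1")


def simulate_kinetics(config: KineticsSimConfig) -> KineticsDataset:
    """Initial rates from the (inhibited) saturation model with CV noise.

    ``v = kcat [E] S / (Km (1 + I/Ki) + S)`` scaled by a multiplicative
    Gaussian factor ``1 + noise_cv * z`` — the typical enzymology error
    structure, keeping rates positive at realistic CVs.
    """
    rng = np.random.default_rng(config.seed)
    inhibitors = (
        [None] if config.inhibitor_grid is None else list(config.inhibitor_grid)
    )
    points = []
    for inhibitor in inhibitors:
        for s in config.substrate_grid:
            i_term = 0.0 if inhibitor in (None, 0) else inhibitor / config.true_ki
            v_true = (
                config.true_kcat
                * config.enzyme_conc
                * s
                / (config.true_km * (1.0 + i_term) + s)
            )
            for rep in range(config.replicates):
                factor = 1.0 + config.noise_cv * rng.standard_normal()
                points.append(
                    KineticsPoint(
                        S=float(s),
                        I=None if inhibitor is None else float(inhibitor),
                        v=float(v_true * factor),
                        replicate=rep,
                    )
                )
    return KineticsDataset(
        points=tuple(points),
        enzyme_conc=config.enzyme_conc,
    )
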