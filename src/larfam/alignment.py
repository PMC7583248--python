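"""Multiple sequence alignment with explicit column/residue coordinate maps.

The internal aligner is a standard progressive scheme: word-composition
distances feed an average-linkage guide tree, profiles are merged bottom-up
with an affine-gap Gotoh DP. It exists so the pipeline is self-contained and
deterministic; externally produced alignments (aligned FASTA) are accepted
as first-class input via :func:`read_alignment`.

Conventions fixed for cross-platform determinism:

* gap of length ``k`` costs ``gap_open + (k - 1) * gap_extend``;
* DP backtrace prefers match/mismatch, then gap-in-first (gap character in
  the first sequence), then gap-in-second.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import AlignmentError, DuplicateIdError, ValidationError
from .io_formats import AMINO_ACIDS, ProteinRecord

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_NEG = -1e30


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 restricted to the 20 canonical residues, ordered as AMINO_ACIDS."""
    raw = substitution_matrices.load("BLOSUM62")
    m = np.empty((20, 20), dtype=float)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = raw[a, b]
    return m


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix plus affine gap penalties (penalties are positive)."""

    matrix: np.ndarray = field(default_factory=blosum62_matrix)
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if self.matrix.shape != (20, 20):
            raise ValidationError("substitution matrix must be 20x20")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValidationError("gap penalties must be non-negative")

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[_AA_INDEX[a], _AA_INDEX[b]])


DEFAULT_SCORING = None  # created lazily; building BLOSUM62 costs a little


def default_scoring() -> Scoring:
    global DEFAULT_SCORING
    if DEFAULT_SCORING is None:
        DEFAULT_SCORING = Scoring()
    return DEFAULT_SCORING


# ---------------------------------------------------------------------------
# Msa
# ---------------------------------------------------------------------------


class Msa:
    """A gapped alignment with bidirectional column <-> residue coordinate maps.

    Rows are ``(record_id, gapped_sequence)`` in a fixed order; all gapped
    sequences have equal length and degap to the original input exactly.
    Residue positions are 1-based (reference-numbering convention); columns
    are 0-based.
    """

    GAP = "-"

    def __init__(self, rows: Sequence):
        rows = [(str(i), str(s).upper()) for i, s in rows]
        if not rows:
            raise ValidationError("Msa requires at least one row")
        n_cols = len(rows[0][1])
        ids = set()
        for rid, seq in rows:
            if rid in ids:
                raise DuplicateIdError(f"duplicate row id {rid!r} in Msa")
            ids.add(rid)
            if len(seq) != n_cols:
                raise ValidationError(
                    f"row {rid!r} has length {len(seq)}, expected {n_cols}"
                )
            bad = set(seq) - set(AMINO_ACIDS) - {self.GAP}
            if bad:
                raise ValidationError(f"row {rid!r}: illegal characters {sorted(bad)}")
        self.rows = rows
        self.n_cols = n_cols
        self._index = {rid: k for k, (rid, _) in enumerate(rows)}
        self._col_of = {}
        self._pos_of = {}
        for rid, seq in rows:
            cols = [c for c, ch in enumerate(seq) if ch != self.GAP]
            self._col_of[rid] = cols  # cols[pos-1] = column of 1-based pos
            pos_map = {}
            for p, c in enumerate(cols, start=1):
                pos_map[c] = p
            self._pos_of[rid] = pos_map

    @property
    def ids(self) -> list:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        return self.rows[self._index[rid]][1]

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(self.GAP, "")

    def col_of(self, rid: str, position: int) -> int:
        """0-based column holding the 1-based ungapped ``position`` of row ``rid``."""
        cols = self._col_of[rid]
        if not 1 <= position <= len(cols):
            raise ValidationError(
                f"position {position} out of range for row {rid!r} "
                f"(ungapped length {len(cols)})"
            )
        return cols[position - 1]

    def pos_of(self, rid: str, column: int) -> Optional[int]:
        """1-based ungapped position at ``column`` of row ``rid`` (None at a gap)."""
        if not 0 <= column < self.n_cols:
            raise ValidationError(f"column {column} out of range")
        return self._pos_of[rid].get(column)

    def column(self, column: int) -> list:
        return [seq[column] for _, seq in self.rows]

    def subset(self, ids: Iterable[str]) -> "Msa":
        wanted = list(ids)
        return Msa([(rid, self.row(rid)) for rid in wanted])

    def __len__(self) -> int:
        return len(self.rows)


def read_alignment(path) -> Msa:
    """Read an aligned FASTA file (rows may contain '-')."""
    from Bio import SeqIO

    rows = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise DuplicateIdError(f"{path}: duplicate row id {entry.id!r}")
        seen.add(entry.id)
        rows.append((entry.id, str(entry.seq).upper()))
    return Msa(rows)


def write_alignment(msa: Msa, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in msa.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Pairwise Gotoh alignment
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def _gotoh_fill(sub: np.ndarray, open_: float, ext: float):
    """Fill Gotoh matrices for a precomputed position-score matrix ``sub``.

    ``sub[i, j]`` is the score of aligning item ``i`` of the first sequence
    with item ``j`` of the second (0-based). Returns (M, A, B) of shape
    (n+1, m+1) where A holds best scores ending in gap-in-first (consuming
    the second sequence) and B gap-in-second.
    """
    n, m = sub.shape
    M = np.full((n + 1, m + 1), _NEG)
    A = np.full((n + 1, m + 1), _NEG)
    B = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    A[0, 1:] = -(open_ + (j - 1) * ext)
    i = np.arange(1, n + 1)
    B[1:, 0] = -(open_ + (i - 1) * ext)
    jj = np.arange(m + 1)
    for i in range(1, n + 1):
        M[i, 1:] = sub[i - 1, :] + np.maximum.reduce(
            [M[i - 1, :-1], A[i - 1, :-1], B[i - 1, :-1]]
        )
        B[i, :] = np.maximum.reduce(
            [M[i - 1, :] - open_, A[i - 1, :] - open_, B[i - 1, :] - ext]
        )
        # A[i, j] = max_{k < j} (max(M, B)[i, k] - open - (j-1-k) * ext):
        # running max over H[i, k] + k*ext, shifted — single accumulate pass.
        H = np.maximum(M[i, :], B[i, :])
        run = np.maximum.accumulate(H + jj * ext)
        A[i, 1:] = run[:-1] - open_ - (jj[1:] - 1) * ext
    return M, A, B


def _gotoh_backtrace(M, A, B, open_, ext):
    """Deterministic backtrace; returns list of ('M'|'A'|'B') column states."""
    n = M.shape[0] - 1
    m = M.shape[1] - 1
    tol = 1e-9 * max(1.0, abs(M[n, m]) if M[n, m] > _NEG / 2 else 1.0)

    def close(x, y):
        return abs(x - y) <= max(tol, 1e-6)

    finals = {"M": M[n, m], "A": A[n, m], "B": B[n, m]}
    best = max(finals.values())
    state = next(s for s in ("M", "A", "B") if close(finals[s], best))
    i, j = n, m
    path = []
    while i > 0 or j > 0:
        path.append(state)
        if state == "M":
            value = M[i, j]
            prev = value - (value - max(M[i - 1, j - 1], A[i - 1, j - 1], B[i - 1, j - 1]))
            # predecessor is whichever of M/A/B at (i-1, j-1) attains the max
            cands = (
                ("M", M[i - 1, j - 1]),
                ("A", A[i - 1, j - 1]),
                ("B", B[i - 1, j - 1]),
            )
            target = max(v for _, v in cands)
            state = next(s for s, v in cands if close(v, target))
            i -= 1
            j -= 1
        elif state == "A":  # gap in first sequence, consumed second[j-1]
            value = A[i, j]
            if close(value, M[i, j - 1] - open_):
                state = "M"
            elif close(value, B[i, j - 1] - open_):
                state = "B"
            else:
                state = "A"
            j -= 1
        else:  # 'B': gap in second sequence, consumed first[i-1]
            value = B[i, j]
            if close(value, M[i - 1, j] - open_):
                state = "M"
            elif close(value, A[i - 1, j] - open_):
                state = "A"
            else:
                state = "B"
            i -= 1
    path.reverse()
    return path, best


def pairwise_align(a: str, b: str, scoring: Optional[Scoring] = None):
    """Optimal global alignment of two sequences under affine gap scoring.

    Returns ``(gapped_a, gapped_b, score)``. Ties on the backtrace are broken
    match/mismatch > gap-in-first > gap-in-second, so output is deterministic.
    """
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    scoring = scoring or default_scoring()
    ea, eb = _encode(a), _encode(b)
    sub = scoring.matrix[np.ix_(ea, eb)]
    M, A, B = _gotoh_fill(sub, scoring.gap_open, scoring.gap_extend)
    path, score = _gotoh_backtrace(M, A, B, scoring.gap_open, scoring.gap_extend)
    ga, gb = [], []
    ia = ib = 0
    for state in path:
        if state == "M":
            ga.append(a[ia])
            gb.append(b[ib])
            ia += 1
            ib += 1
        elif state == "A":
            ga.append(Msa.GAP)
            gb.append(b[ib])
            ib += 1
        else:
            ga.append(a[ia])
            gb.append(Msa.GAP)
            ia += 1
    return "".join(ga), "".join(gb), float(score)


def score_pairwise_alignment(ga: str, gb: str, scoring: Optional[Scoring] = None) -> float:
    """Score an existing pairwise alignment under the package's conventions.

    Columns where both rows are gaps are ignored; a gap run of length ``k``
    costs ``open + (k - 1) * extend`` (terminal gaps included).
    """
    scoring = scoring or default_scoring()
    total = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(ga, gb):
        if ca == Msa.GAP and cb == Msa.GAP:
            continue
        if ca == Msa.GAP:
            total -= scoring.gap_extend if in_gap_a else scoring.gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == Msa.GAP:
            total -= scoring.gap_extend if in_gap_b else scoring.gap_open
            in_gap_b, in_gap_a = True, False
        else:
            total += scoring.score(ca, cb)
            in_gap_a = in_gap_b = False
    return total


# ---------------------------------------------------------------------------
# Distance matrices and guide tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] over an ordered id list."""

    ids: tuple
    d: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match id count")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix must be symmetric")
        if self.d.min() < -1e-12 or self.d.max() > 1 + 1e-12:
            raise ValidationError("distances must lie in [0, 1]")

    def get(self, a: str, b: str) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.d[ia, ib])

    def subset(self, ids: Iterable[str]) -> "DistanceMatrix":
        wanted = list(ids)
        idx = [self.ids.index(i) for i in wanted]
        return DistanceMatrix(tuple(wanted), self.d[np.ix_(idx, idx)].copy())

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids)).to_csv(
            path, sep="\t"
        )


@dataclass(frozen=True)
class TreeNode:
    """Binary guide-tree node; leaves carry an id, internal nodes children."""

    id: Optional[str] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.id is not None

    def leaves(self) -> list:
        if self.is_leaf:
            return [self.id]
        return self.left.leaves() + self.right.leaves()

    def newick(self) -> str:
        """Canonical newick (children sorted by smallest leaf id)."""
        if self.is_leaf:
            return self.id
        parts = sorted(
            (self.left.newick(), self.right.newick()),
            key=lambda s: s.strip("(").split(",")[0],
        )
        return "(" + ",".join(parts) + ")"


def build_guide_tree(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomerative joining order over the ids of ``dm``.

    Ids are processed in lexicographic order so equal-distance ties resolve
    identically regardless of input ordering.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    if len(dm.ids) < 2:
        raise AlignmentError("guide tree requires at least 2 sequences")
    order = sorted(range(len(dm.ids)), key=lambda k: dm.ids[k])
    ids = [dm.ids[k] for k in order]
    d = dm.d[np.ix_(order, order)]
    condensed = squareform(d, checks=False)
    Z = linkage(condensed, method="average")
    nodes = [TreeNode(id=i) for i in ids]
    for a, b, _, _ in Z:
        nodes.append(TreeNode(left=nodes[int(a)], right=nodes[int(b)]))
    return nodes[-1]


def kmer_distance_matrix(records: Sequence[ProteinRecord], k: int = 3) -> DistanceMatrix:
    """Fast word-composition distance: 1 - |shared k-mers| / min(#k-mers).

    Used only to build the guide tree (the classic quick-pairwise shortcut);
    grouping distances come from :func:`p_distance` on the final alignment.
    """
    ids = tuple(r.id for r in records)
    sets = [
        {r.sequence[i : i + k] for i in range(max(1, len(r.sequence) - k + 1))}
        for r in records
    ]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            shared = len(sets[i] & sets[j])
            d[i, j] = d[j, i] = 1.0 - shared / denom if denom else 1.0
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# Progressive profile alignment
# ---------------------------------------------------------------------------


class _Profile:
    """A sub-alignment plus its per-column residue frequency matrix."""

    __slots__ = ("ids", "seqs", "freqs")

    def __init__(self, ids, seqs):
        self.ids = ids
        self.seqs = seqs
        n_cols = len(seqs[0])
        counts = np.zeros((n_cols, 20))
        for seq in seqs:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            for aa, idx in _AA_INDEX.items():
                counts[arr == ord(aa), idx] += 1
        # frequencies normalised by the number of rows: gaps carry zero weight
        self.freqs = counts / len(seqs)


def _align_profiles(p1: _Profile, p2: _Profile, scoring: Scoring) -> _Profile:
    sub = p1.freqs @ scoring.matrix @ p2.freqs.T
    M, A, B = _gotoh_fill(sub, scoring.gap_open, scoring.gap_extend)
    path, _ = _gotoh_backtrace(M, A, B, scoring.gap_open, scoring.gap_extend)
    out1 = [[] for _ in p1.seqs]
    out2 = [[] for _ in p2.seqs]
    i = j = 0
    for state in path:
        if state == "M":
            for r, seq in zip(out1, p1.seqs):
                r.append(seq[i])
            for r, seq in zip(out2, p2.seqs):
                r.append(seq[j])
            i += 1
            j += 1
        elif state == "A":  # gap inserted into profile 1
            for r in out1:
                r.append(Msa.GAP)
            for r, seq in zip(out2, p2.seqs):
                r.append(seq[j])
            j += 1
        else:  # gap inserted into profile 2
            for r, seq in zip(out1, p1.seqs):
                r.append(seq[i])
            for r in out2:
                r.append(Msa.GAP)
            i += 1
    ids = list(p1.ids) + list(p2.ids)
    seqs = ["".join(r) for r in out1] + ["".join(r) for r in out2]
    return _Profile(ids, seqs)


def progressive_align(
    records: Sequence[ProteinRecord], scoring: Optional[Scoring] = None
) -> Msa:
    """Progressive profile-profile alignment along an average-linkage guide tree.

    Deterministic: guide-tree construction sorts ids, and DP tie-breaking is
    fixed. A single record yields a degenerate gap-free Msa. Output row order
    matches input order.
    """
    if not records:
        raise AlignmentError("no records to align")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise DuplicateIdError("duplicate record ids in alignment input")
    if len(records) == 1:
        return Msa([(records[0].id, records[0].sequence)])
    scoring = scoring or default_scoring()
    by_id = {r.id: r for r in records}
    tree = build_guide_tree(kmer_distance_matrix(records))

    def align_node(node: TreeNode) -> _Profile:
        if node.is_leaf:
            rec = by_id[node.id]
            return _Profile([rec.id], [rec.sequence])
        return _align_profiles(align_node(node.left), align_node(node.right), scoring)

    prof = align_node(tree)
    row_map = dict(zip(prof.ids, prof.seqs))
    msa = Msa([(rid, row_map[rid]) for rid in ids])
    for r in records:  # degapping invariant, checked on every produced Msa
        if msa.ungapped(r.id) != r.sequence:
            raise AlignmentError(f"degapping invariant violated for row {r.id!r}")
    return msa


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------


def p_distance(msa: Msa) -> DistanceMatrix:
    """1 - fractional identity over columns where neither row is gapped.

    Pairs with no comparable columns get distance 1 with a logged warning.
    """
    n = len(msa)
    chars = np.array([list(seq) for _, seq in msa.rows])
    not_gap = chars != Msa.GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = not_gap[i] & not_gap[j]
            comparable = int(both.sum())
            if comparable == 0:
                logger.warning(
                    "rows %r and %r share no comparable columns; distance set to 1",
                    msa.rows[i][0],
                    msa.rows[j][0],
                )
                d[i, j] = d[j, i] = 1.0
                continue
            matches = int((chars[i][both] == chars[j][both]).sum())
            d[i, j] = d[j, i] = 1.0 - matches / comparable
    return DistanceMatrix(tuple(msa.ids), d)
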