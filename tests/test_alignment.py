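import numpy as np
import pytest

from larfam.alignment import (
    DistanceMatrix,
    Msa,
    Scoring,
    build_guide_tree,
    kmer_distance_matrix,
    p_distance,
    pairwise_align,
    progressive_align,
    read_alignment,
    score_pairwise_alignment,
    write_alignment,
)
from larfam.errors import AlignmentError, ValidationError
from larfam.io_formats import ProteinRecord

from conftest import random_protein


def oracle_global_score(a, b, scoring):
    """Independent quadratic-space affine-gap DP (plain Python, 3 states)."""
    open_, ext = scoring.gap_open, scoring.gap_extend
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    A = [[NEG] * (m + 1) for _ in range(n + 1)]
    B = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        A[0][j] = -(open_ + (j - 1) * ext)
    for i in range(1, n + 1):
        B[i][0] = -(open_ + (i - 1) * ext)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scoring.score(a[i - 1], b[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], A[i - 1][j - 1], B[i - 1][j - 1])
            A[i][j] = max(
                M[i][j - 1] - open_, B[i][j - 1] - open_, A[i][j - 1] - ext
            )
            B[i][j] = max(
                M[i - 1][j] - open_, A[i - 1][j] - open_, B[i - 1][j] - ext
            )
    return max(M[n][m], A[n][m], B[n][m])


class TestMsa:
    def test_coordinate_maps_inverse(self):
        msa = Msa([("a", "M-KV"), ("b", "MAK-")])
        assert msa.col_of("a", 1) == 0
        assert msa.col_of("a", 2) == 2
        assert msa.pos_of("a", 1) is None
        for rid in msa.ids:
            for col in range(msa.n_cols):
                pos = msa.pos_of(rid, col)
                if pos is not None:
                    assert msa.col_of(rid, pos) == col

    def test_degap_round_trip(self):
        msa = Msa([("a", "M-KV"), ("b", "MAK-")])
        assert msa.ungapped("a") == "MKV"
        assert msa.ungapped("b") == "MAK"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            Msa([("a", "MK"), ("b", "MKV")])

    def test_aligned_fasta_round_trip(self, tmp_path):
        msa = Msa([("a", "M-KV"), ("b", "MAK-")])
        path = tmp_path / "aln.fasta"
        write_alignment(msa, path)
        back = read_alignment(path)
        assert back.rows == msa.rows


class TestPairwiseAlign:
    def test_identity_no_gaps(self, scoring):
        seq = "MKVLAWHE"
        ga, gb, score = pairwise_align(seq, seq, scoring)
        assert ga == gb == seq
        expected = sum(scoring.score(c, c) for c in seq)
        assert score == pytest.approx(expected)

    def test_single_forced_gap(self, scoring):
        ga, gb, _ = pairwise_align("MKV", "MV", scoring)
        assert (ga + gb).count("-") == 1

    def test_empty_sequence_rejected(self, scoring):
        with pytest.raises(AlignmentError):
            pairwise_align("", "MKV", scoring)

    def test_matches_dp_oracle_on_random_pairs(self, scoring):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = random_protein(rng, int(rng.integers(1, 41)))
            b = random_protein(rng, int(rng.integers(1, 41)))
            ga, gb, score = pairwise_align(a, b, scoring)
            assert score == pytest.approx(oracle_global_score(a, b, scoring))
            # the emitted alignment realises the claimed score
            assert score_pairwise_alignment(ga, gb, scoring) == pytest.approx(score)
            assert ga.replace("-", "") == a
            assert gb.replace("-", "") == b

    def test_deterministic(self, scoring):
        rng = np.random.default_rng(0)
        a = random_protein(rng, 30)
        b = random_protein(rng, 25)
        assert pairwise_align(a, b, scoring) == pairwise_align(a, b, scoring)


class TestGuideTree:
    def _dm(self, ids, entries):
        n = len(ids)
        d = np.zeros((n, n))
        for (i, j), value in entries.items():
            d[i, j] = d[j, i] = value
        return DistanceMatrix(tuple(ids), d)

    def test_closest_pair_joined_first(self):
        dm = self._dm(["A", "B", "C"], {(0, 1): 0.1, (0, 2): 0.9, (1, 2): 0.9})
        assert build_guide_tree(dm).newick() == "((A,B),C)"

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        ids = [f"S{k}" for k in range(6)]
        d = rng.random((6, 6))
        d = (d + d.T) / 2 * 0.9
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(tuple(ids), d)
        perm = [3, 0, 5, 1, 4, 2]
        dm2 = dm.subset([ids[k] for k in perm])
        assert build_guide_tree(dm).newick() == build_guide_tree(dm2).newick()

    def test_all_equal_tie_break_lexicographic(self):
        dm = self._dm(["C", "A", "B"], {(0, 1): 0.5, (0, 2): 0.5, (1, 2): 0.5})
        # lexicographically first pair (A, B) joins first
        assert build_guide_tree(dm).newick() == "((A,B),C)"

    def test_single_id_rejected(self):
        dm = DistanceMatrix(("A",), np.zeros((1, 1)))
        with pytest.raises(AlignmentError):
            build_guide_tree(dm)


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        records = [ProteinRecord(id=f"s{k}", sequence="MKVLAWHE") for k in range(4)]
        msa = progressive_align(records)
        assert msa.n_cols == 8
        assert all("-" not in seq for _, seq in msa.rows)

    def test_single_record_degenerate(self):
        (rec,) = [ProteinRecord(id="a", sequence="MKV")]
        msa = progressive_align([rec])
        assert msa.rows == [("a", "MKV")]

    def test_degap_invariant(self):
        rng = np.random.default_rng(11)
        base = random_protein(rng, 60)
        records = []
        for k in range(6):
            seq = list(base)
            for _ in range(6):
                seq[int(rng.integers(0, 60))] = random_protein(rng, 1)
            if k % 2:
                del seq[int(rng.integers(0, 50))]
            records.append(ProteinRecord(id=f"r{k}", sequence="".join(seq)))
        msa = progressive_align(records)
        for rec in records:
            assert msa.ungapped(rec.id) == rec.sequence

    def test_anchor_co_columnation_noise_free(self, noise_free_family):
        fam = noise_free_family
        msa = progressive_align([fam.reference, *fam.records])
        config = fam.config.anchor_config("REF")
        for anchor in config.anchors:
            col = msa.col_of("REF", anchor.position)
            for rec in fam.records:
                member_pos = fam.anchor_maps[rec.id][anchor.position]
                assert msa.col_of(rec.id, member_pos) == col

    def test_anchor_co_columnation_with_indels_95pct(self):
        from larfam.synthetic_data import FamilySimConfig, simulate_family

        fam = simulate_family(
            FamilySimConfig(n_groups=3, members_per_group=6, indel_rate=0.01, seed=5)
        )
        msa = progressive_align([fam.reference, *fam.records])
        config = fam.config.anchor_config("REF")
        hits = total = 0
        for anchor in config.anchors:
            col = msa.col_of("REF", anchor.position)
            for rec in fam.records:
                member_pos = fam.anchor_maps[rec.id][anchor.position]
                total += 1
                hits += msa.col_of(rec.id, member_pos) == col
        assert hits / total >= 0.95

    def test_progressive_admissible_vs_pairwise_oracle(self, scoring):
        rng = np.random.default_rng(21)
        base = random_protein(rng, 40)
        records = []
        for k in range(5):
            seq = list(base)
            for _ in range(8):
                seq[int(rng.integers(0, len(seq)))] = random_protein(rng, 1)
            if k >= 3:
                del seq[5:7]
            records.append(ProteinRecord(id=f"p{k}", sequence="".join(seq)))
        msa = progressive_align(records, scoring)
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                ga = msa.row(records[i].id)
                gb = msa.row(records[j].id)
                induced = score_pairwise_alignment(ga, gb, scoring)
                optimal = oracle_global_score(
                    records[i].sequence, records[j].sequence, scoring
                )
                assert induced <= optimal + 1e-9

    def test_duplicate_row_does_not_shift_original_columns(self):
        rng = np.random.default_rng(8)
        base = random_protein(rng, 50)
        records = []
        for k in range(5):
            seq = list(base)
            for _ in range(10):
                seq[int(rng.integers(0, len(seq)))] = random_protein(rng, 1)
            records.append(ProteinRecord(id=f"q{k}", sequence="".join(seq)))
        msa1 = progressive_align(records)
        dup = ProteinRecord(id="q2_dup", sequence=records[2].sequence)
        msa2 = progressive_align(records + [dup])

        def induced(msa, x, y):
            gx, gy = msa.row(x), msa.row(y)
            return [
                (cx, cy)
                for cx, cy in zip(gx, gy)
                if not (cx == "-" and cy == "-")
            ]

        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                assert induced(msa1, f"q{i}", f"q{j}") == induced(
                    msa2, f"q{i}", f"q{j}"
                )


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = Msa([("a", "MKVA"), ("b", "MKVA")])
        assert p_distance(msa).get("a", "b") == 0.0

    def test_direct_count(self):
        msa = Msa([("a", "AAAA"), ("b", "AAAT")])
        assert p_distance(msa).get("a", "b") == pytest.approx(0.25)

    def test_gaps_excluded_from_denominator(self):
        msa = Msa([("a", "MK-A"), ("b", "MKV-")])
        # comparable columns: 0, 1 -> both match
        assert p_distance(msa).get("a", "b") == 0.0

    def test_no_comparable_positions_distance_one(self, caplog):
        msa = Msa([("a", "MK--"), ("b", "--VA")])
        with caplog.at_level("WARNING"):
            dm = p_distance(msa)
        assert dm.get("a", "b") == 1.0
        assert any("comparable" in m for m in caplog.messages)

    def test_matches_hand_count_on_random_gapped_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            rows = []
            for rid in ("x", "y"):
                chars = [
                    "-" if rng.random() < 0.2 else random_protein(rng, 1)
                    for _ in range(n)
                ]
                if all(c == "-" for c in chars):
                    chars[0] = "A"
                rows.append((rid, "".join(chars)))
            msa = Msa(rows)
            gx, gy = rows[0][1], rows[1][1]
            comparable = [
                (a, b) for a, b in zip(gx, gy) if a != "-" and b != "-"
            ]
            if not comparable:
                expected = 1.0
            else:
                matches = sum(a == b for a, b in comparable)
                expected = 1.0 - matches / len(comparable)
            assert p_distance(msa).get("x", "y") == pytest.approx(expected)


class TestKmerDistance:
    def test_identical_sequences_distance_zero(self):
        recs = [
            ProteinRecord(id="a", sequence="MKVLAWHE"),
            ProteinRecord(id="b", sequence="MKVLAWHE"),
        ]
        assert kmer_distance_matrix(recs).get("a", "b") == 0.0

    def test_bounds(self):
        rng = np.random.default_rng(2)
        recs = [
            ProteinRecord(id=f"s{k}", sequence=random_protein(rng, 50))
            for k in range(5)
        ]
        dm = kmer_distance_matrix(recs)
        assert dm.d.min() >= 0.0 and dm.d.max() <= 1.0
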