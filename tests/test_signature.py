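import math

import numpy as np
import pytest

from larfam.alignment import Msa
from larfam.errors import SignatureError
from larfam.io_formats import default_anchor_config
from larfam.signature import (
    ActivitySignature,
    assign_category_color,
    build_group_profile,
    builtin_activity_signatures,
    classify_group,
    column_profile,
    information_content,
    map_anchor_columns,
    text_logo,
)
from larfam.synthetic_data import FamilySimConfig, simulate_family

LOG2_20 = math.log2(20)


def family_msa(fam):
    """Indel-free families stack into a degenerate (gap-free) alignment."""
    return Msa([("REF", fam.reference.sequence)] + [
        (r.id, r.sequence) for r in fam.records
    ])


def group_members(fam, label):
    return sorted(m for m, g in fam.truth.items() if g == label)


class TestMapAnchorColumns:
    def test_gap_free_identity(self, noise_free_family):
        fam = noise_free_family
        msa = family_msa(fam)
        config = fam.config.anchor_config("REF")
        columns = map_anchor_columns(msa, config)
        for anchor in config.anchors:
            assert columns[anchor.position] == anchor.position - 1

    def test_single_gap_shift(self):
        msa = Msa([("REF", "M-KV"), ("x", "MAKV")])
        from larfam.io_formats import Anchor, AnchorConfig

        config = AnchorConfig("REF", (Anchor(2, "K", "other"),))
        assert map_anchor_columns(msa, config) == {2: 2}

    def test_reference_absent_rejected(self):
        msa = Msa([("a", "MKV")])
        config = default_anchor_config("REF")
        with pytest.raises(SignatureError, match="reference"):
            map_anchor_columns(msa, config)


class TestColumnProfile:
    def test_unanimous_column(self):
        msa = Msa([(f"m{k}", "FA") for k in range(4)])
        prof = column_profile(msa, msa.ids, 0)
        assert prof.freqs == {"F": 1.0}
        assert prof.gap_fraction == 0.0
        assert prof.n_effective == 4

    def test_mixed_column(self):
        msa = Msa([("a", "F"), ("b", "F"), ("c", "L"), ("d", "M")])
        prof = column_profile(msa, msa.ids, 0)
        assert prof.freqs == pytest.approx({"F": 0.5, "L": 0.25, "M": 0.25})

    def test_gap_rows_only_in_gap_fraction(self):
        msa = Msa([("a", "F"), ("b", "-")])
        prof = column_profile(msa, msa.ids, 0)
        assert prof.freqs == {"F": 1.0}
        assert prof.gap_fraction == pytest.approx(0.5)
        assert prof.n_effective == 1

    def test_all_gap_column_flagged(self):
        msa = Msa([("a", "-F"), ("b", "-F")])
        prof = column_profile(msa, msa.ids, 0)
        assert prof.is_empty
        assert prof.dominant_residue is None
        with pytest.raises(SignatureError):
            information_content(prof.freqs, prof.n_effective)

    def test_frequencies_sum_to_one(self, default_family):
        fam = default_family
        msa = family_msa(fam)
        rng = np.random.default_rng(0)
        for col in rng.integers(0, msa.n_cols, size=30):
            prof = column_profile(msa, group_members(fam, "1"), int(col))
            if not prof.is_empty:
                assert sum(prof.freqs.values()) == pytest.approx(1.0)

    def test_dominant_tie_lexicographic(self):
        msa = Msa([("a", "W"), ("b", "A")])
        prof = column_profile(msa, msa.ids, 0)
        assert prof.dominant_residue == "A"


class TestInformationContent:
    def test_uniform_is_zero_without_correction(self):
        freqs = {aa: 1 / 20 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        assert information_content(freqs, 100, False) == pytest.approx(0.0)

    def test_single_residue_max_bits(self):
        assert information_content({"F": 1.0}, 5, False) == pytest.approx(LOG2_20)

    def test_small_sample_correction_closed_form(self):
        # direct evaluation of R = log2(20) - (H + (s-1)/(2 ln2 n)), clamped
        freqs = {"F": 0.5, "L": 0.25, "M": 0.25}
        h = 1.5
        for n in (4, 40):
            e_n = 19 / (2 * math.log(2) * n)
            expected = max(0.0, LOG2_20 - (h + e_n))
            assert information_content(freqs, n, True) == pytest.approx(expected)

    def test_monotone_toward_uniform(self):
        base = {"F": 0.7, "L": 0.2, "M": 0.1}
        uniform = {aa: 1 / 20 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        values = []
        for t in np.linspace(0, 1, 11):
            mixed = {
                aa: (1 - t) * base.get(aa, 0.0) + t * uniform[aa]
                for aa in uniform
            }
            total = sum(mixed.values())
            mixed = {aa: f / total for aa, f in mixed.items() if f > 0}
            values.append(information_content(mixed, 1000, False))
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_zero_n_rejected(self):
        with pytest.raises(SignatureError):
            information_content({"F": 1.0}, 0)


class TestCategoryColor:
    def _prof(self, freqs, n=10):
        from larfam.signature import ColumnProfile

        return ColumnProfile(freqs=freqs, gap_fraction=0.0, n_effective=n)

    def test_catalytic_always_green(self):
        prof = self._prof({"A": 0.4, "D": 0.3, "E": 0.3})
        assert assign_category_color("catalytic", prof, "D", 0.7) == "green"

    def test_npn_always_blue(self):
        prof = self._prof({"R": 1.0})
        assert assign_category_color("npn_binding", prof, "R", 0.7) == "blue"

    def test_substrate_conserved_equal_reference_yellow(self):
        prof = self._prof({"F": 0.95, "L": 0.05})
        assert assign_category_color("substrate", prof, "F", 0.7) == "yellow"

    def test_substrate_conserved_differing_red(self):
        prof = self._prof({"K": 0.9, "F": 0.1})
        assert assign_category_color("substrate", prof, "F", 0.7) == "red"

    def test_not_conserved_black(self):
        prof = self._prof({"K": 0.4, "F": 0.3, "L": 0.3})
        assert assign_category_color("substrate", prof, "F", 0.7) == "black"


class TestClassifyGroup:
    def _profiles(self, fam):
        msa = family_msa(fam)
        config = fam.config.anchor_config("REF")
        return {
            g: build_group_profile(msa, g, group_members(fam, g), config)
            for g in fam.config.group_labels
        }, config

    def test_planted_activities_recovered(self, noise_free_family):
        from larfam.synthetic_data import DEFAULT_GROUP_ACTIVITIES

        profiles, config = self._profiles(noise_free_family)
        for g, profile in profiles.items():
            result = classify_group(profile, config)
            assert result.is_family_member
            assert result.predicted_activity == DEFAULT_GROUP_ACTIVITIES[g]
            assert result.match_scores[result.predicted_activity] == 1.0

    def test_gnte_variant_residues_match(self):
        # epimerase-like signature with the structure-observed variant
        # residues in helix regions still resolves to GntE
        sigs = {
            "1": {175: "E", 176: "S", 297: "G", 358: "N"},
            "2": {175: "F", 176: "F", 297: "V", 358: "W"},
        }
        fam = simulate_family(
            FamilySimConfig(
                n_groups=2, members_per_group=4, group_signatures=sigs,
                background_mutation_rate=0.0, group_divergence_rate=0.0,
                indel_rate=0.0, seed=1,
            )
        )
        profiles, config = self._profiles(fam)
        assert classify_group(profiles["1"], config).predicted_activity == "GntE"
        assert classify_group(profiles["2"], config).predicted_activity == "LAR"

    def test_broken_catalytic_lysine_excludes_group(self, noise_free_family):
        fam = noise_free_family
        rows = [("REF", fam.reference.sequence)]
        for rec in fam.records:
            seq = rec.sequence
            if fam.truth[rec.id] == "1":
                pos = fam.anchor_maps[rec.id][298]
                seq = seq[: pos - 1] + "M" + seq[pos:]
            rows.append((rec.id, seq))
        msa = Msa(rows)
        config = fam.config.anchor_config("REF")
        profile = build_group_profile(msa, "1", group_members(fam, "1"), config)
        result = classify_group(profile, config)
        assert not result.is_family_member
        assert 298 in result.missing_required
        assert result.predicted_activity == "unknown"

    def test_duplication_invariance_correction_off(self, noise_free_family):
        fam = noise_free_family
        msa = family_msa(fam)
        config = fam.config.anchor_config("REF")
        members = group_members(fam, "2")
        rows = [("REF", fam.reference.sequence)]
        for rec in fam.records:
            rows.append((rec.id, rec.sequence))
            if rec.id in members:
                rows.append((rec.id + "_dup", rec.sequence))
        msa2 = Msa(rows)
        p1 = build_group_profile(
            msa, "2", members, config, small_sample_correction=False
        )
        p2 = build_group_profile(
            msa2, "2", members + [m + "_dup" for m in members], config,
            small_sample_correction=False,
        )
        for pos in p1.anchors:
            assert p1.anchors[pos].profile.freqs == p2.anchors[pos].profile.freqs
            assert p1.anchors[pos].information_bits == pytest.approx(
                p2.anchors[pos].information_bits
            )
        r1 = classify_group(p1, config)
        r2 = classify_group(p2, config)
        assert r1.predicted_activity == r2.predicted_activity
        assert r1.is_family_member == r2.is_family_member

    def test_member_order_invariance(self, noise_free_family):
        fam = noise_free_family
        msa = family_msa(fam)
        config = fam.config.anchor_config("REF")
        members = group_members(fam, "3")
        a = classify_group(
            build_group_profile(msa, "3", members, config), config
        )
        b = classify_group(
            build_group_profile(msa, "3", members[::-1], config), config
        )
        assert a == b


class TestActivitySignature:
    def test_builtin_table_names(self):
        names = {s.name for s in builtin_activity_signatures()}
        assert names == {"LAR", "SAR", "MAR", "HGR", "GntE"}

    def test_requires_a_constraint(self):
        with pytest.raises(SignatureError):
            ActivitySignature("X", {})

    def test_mixed_lengths_rejected(self):
        with pytest.raises(SignatureError):
            ActivitySignature("X", {"loop": frozenset({"FF", "F"})})


def test_text_logo_smoke(noise_free_family):
    fam = noise_free_family
    msa = family_msa(fam)
    config = fam.config.anchor_config("REF")
    logo = text_logo(build_group_profile(msa, "1", group_members(fam, "1"), config))
    assert isinstance(logo, str)
    assert "F" in logo  # the loop phenylalanines show up somewhere
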