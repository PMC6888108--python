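import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cladesites import (
    CLADE_SHARED,
    CLADE_SPECIFIC,
    UNIVERSAL,
    VARIABLE,
    DomainAnnotation,
    LabeledAlignment,
    Policy,
    classify_column,
    default_scheme,
    load_sh3p_sites,
    order_by_frequency,
    profile_column,
    scan_alignment,
    summarize_counts,
)
from cladesites.classify import read_calls_tsv, read_site_table, write_calls_tsv

from naive_oracles import naive_classify, naive_order_by_frequency

SCHEME = default_scheme()


def column_aln(chars, clades):
    """Single-column alignment from parallel character/clade sequences."""
    records = tuple((f"s{i}", ch) for i, ch in enumerate(chars))
    clade_of = {f"s{i}": cl for i, cl in enumerate(clades)}
    return LabeledAlignment(records=records, clade_of=clade_of)


def call_of(chars, clades, min_clade_size=2):
    aln = column_aln(chars, clades)
    profile = profile_column(aln, SCHEME, 1)
    return classify_column(profile, Policy(min_clade_size))


class TestProfileColumn:
    def test_fixed_basic_clade(self):
        aln = column_aln("KKKDE", ["A"] * 3 + ["B"] * 2)
        p = profile_column(aln, SCHEME, 1).per_clade["A"]
        assert p.residues == Counter("KKK")
        assert p.gap_count == 0 and p.uncategorized_count == 0
        assert p.categories == frozenset({"basic"})

    def test_gap_excluded_from_residues(self):
        aln = column_aln("K-KDE", ["A"] * 3 + ["B"] * 2)
        p = profile_column(aln, SCHEME, 1).per_clade["A"]
        assert p.residues == Counter("KK") and p.gap_count == 1

    def test_uncategorized_counted(self):
        aln = column_aln("KXKDE", ["A"] * 3 + ["B"] * 2)
        p = profile_column(aln, SCHEME, 1).per_clade["A"]
        assert p.uncategorized_count == 1
        assert p.categories == frozenset({"basic"})

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from("ACDKX-"), min_size=4, max_size=12))
    def test_tallies_match_naive_recount(self, chars):
        clades = ["A", "B"] * (len(chars) // 2) + ["A"] * (len(chars) % 2)
        aln = column_aln(chars, clades)
        profile = profile_column(aln, SCHEME, 1)
        for clade in ("A", "B"):
            mine = [c for c, cl in zip(chars, clades) if cl == clade]
            p = profile.per_clade[clade]
            assert p.residues == Counter(c for c in mine if c != "-")
            assert p.gap_count == mine.count("-")
            assert p.uncategorized_count == mine.count("X")
            assert p.size == len(mine)


class TestClassifyColumn:
    def test_acid_vs_basic_is_clade_specific(self):
        # Focal clade admits D or E while all others are H or R.
        call = call_of("DEDHRHR", ["P3"] * 3 + ["P1"] * 2 + ["P2"] * 2)
        assert call.site_class == CLADE_SPECIFIC
        assert call.focal_clades == ("P3",)
        assert call.focal_categories["P3"] == "acid/amide"

    def test_gaps_elsewhere_do_not_block_specificity(self):
        # Focal clade fixed E; other clades show G or a gap.
        call = call_of("EEEG-G", ["P3"] * 3 + ["P1"] * 2 + ["P2"])
        assert call.site_class == CLADE_SPECIFIC
        assert call.focal_clades == ("P3",)

    def test_all_cysteine_is_universal(self):
        call = call_of("CCCCCC", ["A"] * 3 + ["B"] * 3)
        assert call.site_class == UNIVERSAL and call.focal_clades == ()

    def test_within_category_variation_still_universal(self):
        call = call_of("VILVIL", ["A"] * 3 + ["B"] * 3)
        assert call.site_class == UNIVERSAL

    def test_one_outside_match_demotes_to_shared(self):
        # Clade A fixed aliphatic; one clade-B member also aliphatic.
        call = call_of("VILMFW", ["A"] * 3 + ["B"] * 3)
        assert call.site_class == CLADE_SHARED
        assert call.focal_clades == ("A",)

    def test_gap_inside_focal_clade_disqualifies(self):
        # Without the gap this column is specific for A (E/E/E vs mixed B).
        assert call_of("EEEGKF", ["A"] * 3 + ["B"] * 3).site_class == CLADE_SPECIFIC
        assert call_of("E-EGKF", ["A"] * 3 + ["B"] * 3).site_class == VARIABLE

    def test_uncategorized_inside_focal_clade_disqualifies(self):
        assert call_of("EXEGKF", ["A"] * 3 + ["B"] * 3).site_class == VARIABLE

    def test_universal_requires_gapfree_column(self):
        call = call_of("CCC-CC", ["A"] * 3 + ["B"] * 3)
        assert call.site_class != UNIVERSAL

    def test_min_clade_size_vacuous_singleton(self):
        # Single-member clade fixed for a unique category: vacuous at the
        # default min size of 2, honoured at min size 1.
        assert call_of("CKDWM", ["A"] + ["B"] * 2 + ["C"] * 2).site_class == VARIABLE
        call = call_of("CKDWM", ["A"] + ["B"] * 2 + ["C"] * 2, min_clade_size=1)
        assert call.site_class == CLADE_SPECIFIC and call.focal_clades == ("A",)

    def test_several_clades_can_be_specific_at_once(self):
        call = call_of("KKDDFF", ["A"] * 2 + ["B"] * 2 + ["C"] * 2)
        assert call.site_class == CLADE_SPECIFIC
        assert call.focal_clades == ("A", "B", "C")

    def test_exhaustive_two_clade_columns_match_naive_oracle(self):
        clades = ["A", "A", "B", "B"]
        for chars in itertools.product("AKD-", repeat=4):
            call = call_of(chars, clades)
            exp_class, exp_focal = naive_classify(chars, clades)
            assert (call.site_class, call.focal_clades) == (exp_class, exp_focal), chars

    def test_random_three_clade_columns_match_naive_oracle(self):
        rng = np.random.default_rng(2024)
        alphabet = list("ACDEFGHIKLMNPQRSTVWYX-")
        sizes = rng.integers(2, 6, size=(10_000, 3))
        for row_sizes in sizes:
            clades = [c for c, n in zip("ABC", row_sizes) for _ in range(n)]
            chars = rng.choice(alphabet, size=len(clades),
                               p=_spiky(rng, len(alphabet)))
            call = call_of(chars, clades)
            exp_class, exp_focal = naive_classify(chars, clades)
            assert (call.site_class, call.focal_clades) == (exp_class, exp_focal)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from("AKDC-"), min_size=4, max_size=10),
           st.randoms(use_true_random=False))
    def test_permuting_sequence_order_never_changes_the_call(self, chars, rnd):
        clades = ["A", "B"] * (len(chars) // 2) + ["A"] * (len(chars) % 2)
        base = call_of(chars, clades)
        paired = list(zip(chars, clades))
        rnd.shuffle(paired)
        shuffled = call_of([c for c, _ in paired], [cl for _, cl in paired])
        assert (base.site_class, base.focal_clades) == \
               (shuffled.site_class, shuffled.focal_clades)

    def test_adding_focal_category_residue_elsewhere_only_demotes(self):
        # Monotonicity: a focal-category residue appearing in another clade
        # can demote CLADE_SPECIFIC to CLADE_SHARED, never promote.
        chars, clades = list("KKKDD"), ["A"] * 3 + ["B"] * 2
        assert call_of(chars, clades).site_class == CLADE_SPECIFIC
        demoted = call_of(chars + ["R"], clades + ["B"])
        assert demoted.site_class == CLADE_SHARED
        assert demoted.focal_clades == ("A",)

    def test_classes_mutually_exclusive_by_construction(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            chars = rng.choice(list("AKDEC-X"), size=8)
            call = call_of(chars, ["A"] * 4 + ["B"] * 4)
            assert call.site_class in {UNIVERSAL, CLADE_SPECIFIC,
                                       CLADE_SHARED, VARIABLE}
            if call.site_class in (UNIVERSAL, VARIABLE):
                assert call.focal_clades == ()
            else:
                assert call.focal_clades and call.conserved_category is not None


def _spiky(rng, n):
    """Sparse residue distribution so fixation actually occurs in samples."""
    w = rng.dirichlet(np.full(n, 0.3))
    return w / w.sum()


class TestOrderByFrequency:
    @pytest.mark.parametrize("counts,expected", [
        ({"K": 5, "N": 2, "D": 1}, ["K", "N", "D"]),
        ({"D": 3, "E": 3}, ["D", "E"]),
        ({"V": 1}, ["V"]),
    ])
    def test_examples(self, counts, expected):
        assert order_by_frequency(Counter(counts)) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            order_by_frequency(Counter())

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from("ACDEFGHIK"), min_size=1, max_size=30))
    def test_matches_naive_sort(self, residues):
        assert order_by_frequency(Counter(residues)) == \
            naive_order_by_frequency(residues)


class TestScanAlignment:
    def test_handbuilt_alignment_classes(self, small_alignment):
        calls, table = scan_alignment(small_alignment, SCHEME)
        got = [c.site_class for c in calls]
        assert got == [UNIVERSAL, CLADE_SPECIFIC, CLADE_SHARED, VARIABLE,
                       VARIABLE, CLADE_SPECIFIC, UNIVERSAL, VARIABLE]
        assert [r.column for r in table.rows] == [2, 6]
        assert [r.clade for r in table.rows] == ["A", "A"]
        assert [r.site for r in table.rows] == [1, 2]
        assert table.rows[0].conserved_aa == "K or R"
        assert table.rows[0].other_aa == "D or E or W"
        assert table.rows[1].other_aa == "G or gap"

    def test_positions_use_focal_reference_numbering(self, small_alignment):
        calls, table = scan_alignment(small_alignment, SCHEME)
        # a1 (clade A reference) is gap-free, so positions equal columns.
        assert [r.position for r in table.rows] == [2, 6]

    def test_positions_match_coordinate_conversion(self, default_family):
        from cladesites import column_to_refpos

        aln = default_family.alignment
        _, table = scan_alignment(aln, SCHEME)
        for row in table.rows:
            ref = aln.reference_of[row.clade]
            assert row.position == column_to_refpos(aln, ref, row.column)

    def test_identical_sequences_all_universal(self):
        rows = {"a1": "MKLVE", "a2": "MKLVE", "b1": "MKLVE", "b2": "MKLVE"}
        aln = LabeledAlignment(records=tuple(rows.items()),
                               clade_of={s: s[0] for s in rows})
        calls, table = scan_alignment(aln, SCHEME)
        assert all(c.site_class == UNIVERSAL for c in calls)
        assert len(table) == 0

    def test_recovers_planted_specific_columns(self, default_family):
        calls, table = scan_alignment(default_family.alignment, SCHEME)
        planted = [(t.column, t.focal_clade) for t in default_family.truth
                   if t.site_class == CLADE_SPECIFIC]
        assert [(r.column, r.clade) for r in table.rows] == planted

    def test_specific_rows_have_zero_focal_category_outside(self, default_family):
        aln = default_family.alignment
        calls, table = scan_alignment(aln, SCHEME)
        for row in table.rows:
            col = aln.column(row.column)
            focal_chars = [ch for ch, sid in zip(col, aln.seq_ids)
                           if aln.clade_of[sid] == row.clade]
            cats = {SCHEME._lookup[ch] for ch in focal_chars}
            assert len(cats) == 1
            members = SCHEME.residues_of(next(iter(cats)))
            outside = [ch for ch, sid in zip(col, aln.seq_ids)
                       if aln.clade_of[sid] != row.clade]
            assert sum(ch in members for ch in outside) == 0

    def test_domain_assignment_flows_into_table(self):
        rows = {
            "a1": "KKDDDEEE", "a2": "KKDDDEEE",
            "b1": "KKHHHEEE", "b2": "KKHHHEEE",
        }
        aln = LabeledAlignment(records=tuple(rows.items()),
                               clade_of={s: s[0] for s in rows})
        ann = DomainAnnotation("a1", (("BAR", 1, 4),), reference_length=8)
        calls, table = scan_alignment(aln, SCHEME, annotation=ann)
        assert {r.domain for r in table.rows} == {"BAR", "C-terminal"}

    def test_site_table_tsv_roundtrip(self, tmp_path, default_family):
        _, table = scan_alignment(default_family.alignment, SCHEME)
        path = tmp_path / "sites.tsv"
        table.to_tsv(path)
        again = read_site_table(path)
        assert [(r.site, r.clade, r.position) for r in again.rows] == \
               [(r.site, r.clade, r.position) for r in table.rows]

    def test_calls_tsv_roundtrip(self, tmp_path, default_family):
        calls, _ = scan_alignment(default_family.alignment, SCHEME)
        path = tmp_path / "calls.tsv"
        write_calls_tsv(calls, path)
        again = read_calls_tsv(path)
        assert [(c.column, c.site_class, c.focal_clades) for c in again] == \
               [(c.column, c.site_class, c.focal_clades) for c in calls]


class TestSummarizeCounts:
    def test_published_site_table_counts(self):
        table = load_sh3p_sites()
        by_clade, by_domain = summarize_counts(table)
        assert by_clade == {"SH3P1": 2, "SH3P2": 4, "SH3P3": 8}
        assert sum(by_clade.values()) == 14
        assert by_domain == {"BAR": 10, "linker": 2, "SH3": 1, "C-terminal": 1}

    def test_empty_table(self):
        from cladesites import SiteTable

        by_clade, by_domain = summarize_counts(SiteTable(rows=()))
        assert by_clade == {} and by_domain == {}
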