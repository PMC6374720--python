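"""Sequence diagnostics: haplotypes, p-distances, diagnostic characters,
gap coding, translation check."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridiag import AlignedSequenceSet, TaxonPartition
from hybridiag.seqdiv import (
    code_gaps,
    collapse_haplotypes,
    find_diagnostic_characters,
    group_distance_table,
    p_distance,
    translation_check,
)


def p_distance_oracle(a: str, b: str) -> float:
    """Independent per-column loop used to cross-check p_distance."""
    compared = diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT":
            compared += 1
            diff += x != y
    return diff / compared if compared else float("nan")


class TestCollapse:
    def test_identical_sequences_share_haplotype(self):
        aln = AlignedSequenceSet(
            "COI", {"s1": "ACGT", "s2": "ACGT", "s3": "ACGA"}
        )
        hap = collapse_haplotypes(aln)
        assert hap.n_haplotypes == 2
        assert hap.membership["s1"] == hap.membership["s2"] == "H1"
        assert hap.membership["s3"] == "H2"

    def test_all_distinct(self):
        aln = AlignedSequenceSet(
            "COI", {f"s{i}": base * 4 for i, base in enumerate("ACGT")}
        )
        assert collapse_haplotypes(aln).n_haplotypes == 4

    def test_strict_keeps_ambiguity_separate_lenient_merges(self):
        aln = AlignedSequenceSet("COI", {"s1": "ACGT", "s2": "ACGN"})
        assert collapse_haplotypes(aln, "strict").n_haplotypes == 2
        assert collapse_haplotypes(aln, "lenient").n_haplotypes == 1

    def test_numbering_follows_first_occurrence(self):
        aln = AlignedSequenceSet(
            "COI", {"z": "TTTT", "a": "AAAA", "m": "TTTT"}
        )
        hap = collapse_haplotypes(aln)
        assert hap.haplotypes[0] == ("H1", "TTTT")
        assert hap.multiplicity() == {"H1": 2, "H2": 1}


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("AAAA", "AAAA", 0.0),
            ("AAAA", "AAAT", 0.25),
            ("AA-A", "AATT", 1 / 3),  # pairwise deletion drops the gap column
            ("ANAA", "AAAA", 0.0),    # ambiguity column excluded
        ],
    )
    def test_worked_examples(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_unequal_length_errors(self):
        with pytest.raises(ValueError, match="unequal length"):
            p_distance("AAA", "AAAA")

    def test_no_comparable_columns_is_nan(self):
        assert math.isnan(p_distance("--NN", "AAAA"))

    def test_matches_oracle_on_random_pairs(self):
        rng = random.Random(2024)
        alphabet = "ACGT" + "N-RY"
        for _ in range(1000):
            n = rng.randint(1, 40)
            a = "".join(rng.choice(alphabet) for _ in range(n))
            b = "".join(rng.choice(alphabet) for _ in range(n))
            got, want = p_distance(a, b), p_distance_oracle(a, b)
            assert (math.isnan(got) and math.isnan(want)) or got == want

    @given(
        st.integers(1, 30).flatmap(
            lambda n: st.tuples(
                st.text("ACGTN-", min_size=n, max_size=n),
                st.text("ACGTN-", min_size=n, max_size=n),
            )
        )
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_symmetric_and_bounded(self, pair):
        a, b = pair
        d = p_distance(a, b)
        d_rev = p_distance(b, a)
        assert (math.isnan(d) and math.isnan(d_rev)) or d == d_rev
        if not math.isnan(d):
            assert 0.0 <= d <= 1.0
        if a == b and not math.isnan(d):
            assert d == 0.0


class TestGroupDistances:
    def test_identical_sequences_give_zero_or_na(self):
        aln = AlignedSequenceSet(
            "COI", {"a1": "ACGT", "a2": "ACGT", "b1": "ACGT"}
        )
        part = TaxonPartition({"a1": "A", "a2": "A", "b1": "B"})
        table = group_distance_table(collapse_haplotypes(aln), part)
        assert math.isnan(table.within["A"])  # single haplotype
        assert table.between.at["A", "B"] == 0.0

    def test_two_singleton_groups(self):
        aln = AlignedSequenceSet("COI", {"a": "A" * 10, "b": "A" * 9 + "T"})
        part = TaxonPartition({"a": "A", "b": "B"})
        table = group_distance_table(collapse_haplotypes(aln), part)
        assert table.between.at["A", "B"] == pytest.approx(10.0)
        frame = table.to_frame(na_as_zero=True)
        assert frame.at["B", "A"] == "10.00"
        assert frame.at["A", "A"] == "0.00"

    def test_within_group_mean_over_unique_haplotypes(self):
        # 3 specimens but only 2 haplotypes: the duplicate must not
        # down-weight the within-group mean
        aln = AlignedSequenceSet(
            "COI", {"a1": "AAAA", "a2": "AAAA", "a3": "AAAT"}
        )
        part = TaxonPartition({s: "A" for s in ("a1", "a2", "a3")})
        table = group_distance_table(collapse_haplotypes(aln), part)
        assert table.within["A"] == pytest.approx(25.0)

    def test_shared_haplotype_pulls_between_distance_down(self):
        aln = AlignedSequenceSet(
            "COI",
            {"a1": "AAAA", "a2": "AAAT", "b1": "AAAA", "b2": "AATT"},
        )
        part = TaxonPartition(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        table = group_distance_table(collapse_haplotypes(aln), part)
        # hap sets: A={AAAA, AAAT}, B={AAAA, AATT}; cross pairs:
        # 0, .5, .25, .25 -> mean .25 = 25%
        assert table.between.at["A", "B"] == pytest.approx(25.0)

    def test_empty_group_errors(self):
        aln = AlignedSequenceSet("COI", {"a": "ACGT"})
        part = TaxonPartition({"a": "A"})
        with pytest.raises(ValueError, match="no haplotypes"):
            group_distance_table(collapse_haplotypes(aln), part, ["A", "B"])


class TestDiagnosticCharacters:
    def _make(self, seqs, taxa):
        aln = AlignedSequenceSet("cytb", seqs)
        return aln, TaxonPartition(taxa)

    def test_fixed_difference_found_with_1_based_position(self):
        aln, part = self._make(
            {"f1": "AAAAAAC", "f2": "AAAAAAC", "o1": "AAAAAAA", "o2": "AAAAAAT"},
            {"f1": "F", "f2": "F", "o1": "O", "o2": "O"},
        )
        chars = find_diagnostic_characters(aln, part, "F")
        assert [(c.position, c.state) for c in chars] == [(7, "C")]

    def test_shared_haplotype_defeats_diagnosis(self):
        aln, part = self._make(
            {"f1": "AAAC", "o1": "AAAC"}, {"f1": "F", "o1": "O"}
        )
        assert find_diagnostic_characters(aln, part, "F") == []

    def test_nonfocal_ambiguity_blocks_candidate(self):
        # Y expands to C/T, so C cannot be diagnostic for the focal group
        aln, part = self._make(
            {"f1": "AAAC", "o1": "AAAY"}, {"f1": "F", "o1": "O"}
        )
        assert find_diagnostic_characters(aln, part, "F") == []

    def test_strict_skips_ambiguous_focal_lenient_resolves(self):
        aln, part = self._make(
            {"f1": "AAAC", "f2": "AAAM", "o1": "AAAG"},
            {"f1": "F", "f2": "F", "o1": "O"},
        )
        assert find_diagnostic_characters(aln, part, "F", "strict") == []
        lenient = find_diagnostic_characters(aln, part, "F", "lenient")
        assert [(c.position, c.state) for c in lenient] == [(4, "C")]

    def test_found_characters_are_self_verifying(self):
        rng = random.Random(7)
        seqs = {
            f"s{i}": "".join(rng.choice("ACGT") for _ in range(30))
            for i in range(12)
        }
        taxa = {s: ("F" if i < 5 else "O") for i, s in enumerate(seqs)}
        aln, part = self._make(seqs, taxa)
        for c in find_diagnostic_characters(aln, part, "F"):
            col = c.position - 1
            focal = {seqs[s][col] for s in seqs if taxa[s] == "F"}
            other = {seqs[s][col] for s in seqs if taxa[s] == "O"}
            assert focal == {c.state}
            assert c.state not in other

    def test_empty_focal_group_errors(self):
        aln, part = self._make({"a": "ACGT"}, {"a": "O"})
        with pytest.raises(ValueError, match="no specimens"):
            find_diagnostic_characters(aln, part, "F")


class TestGapCoding:
    def test_single_shared_gap(self):
        aln = AlignedSequenceSet(
            "ITS1", {"s1": "A--A", "s2": "A--A", "s3": "AAAA"}
        )
        block = code_gaps(aln)
        assert len(block.characters) == 1
        c = block.characters[0]
        assert (c.start, c.end) == (2, 3)
        assert [c.score(s) for s in ("s1", "s2", "s3")] == ["1", "1", "0"]

    def test_nested_gap_scored_inapplicable(self):
        aln = AlignedSequenceSet("ITS1", {"s1": "A---A", "s2": "A--CA"})
        block = code_gaps(aln)
        extents = [(c.start, c.end) for c in block.characters]
        assert extents == [(2, 3), (2, 4)]
        short, long = block.characters
        assert short.score("s1") == "-"   # strictly contained in s1's gap
        assert short.score("s2") == "1"
        assert long.score("s1") == "1"
        assert long.score("s2") == "0"

    def test_no_gaps_no_characters(self):
        aln = AlignedSequenceSet("ITS1", {"s1": "ACGT", "s2": "ACGA"})
        assert code_gaps(aln).characters == []

    def test_invariant_to_sequence_order(self):
        seqs = {"s1": "A---A", "s2": "A--CA", "s3": "AAAAA", "s4": "-AAAA"}
        fwd = code_gaps(AlignedSequenceSet("ITS1", seqs))
        rev = code_gaps(
            AlignedSequenceSet("ITS1", dict(reversed(list(seqs.items()))))
        )
        for a, b in zip(fwd.characters, rev.characters):
            assert (a.start, a.end) == (b.start, b.end)
            assert dict(a.states) == dict(b.states)


class TestTranslation:
    def test_clean_sequence_passes(self):
        aln = AlignedSequenceSet("COI", {"s": "ATGAAA"})
        (report,) = translation_check(aln, frame=1)
        assert report.ok

    def test_internal_stop_flagged(self):
        aln = AlignedSequenceSet("COI", {"s": "ATGTAAAAA"})
        (report,) = translation_check(aln, frame=1)
        assert report.internal_stops == (2,)

    def test_ambiguous_amino_acid_flagged(self):
        aln = AlignedSequenceSet("COI", {"s": "ATGNNN"})
        (report,) = translation_check(aln, frame=1)
        assert report.ambiguous_residues == (2,)
        assert not report.ok

    def test_invertebrate_mito_code_is_default(self):
        # AGA codes for serine (not a stop) in the invertebrate mito code
        aln = AlignedSequenceSet("COI", {"s": "ATGAGAAAA"})
        (report,) = translation_check(aln, frame=1)
        assert report.ok

    def test_bad_frame_errors(self):
        aln = AlignedSequenceSet("COI", {"s": "ATGAAA"})
        with pytest.raises(ValueError, match="frame"):
            translation_check(aln, frame=4)
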