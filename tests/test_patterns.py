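"""Polarization, parsimony classification and tabulation."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import numpy as np

from codouble import reference
from codouble.alignment import ROLES
from codouble.patterns import (
    AMONG_PATTERNS,
    CLASSIFICATION,
    TABLE_PATTERNS,
    WITHIN_PATTERNS,
    BinarySitePattern,
    PatternCounts,
    SiteRejection,
    classify_pattern,
    count_patterns_from_states,
    pattern_int,
    pattern_string,
    polarize,
    tabulate,
)

from conftest import column_from_bits, make_alignment, uniform_column
from oracles import exhaustive_min_substitutions

#: The published classification of all 18 double patterns.
EXPECTED_DOUBLES = {
    "000011": ("within_double", {"mx", "my"}),
    "001100": ("within_double", {"hx", "hy"}),
    "110000": ("within_double", {"bsx", "bsy"}),
    "001111": ("within_double", {"bsx", "bsy"}),
    "110011": ("within_double", {"hx", "hy"}),
    "111100": ("within_double", {"mx", "my"}),
    "100100": ("among_double", {"bsx", "hy"}),
    "011000": ("among_double", {"bsy", "hx"}),
    "010010": ("among_double", {"bsy", "mx"}),
    "100001": ("among_double", {"bsx", "my"}),
    "001001": ("among_double", {"hx", "my"}),
    "000110": ("among_double", {"hy", "mx"}),
    "111001": ("among_double", {"hy", "mx"}),
    "110110": ("among_double", {"hx", "my"}),
    "101101": ("among_double", {"bsy", "mx"}),
    "011110": ("among_double", {"bsx", "my"}),
    "100111": ("among_double", {"bsy", "hx"}),
    "011011": ("among_double", {"bsx", "hy"}),
}


class TestPolarize:
    def test_outgroup_maps_to_zero(self):
        pat = polarize_col("010101", variant0="A", variant1="G")
        assert pat.bits == (0, 1, 0, 1, 0, 1)
        assert (pat.variant0, pat.variant1) == ("A", "G")

    def test_orientation_follows_outgroup(self):
        # same column but outgroup carries the other variant
        col = column_from_bits("010101", "A", "G")
        col["out"] = "G"
        pat = polarize(make_alignment([col]).column(0))
        assert pat.bits == (1, 0, 1, 0, 1, 0)
        assert pat.variant0 == "G"

    def test_monomorphic_and_multiallelic_rejected(self):
        mono = polarize(make_alignment([uniform_column("A")]).column(0))
        assert isinstance(mono, SiteRejection) and mono.reason == "monomorphic"
        col = column_from_bits("010101", "A", "G")
        col["mx"] = "T"
        tri = polarize(make_alignment([col]).column(0))
        assert isinstance(tri, SiteRejection) and tri.reason == "multiallelic"

    def test_gap_in_column_is_an_error(self):
        col = {**uniform_column("A"), "hx": "-"}
        aln = make_alignment([col])
        with pytest.raises(ValueError, match="gap-free"):
            polarize(aln.column(0))


def polarize_col(bits, variant0="A", variant1="G"):
    aln = make_alignment([column_from_bits(bits, variant0, variant1)])
    return polarize(aln.column(0))


class TestClassifyPattern:
    @pytest.mark.parametrize("bits,expected", sorted(EXPECTED_DOUBLES.items()))
    def test_published_double_patterns(self, bits, expected):
        cls = classify_pattern(bits)
        assert (cls.category, set(cls.branches)) == expected
        assert cls.min_substitutions == 2

    def test_no_other_pattern_is_a_double(self):
        doubles = {
            pattern_string(v)
            for v, c in CLASSIFICATION.items()
            if c.category in ("within_double", "among_double")
        }
        assert doubles == set(TABLE_PATTERNS)

    def test_stem_singles_and_extremes(self):
        assert classify_pattern("101010").category == "single"
        assert classify_pattern("101010").branches == frozenset({"xstem"})
        assert classify_pattern("010101").branches == frozenset({"ystem"})
        assert classify_pattern("000000").category == "monomorphic"
        assert classify_pattern("111111").category == "root_single"

    def test_bsx_lumping_not_extended_to_mismatched_stem_pairs(self):
        # bovine-X with stem-Y (and the reverse) are genuine doubles but
        # fall outside the published 18-pattern scheme
        assert classify_pattern("100101").category == "complex"
        assert classify_pattern("011010").category == "complex"

    def test_minimal_substitutions_match_exhaustive_search(self):
        oracle = exhaustive_min_substitutions()
        for v, cls in CLASSIFICATION.items():
            bits = tuple(int(c) for c in pattern_string(v))
            if cls.category == "root_single":
                # charged as the one outgroup-branch substitution
                assert cls.min_substitutions == 1
                assert oracle[bits] == 0
            else:
                assert cls.min_substitutions == oracle[bits], bits

    def test_complement_equivalence(self):
        """A pattern and its complement carry the same test-relevant class."""
        for v, cls in CLASSIFICATION.items():
            comp = CLASSIFICATION[v ^ 0b111111]
            if cls.category in ("within_double", "among_double", "complex"):
                assert comp.category == cls.category
                assert comp.branches == cls.branches
            elif cls.category == "monomorphic":
                assert comp.category == "root_single"
            elif cls.category == "root_single":
                assert comp.category == "monomorphic"
            else:  # singles: xstem pairs with ystem, others with themselves
                assert comp.category == "single"
                mirror = {"xstem": "ystem", "ystem": "xstem"}
                (b,) = cls.branches
                assert comp.branches in (
                    frozenset({b}),
                    frozenset({mirror.get(b, b)}),
                )

    def test_accounting_identity(self):
        """Within rows hold each class twice, among rows four times."""
        tokens_within: dict[str, int] = {}
        tokens_among: dict[str, int] = {}
        for p in WITHIN_PATTERNS:
            for b in CLASSIFICATION[pattern_int(p)].branches:
                tokens_within[b] = tokens_within.get(b, 0) + 1
        for p in AMONG_PATTERNS:
            for b in CLASSIFICATION[pattern_int(p)].branches:
                tokens_among[b] = tokens_among.get(b, 0) + 1
        classes = {"bsx", "bsy", "hx", "hy", "mx", "my"}
        assert tokens_within == {c: 2 for c in classes}
        assert tokens_among == {c: 4 for c in classes}

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern("01010")
        with pytest.raises(ValueError):
            classify_pattern((0, 1, 0, 1, 0, 2))


class TestTabulate:
    @pytest.mark.parametrize(
        "gene,expected_within,expected_among",
        [("DDX3", 30, 35), ("RBM", 35, 28), ("UTX", 33, 42)],
    )
    def test_published_pattern_tables_reproduce_totals(
        self, gene, expected_within, expected_among
    ):
        pc = PatternCounts.from_pattern_table(gene, reference.PATTERN_COUNTS[gene])
        assert (pc.within_total, pc.among_total) == (expected_within, expected_among)

    def test_usp9_per_pattern_column_sums_internally(self):
        # the published USP9 per-pattern counts sum to 96/130 (see the
        # reference module's note on the 130-vs-113 inconsistency)
        pc = PatternCounts.from_pattern_table("USP9", reference.PATTERN_COUNTS["USP9"])
        assert (pc.within_total, pc.among_total) == (96, 130)

    def test_empty_input_all_zero(self):
        pc = tabulate([], gene_name="empty")
        assert pc.within_total == 0 and pc.among_total == 0 and pc.other == 0

    def test_counts_orientation_kept_and_pooled(self):
        pats = [
            make_pattern("000011", 0),
            make_pattern("111100", 1),
            make_pattern("000011", 2),
        ]
        pc = tabulate(pats)
        assert pc.per_pattern["000011"] == 2
        assert pc.per_pattern["111100"] == 1
        assert pc.pooled[frozenset({"000011", "111100"})] == 3

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_totals_permutation_invariant(self, rnd):
        pats = [make_pattern(p, i) for i, p in enumerate(TABLE_PATTERNS * 2)]
        shuffled = pats[:]
        rnd.shuffle(shuffled)
        a, b = tabulate(pats), tabulate(shuffled)
        assert (a.within_total, a.among_total, a.per_pattern) == (
            b.within_total,
            b.among_total,
            b.per_pattern,
        )

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_vectorized_tabulation_matches_column_path(self, seed):
        rng = np.random.default_rng(seed)
        states = rng.integers(0, 4, size=(7, 300)).astype(np.int8)
        fast = count_patterns_from_states(states)
        nucs = "ACGT"
        cols = [
            {r: nucs[states[i, j]] for i, r in enumerate(ROLES)} for j in range(300)
        ]
        aln = make_alignment(cols)
        pats = [
            p
            for p in (polarize(aln.column(j)) for j in range(300))
            if isinstance(p, BinarySitePattern)
        ]
        slow = tabulate(pats, n_gapless_sites=300)
        assert fast.per_pattern == slow.per_pattern
        assert fast.singles == slow.singles
        assert fast.other == slow.other


def make_pattern(bits: str, site_index: int) -> BinarySitePattern:
    return BinarySitePattern(
        bits=tuple(int(c) for c in bits), site_index=site_index, variant0="A", variant1="G"
    )
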