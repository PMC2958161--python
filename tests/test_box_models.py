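import numpy as np
import pytest
from hypothesis import given, strategies as st

from sopescan.box_models import (
    BoxDefinition,
    default_box_set,
    expected_hit_density,
    iupac_match,
    pattern_match_probability,
    palindromic_match_probability,
    reverse_complement,
    scan_at_rich,
    scan_boxes,
    scan_iupac_boxes,
)
from .helpers import oracle_scan_all

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


class TestIupacMatch:
    @pytest.mark.parametrize(
        "pattern,window,expected",
        [
            ("CANNTG", "CAGCTG", True),
            ("CANNTG", "CAGCTA", False),
            ("NNNNNN", "ACGTAC", True),
            ("CACNAG", "CACCAG", True),
            ("GGGWWWNCC", "GGGATTGCC", True),
            ("GGGWWWNCC", "GGGCTTGCC", False),
        ],
    )
    def test_subset_rule(self, pattern, window, expected):
        assert iupac_match(pattern, window) is expected

    def test_n_in_window_matches_only_n_in_pattern_by_default(self):
        assert not iupac_match("CANNTG", "CANNTG"[:4] + "NG")  # N under T fails
        assert iupac_match("CANNTG", "CANNTG")  # N under N passes
        # wildcard policy relaxes sequence ambiguity to intersection
        assert iupac_match("CANNTG", "CANNNG", n_policy="wildcard")

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="length"):
            iupac_match("CANNTG", "CAG")


class TestScanIupac:
    def test_empty_sequence(self, default_defs):
        iupac = [d for d in default_defs if d.kind == "iupac_pattern"]
        assert scan_iupac_boxes("", iupac) == []

    def test_single_palindromic_e_box_deduplicated(self, default_defs):
        e = [d for d in default_defs if d.name == "E"]
        hits = scan_iupac_boxes("TTCAGCTGTT", e)
        assert len(hits) == 1
        h = hits[0]
        assert (h.region.start, h.region.end, h.strand) == (2, 8, "+")
        assert h.matched_text == "CAGCTG"

    def test_minus_strand_hit_in_forward_coordinates(self, default_defs):
        n = [d for d in default_defs if d.name == "N"]
        hits = scan_iupac_boxes("CTGGTG", n)
        assert len(hits) == 1
        h = hits[0]
        assert (h.region.start, h.region.end, h.strand) == (0, 6, "-")
        assert h.matched_text == "CTGGTG"  # forward-strand slice

    def test_non_palindromic_double_match_gives_two_hits(self):
        # CAACTG matches CANNTG forward; its revcomp CAGTTG also matches
        d = BoxDefinition(name="E", kind="iupac_pattern", pattern="CANNTG")
        hits = scan_iupac_boxes("CAACTG", [d])
        assert [(h.strand) for h in hits] == ["+", "-"]

    @given(dna, st.integers(0, 3))
    def test_equals_regex_oracle(self, seq, which):
        defs = [d for d in default_box_set() if d.kind == "iupac_pattern"]
        if which < len(defs):
            defs = [defs[which]]
        hits = scan_iupac_boxes(seq, defs)
        got = [
            (h.box_name, h.region.start, h.region.end, h.strand) for h in hits
        ]
        assert got == oracle_scan_all(seq, defs)

    @given(dna)
    def test_reverse_complement_mirrors_hit_set(self, seq):
        defs = [d for d in default_box_set() if d.kind == "iupac_pattern"]
        fwd = scan_iupac_boxes(seq, defs)
        rev = scan_iupac_boxes(reverse_complement(seq), defs)
        L = len(seq)
        mirrored = sorted(
            (h.box_name, L - h.region.end, L - h.region.start) for h in rev
        )
        assert mirrored == sorted(
            (h.box_name, h.region.start, h.region.end) for h in fwd
        )

    @given(dna)
    def test_hits_in_bounds_and_duplicate_free(self, seq):
        hits = scan_boxes(seq, default_box_set())
        keys = [(h.box_name, h.region.start, h.region.end, h.strand) for h in hits]
        assert len(keys) == len(set(keys))
        for h in hits:
            assert 0 <= h.region.start <= h.region.end <= len(seq)
            assert h.matched_text == seq[h.region.start : h.region.end]


class TestScanAtRich:
    beta = BoxDefinition(
        name="beta", kind="at_rich_window", width=8, min_at_fraction=0.85
    )

    def test_pure_at_window(self):
        hits = scan_at_rich("ATATATAT", self.beta)
        assert [(h.region.start, h.region.end) for h in hits] == [(0, 8)]

    def test_pure_gc_no_hits(self):
        assert scan_at_rich("GCGCGCGC", self.beta) == []

    def test_two_islands_merge_and_trim(self):
        hits = scan_at_rich("ATATATATGGGGATATATAT", self.beta)
        assert [(h.region.start, h.region.end) for h in hits] == [(0, 8), (12, 20)]

    def test_width_exceeding_sequence_is_empty_not_error(self):
        assert scan_at_rich("ATAT", self.beta) == []

    def test_adjacent_windows_merge_to_maximal_region(self):
        hits = scan_at_rich("A" * 20, self.beta)
        assert [(h.region.start, h.region.end) for h in hits] == [(0, 20)]


class TestDefaultBoxSet:
    def test_names_are_the_four_classes(self, default_defs):
        assert {d.name for d in default_defs} == {"E", "alpha", "beta", "N"}

    def test_e_box_matched_by_the_published_logo(self, default_defs):
        e = next(d for d in default_defs if d.name == "E")
        assert iupac_match(e.pattern, "CAGCTG")

    def test_definitions_pass_their_invariants(self, default_defs):
        # constructing them already validated; spot-check fields
        beta = next(d for d in default_defs if d.name == "beta")
        assert beta.width >= 4 and 0 < beta.min_at_fraction <= 1
        for d in default_defs:
            if d.kind == "iupac_pattern":
                assert d.both_strands


class TestAnalyticDensity:
    def test_e_box_per_strand_probability(self):
        assert pattern_match_probability("CANNTG") == pytest.approx(1 / 256)

    def test_palindromic_probability_of_e_box(self):
        # CAxx'TG with x free: 4 windows of 4096
        assert palindromic_match_probability("CANNTG") == pytest.approx(4 / 4096)

    def test_monte_carlo_hit_density_matches_analytic(self):
        rng = np.random.default_rng(11)
        defs = [d for d in default_box_set() if d.kind == "iupac_pattern"]
        n, L = 400, 500
        counts = {d.name: 0 for d in defs}
        for _ in range(n):
            seq = "".join("ACGT"[i] for i in rng.integers(4, size=L))
            for d in defs:
                counts[d.name] += sum(
                    1 for h in scan_iupac_boxes(seq, [d])
                )
        for d in defs:
            windows = n * (L - len(d.pattern) + 1)
            p = expected_hit_density(d)
            expect = windows * p
            sd = (windows * p * (1 - p)) ** 0.5
            assert abs(counts[d.name] - expect) < 4 * sd, d.name
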