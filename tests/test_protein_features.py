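import numpy as np
import pytest
from hypothesis import given, strategies as st

from sopescan.protein_features import (
    ASH_CTERM_REFERENCE,
    AaClassConfig,
    classify_protein,
    cterm_identity,
    find_ase_motif,
    integrate_gene_call,
    measure_protein,
)

REF = ASH_CTERM_REFERENCE
AA = "ACDEFGHIKLMNPQRSTVWY"


class TestCtermIdentity:
    def test_perfect_self_match(self):
        m = cterm_identity("G" * 40 + REF)
        assert m.identity == 1.0 and m.n_identical == 16
        assert m.display_percent == 100

    def test_three_terminal_mismatches(self):
        m = cterm_identity("G" * 40 + "PDDEELLDYISWWAAA")
        assert m.n_identical == 13
        assert m.identity == pytest.approx(13 / 16)

    def test_short_protein_is_absent(self):
        assert cterm_identity("PDDEELLDYI") is None

    def test_display_percent_truncates(self):
        # 10/16 = 62.5% prints as 62
        mutated = "AAAAAA" + REF[6:]
        m = cterm_identity("G" * 40 + mutated)
        assert m.n_identical == 10 and m.display_percent == 62

    def test_tie_broken_toward_c_terminus(self):
        # two windows with zero matches: the last one is reported
        m = cterm_identity("G" * 60)
        assert m.window.end == 60

    def test_invariant_to_residues_outside_search_tail(self):
        a = cterm_identity("W" * 100 + REF, search_tail=40)
        b = cterm_identity("M" * 100 + REF, search_tail=40)
        assert (a.identity, a.window.end) == (b.identity, b.window.end)

    def test_symmetry_of_the_16mer_comparison(self):
        other = "PDDEELLDYISWWAAA"
        a = cterm_identity(other, reference=REF, search_tail=16)
        b = cterm_identity(REF, reference=other, search_tail=16)
        assert a.n_identical == b.n_identical

    def test_identity_one_iff_identical(self):
        for window in ("PDDEELLDYISWWQQQ", "PDDEELLDYISWWQQA"):
            m = cterm_identity(window, reference=REF, search_tail=16)
            assert (m.identity == 1.0) == (window == REF)


class TestAseMotif:
    def test_constructed_instance_found(self):
        assert find_ase_motif("AAVKSEIAA") == [2]

    def test_lysine_is_mandatory(self):
        assert find_ase_motif("AAVRSEIAA") == []

    def test_empty_text(self):
        assert find_ase_motif("") == []

    def test_glutamate_position_is_mandatory(self):
        assert find_ase_motif("AAVKSDIAA") == []

    def test_monte_carlo_rate_matches_class_sizes(self):
        classes = AaClassConfig()
        p = (
            (len(classes.hydrophobic) / 20)
            * (1 / 20)
            * (len(classes.polar) / 20)
            * (1 / 20)
            * (len(classes.hydrophobic) / 20)
        )
        rng = np.random.default_rng(5)
        n, L = 300, 400
        hits = 0
        for _ in range(n):
            seq = "".join(AA[i] for i in rng.integers(20, size=L))
            hits += len(find_ase_motif(seq))
        windows = n * (L - 4)
        expect = windows * p
        sd = (windows * p * (1 - p)) ** 0.5
        assert abs(hits - expect) < 4 * sd


class TestClassify:
    @pytest.mark.parametrize(
        "identity,motif,expected",
        [
            (1.0, False, "ASH"),
            (0.375, True, "ase"),  # motif dominates a weak C-terminal domain
            (0.3125, False, "indeterminate"),  # CsASH2-like: ~30%, no motif
            (0.5, False, "ASH"),  # boundary: 50% identity counts as ASH
            (None, True, "ase"),
        ],
    )
    def test_rule(self, identity, motif, expected):
        cterm = None
        if identity is not None:
            cterm = cterm_identity(
                _protein_with_identity(identity), search_tail=16
            )
            assert cterm.identity == pytest.approx(identity)
        assert classify_protein(cterm, [1] if motif else [], 0.5) == expected

    def test_monotone_in_motif_and_threshold(self):
        cterm = cterm_identity(REF, search_tail=16)
        # adding a motif hit never moves the label away from ase
        assert classify_protein(cterm, [0], 0.5) == "ase"
        # raising the threshold can only demote ASH toward indeterminate
        for t in (0.2, 0.5, 0.9, 1.01):
            label = classify_protein(
                cterm_identity(_protein_with_identity(0.5), search_tail=16), [], t
            )
            assert label in ("ASH", "indeterminate")
            if t > 0.5:
                assert label == "indeterminate"


def _protein_with_identity(identity):
    k = round(identity * 16)
    return REF[:k] + "G" * (16 - k)


class TestIntegrateGeneCall:
    def _ev(self, label):
        return measure_protein(
            {
                "ASH": "G" * 30 + REF,
                "ase": "AVKSEI" + "G" * 30 + REF,
                "indeterminate": "G" * 46,
            }[label]
        )

    def _sope(self):
        from sopescan.seq_io import Region
        from sopescan.box_models import BoxHit
        from sopescan.sope_caller import SopeCall

        h = BoxHit("E", Region(0, 6), "+", "CAGCTG")
        return SopeCall(Region(0, 6), (h,), {"E": 1}, 1, 6)

    @pytest.mark.parametrize(
        "protein_label,with_sope,expected",
        [
            ("ASH", True, "ancestral_ASH_ase_like"),
            ("indeterminate", True, "ase_like"),
            ("ase", True, "ase_like"),
            ("ASH", False, "proneural_ASH"),
            ("ase", False, "ase_like"),
            ("indeterminate", False, "indeterminate"),
        ],
    )
    def test_truth_table(self, protein_label, with_sope, expected):
        ev = self._ev(protein_label)
        assert ev.label == protein_label
        gc = integrate_gene_call(ev, self._sope() if with_sope else None)
        assert gc.gene_label == expected
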