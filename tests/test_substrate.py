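"""Recognition windows, core rules, scanning and the mismatch-trap construct."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import bridgekit as bk
from bridgekit.substrate import (
    DoubleTrapError,
    ScanWarning,
    SubstrateError,
    Verdict,
)

# independent reverse-complement oracle for the tests
_RC = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_RC)[::-1]


dna14 = st.text(alphabet="ACGT", min_size=14, max_size=14)


class TestMakeWindow:
    @given(top=dna14)
    def test_default_bottom_is_reverse_complement(self, top):
        w = bk.make_window(top)
        assert w.bottom == rc(top)
        assert w.mismatches == frozenset()

    def test_planted_bottom_violation_maps_to_top_position(self):
        top = "ACGTACGCTGACTA"
        bottom = list(rc(top))
        # corrupt starred position 9*: across from top position 15 - 9 = 6
        bottom[8] = "A" if bottom[8] != "A" else "C"
        w = bk.DnaWindow(top=top, bottom="".join(bottom))
        assert w.mismatches == frozenset({6})

    @pytest.mark.parametrize("bad", ["ACGTACGCTGACT", "ACGTACGCTGACTAA", ""])
    def test_wrong_length_rejected(self, bad):
        with pytest.raises(ValueError):
            bk.make_window(bad)

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError):
            bk.make_window("ACGTACGNTGACTA")


class TestCoreRules:
    @pytest.mark.parametrize(
        "core, verdict",
        [
            ("CT", Verdict.PASS),
            ("GT", Verdict.PASS_WITH_WARNING),
            ("AT", Verdict.PASS_WITH_WARNING),
            ("TT", Verdict.PASS_WITH_WARNING),
            ("CA", Verdict.FAIL),
            ("CC", Verdict.FAIL),
        ],
    )
    def test_verdicts(self, core, verdict):
        w = bk.make_window("ACGTACG" + core + "GACTA")
        report = bk.validate_core(w)
        assert report.verdict is verdict
        assert report.position8_class == core[0]
        assert report.position9_ok == (core[1] == "T")

    def test_report_is_role_independent(self):
        top = "ACGTACGGTGACTA"
        assert bk.validate_core(bk.make_window(top, role="target")) == bk.validate_core(
            bk.make_window(top, role="donor")
        )


def scan_oracle(seq: str, circular: bool):
    """Brute-force enumeration of all offsets x strands with T at position 9."""
    hits = set()
    for strand, s in (("+", seq), ("-", rc(seq))):
        n = len(s)
        starts = range(1, n + 1) if circular else range(1, n - 12)
        for start in starts:
            top = "".join(s[(start - 1 + k) % n] for k in range(14))
            if top[8] == "T":
                hits.add((start, strand, top[7:9]))
    return hits


class TestScanCores:
    def test_single_forward_ct_hit(self):
        mol = bk.SubstrateMolecule("AAAAAAACTAAAAA", "linear", 1)
        hits = bk.scan_cores(mol)
        forward_ct = [h for h in hits if h.strand == "+" and h.core == "CT"]
        assert len(forward_ct) == 1
        assert forward_ct[0].window_start == 1

    def test_no_t_on_either_strand_means_no_hits(self):
        # G/C-only sequence: position 9 is unsatisfiable on both strands
        mol = bk.SubstrateMolecule("GCGCGCGCGCGCGCGC", "linear", 1)
        assert bk.scan_cores(mol) == []

    def test_circular_hit_wrapping_the_origin(self):
        # window start 7 places core positions 8-9 at sequence coordinates
        # 14 and 1 of the circular 14-mer (wraparound)
        seq = "TAAAAAAAAAAAAC"
        mol = bk.SubstrateMolecule(seq, "circular", 1)
        hits = [h for h in bk.scan_cores(mol) if h.strand == "+" and h.core == "CT"]
        assert [h.window_start for h in hits] == [7]

    def test_short_linear_sequence_warns_and_returns_empty(self):
        mol = bk.SubstrateMolecule("ACGTACGTAACC", "linear")
        with pytest.warns(ScanWarning):
            assert bk.scan_cores(mol) == []

    def test_ranking_ct_before_gt_before_at(self):
        seq = "AAAAAAAATAAAAAAACTAAAAAAGTAAAAA"
        hits = bk.scan_cores(bk.SubstrateMolecule(seq, "linear", 1))
        ranks = [h.report.rank for h in hits]
        assert ranks == sorted(ranks)

    @given(seq=st.text(alphabet="ACGT", min_size=14, max_size=120),
           circular=st.booleans())
    def test_agrees_with_brute_force_enumeration(self, seq, circular):
        mol = bk.SubstrateMolecule(seq, "circular" if circular else "linear", 1)
        got = {(h.window_start, h.strand, h.core) for h in bk.scan_cores(mol)}
        assert got == scan_oracle(seq, circular)


class TestTrapMismatches:
    def test_worked_example_complements_positions_2_to_7(self):
        w = bk.make_window("ACGTACGCTGACTA")
        trapped = bk.trap_mismatches(w)
        assert trapped.top == "AGCATGCCTGACTA"
        assert trapped.bottom == w.bottom
        assert trapped.mismatches == frozenset({2, 3, 4, 5, 6, 7})

    def test_restoring_from_bottom_strand_round_trips(self):
        w = bk.make_window("ACGTACGCTGACTA")
        trapped = bk.trap_mismatches(w)
        top = list(trapped.top)
        for i in range(2, 8):
            # complement of the bottom base across from top position i
            top[i - 1] = rc(trapped.bottom)[i - 1]
        restored = bk.DnaWindow(top="".join(top), bottom=trapped.bottom)
        assert restored.mismatches == frozenset()
        assert restored.top == w.top

    def test_double_trapping_is_refused(self):
        trapped = bk.trap_mismatches(bk.make_window("ACGTACGCTGACTA"))
        with pytest.raises(DoubleTrapError):
            bk.trap_mismatches(trapped)

    @given(top=dna14)
    def test_changes_exactly_six_positions_never_the_core(self, top):
        w = bk.make_window(top)
        trapped = bk.trap_mismatches(w)
        changed = {i + 1 for i in range(14) if trapped.top[i] != w.top[i]}
        assert changed == {2, 3, 4, 5, 6, 7}
        assert trapped.top[7:9] == w.top[7:9]


class TestSubstrateMolecule:
    def test_window_extraction_matches_make_window(self):
        mol = bk.SubstrateMolecule("GGGG" + "ACGTACGCTGACTA" + "TTTT", "linear", 5, "target")
        w = mol.window()
        assert w.top == "ACGTACGCTGACTA"
        assert w.bottom == rc("ACGTACGCTGACTA")

    def test_window_must_fit_linear_sequence(self):
        with pytest.raises(SubstrateError):
            bk.SubstrateMolecule("ACGTACGCTGACTAGG", "linear", 5)

    def test_circular_window_wraps(self):
        seq = "CTGACTAGGGACGTACG"  # window starts at 12 and wraps
        mol = bk.SubstrateMolecule(seq, "circular", 12)
        assert mol.window().top == seq[11:] + seq[:8]
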