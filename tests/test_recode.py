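"""Recoding, identity-run detection, homology breaking, termini."""

import pytest
from hypothesis import given, settings, strategies as st

from codoncompress.codon_model import STANDARD_CODE, UsageTable
from codoncompress.genome_io import CDSRecord
from codoncompress.fixtures import make_toy_plastome
from codoncompress.recode import (
    RecodingError,
    break_homology_runs,
    diff_stats,
    diversify_termini,
    find_identity_runs,
    recode_cds,
)


class TestRecodeCDS:
    def test_hand_example_under_toy_scheme(self, toy_scheme):
        cds = CDSRecord("x", "ATGCTGAGAGGGTAG")
        result = recode_cds(cds, toy_scheme)
        assert result.recoded == "ATGTTACGTGGTTAA"
        assert len(result.ledger) == 4
        categories = [e.category for e in result.ledger]
        assert categories == ["target", "target", "target", "stop"]

    def test_no_targets_means_no_edits(self, toy_scheme):
        cds = CDSRecord("x", "ATGTTAAAATAA")
        result = recode_cds(cds, toy_scheme)
        assert result.recoded == cds.seq
        assert len(result.ledger) == 0
        assert result.stats == {"codons_changed": 0, "bases_changed": 0,
                                "base_fraction": 0.0}

    def test_ledger_against_scheme_oracle(self, toy, toy_scheme):
        """Every edit's old codon is eliminated and its new codon is in
        the permitted set (or the canonical stop); brute scan agrees."""
        for cds in toy.cds_records[:5]:
            result = recode_cds(cds, toy_scheme)
            edited = {e.codon_index for e in result.ledger}
            for i, codon in enumerate(cds.codons()):
                assert (i in edited) == (codon in toy_scheme.eliminated)
            for e in result.ledger:
                assert e.old_codon in toy_scheme.eliminated
                if e.category == "stop":
                    assert e.new_codon == "TAA"
                else:
                    aa = STANDARD_CODE.amino_acid(e.old_codon)
                    assert e.new_codon in toy_scheme.permitted[aa]

    def test_idempotent_on_recoded_sequence(self, toy, toy_scheme):
        result = recode_cds(toy.cds_records[0], toy_scheme)
        again = recode_cds(CDSRecord("again", result.recoded), toy_scheme)
        assert len(again.ledger) == 0
        assert again.recoded == result.recoded

    def test_ambiguous_codon_rejected(self, toy_scheme):
        with pytest.raises(ValueError):
            recode_cds(CDSRecord("x", "ATGNNNTAA"), toy_scheme)


class TestIdentityRuns:
    def test_identical_strings_single_run(self):
        runs = find_identity_runs("ATGAAA", "ATGAAA")
        assert [(r.start, r.end) for r in runs] == [(0, 6)]

    def test_hand_example(self):
        runs = find_identity_runs("ATGAAACCC", "ATGAAGCCC")
        assert [(r.start, r.end) for r in runs] == [(0, 5), (6, 9)]

    def test_length_mismatch_raises(self):
        with pytest.raises(RecodingError):
            find_identity_runs("AAA", "AAAA")

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2 ** 40 - 1))
    def test_matches_naive_oracle(self, bits):
        """Runs computed by the scanner equal a per-position oracle."""
        n = 40
        a = "A" * n
        b = "".join("A" if (bits >> i) & 1 else "C" for i in range(n))
        runs = find_identity_runs(a, b)
        covered = set()
        for r in runs:
            assert r.end > r.start
            covered.update(range(r.start, r.end))
        match_positions = {i for i in range(n) if a[i] == b[i]}
        assert covered == match_positions
        # maximality: boundaries differ
        for r in runs:
            if r.start > 0:
                assert a[r.start - 1] != b[r.start - 1]
            if r.end < n:
                assert a[r.end] != b[r.end]


class TestBreakHomologyRuns:
    def test_long_lysine_run_is_broken(self, toy_scheme, toy_usage):
        cds = CDSRecord("lys", "ATG" + "AAA" * 70 + "TAA")
        result = recode_cds(cds, toy_scheme)  # no targets: full-length run
        broken = break_homology_runs(result, toy_scheme, toy_usage,
                                     max_run_bp=60)
        runs = find_identity_runs(cds.seq, broken.recoded)
        assert max(r.length for r in runs) < 60
        assert any(e.category == "homology_break" for e in broken.ledger)
        assert all(e.old_codon == "AAA" and e.new_codon == "AAG"
                   for e in broken.ledger)

    def test_already_under_threshold_unchanged(self, toy, toy_scheme, toy_usage):
        result = recode_cds(toy.cds_records[0], toy_scheme)
        longest = max(r.length for r in find_identity_runs(
            result.original.seq, result.recoded))
        out = break_homology_runs(result, toy_scheme, toy_usage,
                                  max_run_bp=longest + 1)
        assert out.recoded == result.recoded
        assert out.ledger.edits == result.ledger.edits

    def test_unbreakable_run_raises(self, toy_scheme, toy_usage):
        # Met/Trp have no synonyms; the run cannot be broken
        cds = CDSRecord("mw", "ATG" + "TGG" * 30 + "TAA")
        result = recode_cds(cds, toy_scheme)
        with pytest.raises(RecodingError, match="run"):
            break_homology_runs(result, toy_scheme, toy_usage, max_run_bp=30)

    def test_threshold_validation(self, toy, toy_scheme, toy_usage):
        result = recode_cds(toy.cds_records[0], toy_scheme)
        with pytest.raises(RecodingError):
            break_homology_runs(result, toy_scheme, toy_usage, max_run_bp=2)

    def test_translation_and_alphabet_preserved(self, toy, toy_scheme,
                                                toy_usage):
        for cds in toy.cds_records[:5]:
            result = recode_cds(cds, toy_scheme)
            broken = break_homology_runs(result, toy_scheme, toy_usage,
                                         max_run_bp=60)
            assert STANDARD_CODE.translate(broken.recoded) == \
                STANDARD_CODE.translate(cds.seq)
            for i in range(0, len(broken.recoded), 3):
                assert broken.recoded[i:i + 3] not in toy_scheme.eliminated


class TestDiversifyTermini:
    def test_zero_codons_is_identity(self, toy, toy_scheme, toy_usage):
        result = recode_cds(toy.cds_records[1], toy_scheme)
        out = diversify_termini(result, toy_scheme, toy_usage, n_codons=0)
        assert out.recoded == result.recoded

    def test_left_end_lysines_swapped(self, toy_scheme, toy_usage):
        cds = CDSRecord("k", "ATG" + "AAA" * 10 + "TAA")
        result = recode_cds(cds, toy_scheme)
        out = diversify_termini(result, toy_scheme, toy_usage,
                                n_codons=2, ends="left")
        terminal = [e for e in out.ledger if e.category == "terminal"]
        assert [(e.codon_index, e.old_codon, e.new_codon) for e in terminal] == \
            [(1, "AAA", "AAG"), (2, "AAA", "AAG")]
        # start codon untouched
        assert out.recoded.startswith("ATG")

    def test_start_and_stop_never_edited(self, toy, toy_scheme, toy_usage):
        for cds in toy.cds_records[:5]:
            result = recode_cds(cds, toy_scheme)
            out = diversify_termini(result, toy_scheme, toy_usage,
                                    n_codons=10, ends="both")
            n = cds.n_codons
            for e in out.ledger:
                if e.category == "terminal":
                    assert e.codon_index not in (0, n - 1)

    def test_edit_count_bounded_by_window(self, toy, toy_scheme, toy_usage):
        n_codons = 7
        for cds in toy.cds_records[:5]:
            result = recode_cds(cds, toy_scheme)
            out = diversify_termini(result, toy_scheme, toy_usage,
                                    n_codons=n_codons, ends="both")
            terminal = [e for e in out.ledger if e.category == "terminal"]
            left = sum(1 for e in terminal if e.codon_index <= n_codons)
            right = sum(1 for e in terminal
                        if e.codon_index >= cds.n_codons - 1 - n_codons)
            assert left <= n_codons
            assert right <= n_codons
            assert len(terminal) == left + right

    def test_translation_preserved(self, toy, toy_scheme, toy_usage):
        cds = toy.cds_records[2]
        result = recode_cds(cds, toy_scheme)
        out = diversify_termini(result, toy_scheme, toy_usage, n_codons=10)
        assert STANDARD_CODE.translate(out.recoded) == \
            STANDARD_CODE.translate(cds.seq)


class TestDiffStats:
    def test_identical(self):
        assert diff_stats("ATGTTA", "ATGTTA") == {
            "codons_changed": 0, "bases_changed": 0, "base_fraction": 0.0}

    def test_single_base(self):
        stats = diff_stats("ATGTTA", "ATGTTG")
        assert stats["codons_changed"] == 1
        assert stats["bases_changed"] == 1
        assert stats["base_fraction"] == pytest.approx(1 / 6)

    def test_mismatched_length_raises(self):
        with pytest.raises(RecodingError):
            diff_stats("ATG", "ATGTTA")

    def test_agrees_with_ground_truth_edits(self, toy, toy_scheme):
        from codoncompress.fixtures import make_recoded_pair
        wt, rec, edits = make_recoded_pair(toy.cds_records[3], toy_scheme)
        stats = diff_stats(wt, rec)
        assert stats["codons_changed"] == len(edits)
        expected_bases = sum(
            sum(1 for a, b in zip(e.old_codon, e.new_codon) if a != b)
            for e in edits)
        assert stats["bases_changed"] == expected_bases
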