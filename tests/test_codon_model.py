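"""Genetic code, usage counting, wobble decoding, boxes, and CAI."""

import math

import pytest
from scipy import stats

from codoncompress.codon_model import (
    CODONS,
    RosterError,
    STANDARD_CODE,
    UsageTable,
    cai_score,
    cai_weights,
    classify_codon_frequency_class,
    count_codon_usage,
    decode_anticodon,
    is_dual,
    partition_isoacceptor_boxes,
)
from codoncompress.genome_io import CDSRecord, TRNAGene
from codoncompress.fixtures import TOY_USAGE, make_toy_plastome


class TestUsageCounting:
    def test_single_cds_with_stops(self):
        table = count_codon_usage([CDSRecord("x", "ATGTAA")], include_stops=True)
        assert table.counts == {"ATG": 1, "TAA": 1}

    def test_stops_excluded_by_default(self):
        table = count_codon_usage([CDSRecord("x", "ATGTAA")])
        assert table.counts == {"ATG": 1}

    def test_empty_list_gives_empty_table(self):
        table = count_codon_usage([])
        assert table.total == 0
        assert table.frequency("ATG") == 0.0

    def test_counts_equal_generator_emission_record(self, toy):
        """Brute-force counting over the generated CDSs must equal the
        generator's own log of every emitted codon."""
        table = count_codon_usage(toy.cds_records, include_stops=True)
        assert dict(table.counts) == dict(toy.emission)

    def test_large_sample_matches_profile_by_chi2(self):
        """Per-family codon frequencies of >=10^4 sampled codons are
        consistent with the sampling profile (chi-square, p > 0.01)."""
        toy = make_toy_plastome(n_genes=20, length_mean=600, seed=5)
        table = count_codon_usage(toy.cds_records, include_stops=True)
        freqs = TOY_USAGE.target_frequencies()
        assert table.total >= 10_000
        for aa in "LISRG":
            family = sorted(TOY_USAGE.weights[aa])
            observed = [table.count(c) for c in family]
            n = sum(observed)
            expected = [freqs[c] * n for c in family]
            # drop zero-probability cells
            obs, exp = zip(*[(o, e) for o, e in zip(observed, expected) if e > 0])
            _, p = stats.chisquare(obs, exp)
            assert p > 0.01, f"family {aa}: p={p}"

    def test_tsv_round_trip(self, toy_usage, tmp_path):
        path = tmp_path / "usage.tsv"
        toy_usage.to_tsv(path)
        assert UsageTable.from_tsv(path).counts == toy_usage.counts


class TestAnticodonDecoding:
    @pytest.mark.parametrize("anticodon,superwobble,expected", [
        ("TAA", False, {"TTA", "TTG"}),                      # tRNA-Leu(UAA)
        ("TCC", True, {"GGA", "GGG", "GGT", "GGC"}),         # trnG-UCC superwobble
        ("GAT", False, {"ATC", "ATT"}),
        ("CAT", False, {"ATG"}),
        ("CCA", False, {"TGG"}),
        ("GCA", False, {"TGC", "TGT"}),
    ])
    def test_wobble_table(self, anticodon, superwobble, expected):
        aa = STANDARD_CODE.amino_acid(next(iter(expected)))
        trna = TRNAGene("t", aa, anticodon, superwobble=superwobble)
        assert decode_anticodon(trna) == frozenset(expected)

    def test_rna_anticodon_accepted(self):
        trna = TRNAGene("t", "L", "UAA")
        assert decode_anticodon(trna) == frozenset({"TTA", "TTG"})

    def test_codon_override_wins(self):
        trna = TRNAGene("t", "I", "CAT", codon_override=frozenset({"ATA"}))
        assert decode_anticodon(trna) == frozenset({"ATA"})

    def test_override_must_be_synonymous(self):
        with pytest.raises(ValueError):
            TRNAGene("t", "I", "CAT", codon_override=frozenset({"ATG"}))

    def test_invalid_anticodon_rejected(self):
        trna = TRNAGene.__new__(TRNAGene)
        trna.id, trna.amino_acid, trna.anticodon = "t", "L", "TNA"
        trna.superwobble, trna.codon_override = False, None
        with pytest.raises(ValueError):
            decode_anticodon(trna)

    def test_decoded_codons_translate_to_trna_amino_acid(self, toy):
        for trna in toy.roster:
            for codon in decode_anticodon(trna):
                assert STANDARD_CODE.amino_acid(codon) == trna.amino_acid


class TestBoxPartition:
    def test_dual_families_on_default_roster(self, toy_boxes):
        dual = {aa for aa in toy_boxes if is_dual(toy_boxes, aa)}
        assert dual == {"L", "I", "S", "R", "G"}

    def test_leu_and_gly_boxes(self, toy_boxes):
        leu = {frozenset(b.codons) for b in toy_boxes["L"]}
        assert leu == {frozenset({"TTA", "TTG"}),
                       frozenset({"CTT", "CTC", "CTA", "CTG"})}
        # superwobble GGN overlap with GGY resolved: trnG-GCC keeps GGY
        gly = {frozenset(b.codons) for b in toy_boxes["G"]}
        assert gly == {frozenset({"GGC", "GGT"}), frozenset({"GGA", "GGG"})}

    def test_single_trp_box_not_dual(self, toy_boxes):
        assert not is_dual(toy_boxes, "W")
        assert {c for b in toy_boxes["W"] for c in b.codons} == {"TGG"}

    def test_duplicate_trnas_merge_to_one_box(self, toy_boxes):
        # trnA-UGC appears twice (IR copies), trnM x2 (initiator/elongator)
        assert len(toy_boxes["A"]) == 1
        assert len(toy_boxes["M"]) == 1
        assert toy_boxes["M"][0].codons == frozenset({"ATG"})

    def test_boxes_partition_each_family(self, toy_boxes):
        for aa, boxes in toy_boxes.items():
            union = set()
            for box in boxes:
                assert not (union & box.codons), f"{aa} boxes overlap"
                union |= box.codons
            assert union == set(STANDARD_CODE.synonymous_family(aa))

    def test_unresolvable_overlap_raises(self):
        # two superwobble Gly tRNAs both claim GGN
        roster = [TRNAGene("a", "G", "TCC", superwobble=True),
                  TRNAGene("b", "G", "GCC", superwobble=True)]
        with pytest.raises(RosterError):
            partition_isoacceptor_boxes(roster)

    def test_wrong_amino_acid_assignment_raises(self):
        with pytest.raises(RosterError):
            partition_isoacceptor_boxes([TRNAGene("t", "L", "GAA")])  # decodes Phe


class TestFrequencyClass:
    def test_definition(self):
        assert classify_codon_frequency_class("TTA") == "frequent"
        assert classify_codon_frequency_class("CGG") == "rare"

    def test_alphabet_splits_evenly(self):
        classes = [classify_codon_frequency_class(c) for c in CODONS]
        assert classes.count("frequent") == 32
        assert classes.count("rare") == 32


class TestCAI:
    def test_weights_are_count_over_family_max(self):
        table = UsageTable({"TTA": 90, "TTG": 10})
        model = cai_weights(table)
        assert model.weight("TTA") == 1.0
        assert model.weight("TTG") == pytest.approx(1 / 9)

    def test_uniform_counts_give_weight_one(self):
        table = UsageTable({c: 7 for c in STANDARD_CODE.synonymous_family("G")})
        model = cai_weights(table)
        assert all(model.weight(c) == 1.0
                   for c in STANDARD_CODE.synonymous_family("G"))

    def test_zero_count_floor(self):
        table = UsageTable({"TTA": 90})
        model = cai_weights(table)
        assert model.weight("TTG") == pytest.approx(0.5 / 90)

    def test_absent_family_raises_naming_the_amino_acid(self):
        model = cai_weights(UsageTable({"TTA": 90}))
        with pytest.raises(ValueError, match="G"):
            cai_score(["GGT"], model)

    def test_geometric_mean(self):
        model = cai_weights(UsageTable({"TTA": 90, "TTG": 10}))
        assert cai_score(["TTA", "TTG"], model) == pytest.approx(
            math.sqrt(1 * 1 / 9))
        assert cai_score(["TTA", "TTG"], model) == pytest.approx(1 / 3)

    def test_all_maximal_codons_score_one(self, toy_usage, toy_cai):
        seq = []
        for aa in "LSRGKF":
            family = STANDARD_CODE.synonymous_family(aa)
            seq.append(max(family, key=toy_usage.count))
        assert cai_score(seq, toy_cai) == pytest.approx(1.0)

    def test_met_trp_and_stops_excluded(self, toy_usage, toy_cai):
        top_leu = max(STANDARD_CODE.synonymous_family("L"), key=toy_usage.count)
        assert cai_score(["ATG", "TGG", top_leu, "TAA"],
                         toy_cai) == pytest.approx(1.0)

    def test_empty_inclusion_set_raises(self, toy_cai):
        with pytest.raises(ValueError):
            cai_score("ATGTGG", toy_cai)  # only excluded families
        with pytest.raises(ValueError):
            cai_score("TTATTG", toy_cai, positions=[])

    def test_permutation_invariance(self, toy_cai):
        codons = ["TTA", "TTG", "CGG", "GGC", "TCA"]
        forward = cai_score(codons, toy_cai)
        assert cai_score(codons[::-1], toy_cai) == pytest.approx(forward)

    def test_monotone_under_lower_weight_swap(self, toy_usage, toy_cai):
        family = sorted(STANDARD_CODE.synonymous_family("L"),
                        key=toy_usage.count)
        low, high = family[0], family[-1]
        base = cai_score([high, "AAA", "GAA"], toy_cai)
        worse = cai_score([low, "AAA", "GAA"], toy_cai)
        assert worse < base
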