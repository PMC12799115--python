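"""Synthetic AT-rich plastome-like genomes with known ground truth.

Real plastomes are AT-rich (65% in *Chlamydomonas reinhardtii*) with a
strong bias toward codons ending A or T, and are translated by a small
tRNA roster in which five amino acids (Leu, Ile, Ser, Arg, Gly) have two
isoacceptor tRNAs of very unequal use.  The generator emulates exactly
those features — a configurable per-family codon-usage profile and a
29-gene tRNA roster with dual-isoacceptor families — so that scheme
derivation, recoding, library design and read verification are all
testable without downloading a genome.  It does not simulate inverted
repeats, dispersed repeats, introns or trans-splicing.

Every emitted codon is logged in an emission record, giving an exact
oracle for usage counting, and all randomness flows through a single
seeded generator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import json

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .codon_model import (
    CODONS,
    GeneticCode,
    STANDARD_CODE,
    normalize_dna,
)
from .genome_io import CDSRecord, TRNAGene
from .recode import RecodingResult, recode_cds
from .scheme import CompressionScheme

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def _frequent_biased(family: Sequence[str]) -> dict[str, float]:
    # codons ending A/T three times as likely as those ending G/C
    return {c: (3.0 if c[2] in "AT" else 1.0) for c in family}


def _build_toy_weights(code: GeneticCode) -> dict[str, dict[str, float]]:
    explicit = {
        "L": {"TTA": 90, "TTG": 10, "CTT": 5, "CTC": 5, "CTA": 5, "CTG": 5},
        "I": {"ATT": 60, "ATC": 20, "ATA": 8},
        "S": {"TCT": 30, "TCA": 25, "TCC": 5, "TCG": 2, "AGT": 10, "AGC": 6},
        "R": {"CGT": 40, "CGC": 5, "CGA": 3, "CGG": 1, "AGA": 30, "AGG": 6},
        "G": {"GGT": 50, "GGC": 20, "GGA": 25, "GGG": 5},
        "*": {"TAA": 60, "TAG": 4, "TGA": 0},
    }
    weights: dict[str, dict[str, float]] = {}
    families: dict[str, list[str]] = {}
    for codon in CODONS:
        families.setdefault(code.amino_acid(codon), []).append(codon)
    for aa, family in families.items():
        if aa in explicit:
            weights[aa] = {c: float(explicit[aa].get(c, 0.0)) for c in family}
        else:
            weights[aa] = _frequent_biased(family)
    return weights


@dataclass
class UsageProfile:
    """Per-amino-acid codon sampling weights (normalized per family)."""

    weights: dict[str, dict[str, float]]
    name: str = "profile"

    def __post_init__(self) -> None:
        for aa, family in self.weights.items():
            if sum(family.values()) <= 0:
                raise ValueError(f"family {aa} has no positive weight")

    def target_frequencies(self) -> dict[str, float]:
        freqs = {}
        for family in self.weights.values():
            total = sum(family.values())
            for codon, w in family.items():
                freqs[codon] = w / total
        return freqs

    @property
    def at_richness(self) -> float:
        """Expected A/T base fraction of coding sequence under uniform
        amino-acid composition."""
        at = 0.0
        n_fam = 0
        for aa, family in self.weights.items():
            if aa == "*":
                continue
            total = sum(family.values())
            at += sum(w / total * sum(1 for b in c if b in "AT") / 3
                      for c, w in family.items())
            n_fam += 1
        return at / n_fam


TOY_USAGE = UsageProfile(weights=_build_toy_weights(STANDARD_CODE),
                         name="TOY_USAGE")


def default_toy_roster() -> list[TRNAGene]:
    """A 29-gene tRNA roster mirroring the plastid decoding landscape.

    Dual-isoacceptor families: Leu (TTR vs superwobble CTN), Ile (GAU
    wobble ATY vs lysidine-modified CAU reading ATA via codon_override),
    Ser (superwobble TCN vs AGY), Arg (inosine CGN via codon_override vs
    AGR), Gly (GGY vs superwobble GGN, resolved to GGR by precedence).
    Duplicated genes (trnA-UGC, trnI-GAU, trnE-UUC) and the
    initiator/elongator Met pair are included so roster merging is
    exercised.
    """
    T = TRNAGene
    return [
        T("Ct001", "F", "GAA"),
        T("Ct002", "L", "TAA"),
        T("Ct003", "E", "TTC"),
        T("Ct004", "V", "TAC", superwobble=True),
        T("Ct005", "S", "TGA", superwobble=True),
        T("Ct006", "R", "TCT"),
        T("Ct007", "P", "TGG", superwobble=True),
        T("Ct008", "T", "TGT", superwobble=True),
        T("Ct009", "L", "TAG", superwobble=True),
        T("Ct010", "I", "CAT", codon_override=frozenset({"ATA"})),
        T("Ct011", "G", "GCC"),
        T("Ct012", "I", "GAT"),
        T("Ct013", "A", "TGC", superwobble=True),
        T("Ct014", "S", "GCT"),
        T("Ct015", "Y", "GTA"),
        T("Ct016", "E", "TTC"),
        T("Ct017", "H", "GTG"),
        T("Ct018", "M", "CAT"),
        T("Ct019", "Q", "TTG"),
        T("Ct020", "N", "GTT"),
        T("Ct021", "G", "TCC", superwobble=True),
        T("Ct022", "K", "TTT"),
        T("Ct023", "A", "TGC", superwobble=True),
        T("Ct024", "I", "GAT"),
        T("Ct025", "D", "GTC"),
        T("Ct026", "M", "CAT"),
        T("Ct027", "C", "GCA"),
        T("Ct028", "W", "CCA"),
        T("Ct029", "R", "ACG",
          codon_override=frozenset({"CGT", "CGC", "CGA", "CGG"})),
    ]


_TRNA_NAMES = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


@dataclass
class ToyPlastome:
    """A generated genome plus its ground truth."""

    record: SeqRecord                  # single annotated contig
    cds_records: list[CDSRecord]       # coding-strand ground truth
    roster: list[TRNAGene]
    emission: Counter                  # exact count of every emitted codon
    seed: int
    profile_name: str = "TOY_USAGE"

    def write_genbank(self, path) -> None:
        with open(path, "w") as fh:
            SeqIO.write([self.record], fh, "genbank")

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            SeqIO.write(
                [SeqRecord(Seq(c.seq), id=c.id, description="")
                 for c in self.cds_records], fh, "fasta")

    def write_emission_record(self, path) -> None:
        payload = {
            "seed": self.seed,
            "profile": self.profile_name,
            "codon_counts": {c: int(n) for c, n in sorted(self.emission.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def _sample_codon(rng: np.random.Generator, family: dict[str, float]) -> str:
    codons = sorted(family)
    weights = np.array([family[c] for c in codons], dtype=float)
    weights /= weights.sum()
    return codons[rng.choice(len(codons), p=weights)]


def _spacer(rng: np.random.Generator, length: int, at_fraction: float = 0.7) -> str:
    p = np.array([at_fraction / 2, (1 - at_fraction) / 2,
                  (1 - at_fraction) / 2, at_fraction / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def make_toy_plastome(n_genes: int = 20, length_mean: int = 300,
                      profile: UsageProfile = TOY_USAGE,
                      seed: int = 0,
                      code: GeneticCode = STANDARD_CODE) -> ToyPlastome:
    """Generate an annotated toy plastome.

    Each CDS has a uniform-random amino-acid sequence of ~``length_mean``
    codons (Poisson, floor 30), an ATG start, codons drawn per family
    from ``profile`` and a stop drawn from the stop weights.  Genes
    alternate between strands on a single contig separated by AT-rich
    spacers; the roster's tRNAs are annotated as features downstream.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    aa_letters = [aa for aa in _AA_ORDER if aa != "M"]
    emission: Counter = Counter()
    cds_records: list[CDSRecord] = []
    features: list[SeqFeature] = []
    contig_parts: list[str] = []
    offset = 0

    for g in range(n_genes):
        spacer = _spacer(rng, int(rng.integers(40, 80)))
        contig_parts.append(spacer)
        offset += len(spacer)

        n_codons = max(30, int(rng.poisson(length_mean)))
        codons = ["ATG"]
        emission["ATG"] += 1
        for _ in range(n_codons - 2):
            aa = aa_letters[rng.integers(len(aa_letters))]
            codon = _sample_codon(rng, profile.weights[aa])
            codons.append(codon)
            emission[codon] += 1
        stop = _sample_codon(rng, profile.weights["*"])
        codons.append(stop)
        emission[stop] += 1
        seq = "".join(codons)

        strand = 1 if g % 2 == 0 else -1
        genomic = seq if strand == 1 else str(Seq(seq).reverse_complement())
        start, end = offset, offset + len(genomic)
        contig_parts.append(genomic)
        offset = end

        gene_id = f"toy{g + 1:03d}"
        cds_records.append(CDSRecord(
            id=gene_id, seq=seq, product=f"toy protein {g + 1}",
            source_interval=("toy_plastome", start, end, strand)))
        features.append(SeqFeature(
            FeatureLocation(start, end, strand=strand), type="CDS",
            qualifiers={"locus_tag": [gene_id],
                        "product": [f"toy protein {g + 1}"]}))

    roster = default_toy_roster()
    for trna in roster:
        spacer = _spacer(rng, 30)
        contig_parts.append(spacer)
        offset += len(spacer)
        body = _spacer(rng, 72, at_fraction=0.5)
        start, end = offset, offset + len(body)
        contig_parts.append(body)
        offset = end
        anticodon_rna = trna.anticodon.replace("T", "U")
        features.append(SeqFeature(
            FeatureLocation(start, end, strand=1), type="tRNA",
            qualifiers={
                "locus_tag": [trna.id],
                "gene": [f"trn{trna.amino_acid}-{anticodon_rna}"],
                "product": [f"tRNA-{_TRNA_NAMES[trna.amino_acid]}"],
                "anticodon": [trna.anticodon],
            }))

    record = SeqRecord(Seq("".join(contig_parts)), id="toy_plastome",
                       name="toy_plastome",
                       description=f"synthetic AT-rich toy plastome "
                                   f"(profile {profile.name}, seed {seed})",
                       annotations={"molecule_type": "DNA",
                                    "topology": "circular"})
    record.features = features
    return ToyPlastome(record=record, cds_records=cds_records, roster=roster,
                       emission=emission, seed=seed,
                       profile_name=profile.name)


def make_recoded_pair(toy_cds: CDSRecord, scheme: CompressionScheme,
                      code: GeneticCode = STANDARD_CODE,
                      ) -> tuple[str, str, list]:
    """Ground-truth (wt, recoded, true edits) pair for diff/read tests."""
    result: RecodingResult = recode_cds(toy_cds, scheme, code)
    return toy_cds.seq, result.recoded, list(result.ledger)
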