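"""Genetic code, codon usage, tRNA decoding, codon boxes, and CAI.

The chloroplast translation system reads all 61 sense codons with a small
roster of tRNAs (29 genes in *Chlamydomonas reinhardtii*), relying on
wobble and superwobble pairing at the third codon position.  This module
models that decoding, partitions each amino acid's codons into
isoacceptor "codon boxes" (the synonymous set read by one tRNA), and
provides the usage statistics and codon adaptation index (CAI) needed to
choose which box of a dual-tRNA amino acid to eliminate.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data import CodonTable

BASES = "ACGT"
CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_dna(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


class RosterError(ValueError):
    """A tRNA roster is internally inconsistent."""


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> one-letter amino acid map over all 64 codons.

    Stop codons are keyed with ``*``.  The default is NCBI translation
    table 11 (bacterial/plastid), which over the 64-codon map coincides
    with the standard code.
    """

    table: Mapping[str, str]
    stops: frozenset[str]

    def __post_init__(self) -> None:
        if set(self.table) != set(CODONS):
            raise ValueError("genetic code must key exactly the 64 codons")
        if any(self.table[c] != "*" for c in self.stops):
            raise ValueError("stop codons must map to '*'")

    @classmethod
    def from_ncbi_table(cls, table_id: int = 11) -> "GeneticCode":
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(ncbi.forward_table)
        for stop in ncbi.stop_codons:
            table[stop] = "*"
        return cls(table=table, stops=frozenset(ncbi.stop_codons))

    def amino_acid(self, codon: str) -> str:
        codon = normalize_dna(codon)
        try:
            return self.table[codon]
        except KeyError:
            raise ValueError(f"not an unambiguous codon: {codon!r}") from None

    def is_stop(self, codon: str) -> bool:
        return normalize_dna(codon) in self.stops

    def translate(self, seq: str) -> str:
        seq = normalize_dna(seq)
        if len(seq) % 3:
            raise ValueError("sequence length not divisible by 3")
        return "".join(self.amino_acid(seq[i : i + 3]) for i in range(0, len(seq), 3))

    def synonymous_family(self, amino_acid: str) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == amino_acid)


STANDARD_CODE = GeneticCode.from_ncbi_table(11)


def codons_of(seq: str) -> list[str]:
    seq = normalize_dna(seq)
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


@dataclass
class UsageTable:
    """Per-codon occurrence counts over a CDS set."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for codon, n in self.counts.items():
            if codon not in CODONS:
                raise ValueError(f"invalid codon in usage table: {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, codon: str) -> int:
        return self.counts.get(normalize_dna(codon), 0)

    def frequency(self, codon: str) -> float:
        total = self.total
        return self.count(codon) / total if total else 0.0

    def box_usage(self, codons: Iterable[str]) -> int:
        return sum(self.count(c) for c in codons)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tcount\n")
            for codon in CODONS:
                if codon in self.counts:
                    fh.write(f"{codon}\t{self.counts[codon]}\n")

    @classmethod
    def from_tsv(cls, path) -> "UsageTable":
        counts: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("codon"):
                raise ValueError("usage TSV must start with a 'codon\\tcount' header")
            for line in fh:
                if not line.strip():
                    continue
                codon, n = line.split("\t")
                counts[normalize_dna(codon)] = int(n)
        return cls(counts=counts)


def count_codon_usage(cds_list: Sequence, include_stops: bool = False,
                      code: GeneticCode = STANDARD_CODE) -> UsageTable:
    """Count every codon of every CDS; stops only if ``include_stops``."""
    counts: Counter[str] = Counter()
    for cds in cds_list:
        seq = cds.seq if hasattr(cds, "seq") else cds
        for codon in codons_of(seq):
            if code.is_stop(codon) and not include_stops:
                continue
            counts[codon] += 1
    return UsageTable(counts=dict(counts))


# Wobble rules: anticodon base 34 (5' base) determines which third codon
# bases can be read.  An unmodified U34 without other constraints reads all
# four (superwobble), as shown for plastid trnG-UCC.
_WOBBLE = {
    "G": ("C", "T"),
    "C": ("G",),
    "T": ("A", "G"),
    "A": ("T",),
}
_SUPERWOBBLE = ("A", "C", "G", "T")


def decode_anticodon(trna, code: GeneticCode = STANDARD_CODE) -> frozenset[str]:
    """Codon set read by a tRNA, from its anticodon under wobble rules.

    The codon's first two bases are the reverse complement of the
    anticodon's bases 2-3; the third base set depends on the wobble class
    of the anticodon's 5' base (position 34).  An explicit
    ``codon_override`` (e.g. for inosine- or lysidine-modified tRNAs)
    wins outright.
    """
    if trna.codon_override:
        return frozenset(normalize_dna(c) for c in trna.codon_override)
    anticodon = normalize_dna(trna.anticodon)
    if len(anticodon) != 3 or any(b not in BASES for b in anticodon):
        raise ValueError(f"invalid anticodon {trna.anticodon!r} for {trna.id}")
    prefix = reverse_complement(anticodon[1:])
    wobble_base = anticodon[0]
    if getattr(trna, "superwobble", False):
        thirds = _SUPERWOBBLE
    else:
        thirds = _WOBBLE[wobble_base]
    return frozenset(prefix + b for b in thirds)


@dataclass(frozen=True)
class CodonBox:
    """Synonymous codons read by a single tRNA via (super)wobble."""

    amino_acid: str
    codons: frozenset[str]
    trna_id: str


def partition_isoacceptor_boxes(trnas: Sequence, code: GeneticCode = STANDARD_CODE,
                                ) -> dict[str, list[CodonBox]]:
    """Partition each amino acid's codons into isoacceptor boxes.

    Duplicated tRNAs (identical anticodon, e.g. inverted-repeat copies)
    merge into one box.  When a superwobble 4-codon box overlaps a
    2-codon wobble box of the same amino acid (plastid Gly: trnG-UCC
    superwobbles GGN while trnG-GCC reads GGY), the overlap is assigned
    to the non-superwobble tRNA and the superwobble box keeps the
    remainder.  Amino acids left with two disjoint boxes are the "dual"
    families targeted by compression.
    """
    decoded: dict[str, list[tuple[object, frozenset[str]]]] = defaultdict(list)
    for trna in trnas:
        codons = decode_anticodon(trna, code)
        for codon in codons:
            aa = code.amino_acid(codon)
            if aa != trna.amino_acid:
                raise RosterError(
                    f"tRNA {trna.id} ({trna.amino_acid}) decodes {codon}, "
                    f"which translates to {aa}")
        # merge duplicated genes: identical anticodon (and modifiers), e.g.
        # inverted-repeat copies or the initiator/elongator Met pair
        key = (normalize_dna(trna.anticodon), getattr(trna, "superwobble", False),
               trna.codon_override or frozenset())
        for existing, existing_codons in decoded[trna.amino_acid]:
            existing_key = (normalize_dna(existing.anticodon),
                            getattr(existing, "superwobble", False),
                            existing.codon_override or frozenset())
            if existing_key == key:
                break
        else:
            decoded[trna.amino_acid].append((trna, codons))

    boxes: dict[str, list[CodonBox]] = {}
    for aa, members in decoded.items():
        sets = [(t, set(c)) for t, c in members]
        # superwobble-overlap precedence
        for i, (ti, ci) in enumerate(sets):
            for j, (tj, cj) in enumerate(sets):
                if i == j or not (ci & cj):
                    continue
                si = getattr(ti, "superwobble", False)
                sj = getattr(tj, "superwobble", False)
                if si and not sj:
                    ci -= cj
                elif sj and not si:
                    cj -= ci
                else:
                    raise RosterError(
                        f"unresolvable box overlap for {aa}: "
                        f"{ti.id} vs {tj.id} share {sorted(ci & cj)}")
        boxes[aa] = [CodonBox(amino_acid=aa, codons=frozenset(c), trna_id=t.id)
                     for t, c in sets if c]
    return boxes


def is_dual(boxes: Mapping[str, list[CodonBox]], amino_acid: str) -> bool:
    return len(boxes.get(amino_acid, [])) == 2


def classify_codon_frequency_class(codon: str) -> str:
    """'frequent' iff the third base is A or T (AT-rich plastome bias)."""
    codon = normalize_dna(codon)
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    return "frequent" if codon[2] in "AT" else "rare"


@dataclass
class CAIModel:
    """Relative-adaptiveness weights w(c) = f(c)/max f within each family."""

    weights: dict[str, float]
    reference_description: str = ""

    def weight(self, codon: str, code: GeneticCode = STANDARD_CODE) -> float:
        codon = normalize_dna(codon)
        try:
            return self.weights[codon]
        except KeyError:
            aa = code.amino_acid(codon)
            raise ValueError(
                f"no CAI weight for codon {codon} (amino acid {aa}): "
                f"family absent from the reference usage") from None


# Amino acids excluded from the geometric mean: single-codon families have
# weight 1 by construction and would only dilute the index.
_CAI_EXCLUDED_AA = frozenset({"M", "W", "*"})


def cai_weights(reference: UsageTable, code: GeneticCode = STANDARD_CODE,
                zero_count_floor: float = 0.5,
                reference_description: str = "") -> CAIModel:
    """Build CAI weights from a reference usage table.

    Within each synonymous family, w = count/max-count; codons unobserved
    in the reference get ``zero_count_floor``/max-count so geometric means
    stay finite.  Families entirely absent from the reference get no
    weights; scoring a position in such a family raises an error naming
    the amino acid.
    """
    weights: dict[str, float] = {}
    families: dict[str, list[str]] = defaultdict(list)
    for codon in CODONS:
        aa = code.amino_acid(codon)
        if aa != "*":
            families[aa].append(codon)
    for aa, codons in families.items():
        max_count = max(reference.count(c) for c in codons)
        if max_count == 0:
            continue
        for c in codons:
            n = reference.count(c)
            weights[c] = (n if n > 0 else zero_count_floor) / max_count
    return CAIModel(weights=weights, reference_description=reference_description)


def cai_score(seq_or_codons, model: CAIModel,
              positions: Optional[Iterable[int]] = None,
              code: GeneticCode = STANDARD_CODE) -> float:
    """Geometric mean of CAI weights over the included codon positions.

    Stop codons and single-codon families (Met, Trp) are excluded.  An
    empty inclusion set (after exclusions) is an error.
    """
    if isinstance(seq_or_codons, str):
        codons = codons_of(seq_or_codons)
    else:
        codons = [normalize_dna(c) for c in seq_or_codons]
    if positions is not None:
        positions = sorted(set(positions))
        if any(p < 0 or p >= len(codons) for p in positions):
            raise IndexError("position outside the coding sequence")
        codons = [codons[p] for p in positions]
    included = [c for c in codons if code.amino_acid(c) not in _CAI_EXCLUDED_AA]
    if not included:
        raise ValueError("no scorable codon positions (empty inclusion set)")
    log_sum = sum(math.log(model.weight(c, code)) for c in included)
    return math.exp(log_sum / len(included))
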