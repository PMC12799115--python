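"""Read annotated genomes and sequence files into domain records.

Coordinates are 0-based half-open internally; human-facing reports
(TSV ledgers) use 1-based numbering.  Codon index ``i`` covers
nucleotides ``[3i, 3i+3)`` of the coding strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_model import (
    BASES,
    GeneticCode,
    STANDARD_CODE,
    codons_of,
    normalize_dna,
)

EDIT_CATEGORIES = frozenset({"target", "stop", "homology_break", "terminal"})


class ParseError(ValueError):
    """A genome or sequence file could not be parsed."""


@dataclass
class CDSRecord:
    """A coding sequence on its coding strand, 5'->3'."""

    id: str
    seq: str
    product: str = ""
    source_interval: Optional[tuple[str, int, int, int]] = None  # contig, start, end, strand
    no_stop: bool = False
    issues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.seq = normalize_dna(self.seq)

    def validate(self, code: GeneticCode = STANDARD_CODE) -> None:
        if len(self.seq) % 3:
            raise ValueError(f"{self.id}: CDS length {len(self.seq)} not divisible by 3")
        bad = set(self.seq) - set(BASES)
        if bad:
            raise ValueError(f"{self.id}: ambiguous/invalid bases {sorted(bad)}")
        if not self.no_stop and not code.is_stop(self.seq[-3:]):
            raise ValueError(f"{self.id}: last codon {self.seq[-3:]} is not a stop")

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codons(self) -> list[str]:
        return codons_of(self.seq)


@dataclass
class TRNAGene:
    """A tRNA gene with its anticodon and decoding modifiers."""

    id: str
    amino_acid: str
    anticodon: str
    superwobble: bool = False
    codon_override: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        self.anticodon = normalize_dna(self.anticodon)
        if len(self.anticodon) != 3:
            raise ValueError(f"{self.id}: anticodon must be 3 nt, got {self.anticodon!r}")
        if self.codon_override is not None:
            override = frozenset(normalize_dna(c) for c in self.codon_override)
            if not override:
                raise ValueError(f"{self.id}: empty codon_override")
            for codon in override:
                if STANDARD_CODE.amino_acid(codon) != self.amino_acid:
                    raise ValueError(
                        f"{self.id}: override codon {codon} does not encode "
                        f"{self.amino_acid}")
            self.codon_override = override


@dataclass(frozen=True)
class Edit:
    codon_index: int  # 0-based
    old_codon: str
    new_codon: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in EDIT_CATEGORIES:
            raise ValueError(f"unknown edit category {self.category!r}")
        if self.old_codon == self.new_codon:
            raise ValueError(f"edit at codon {self.codon_index} changes nothing")


@dataclass
class EditLedger:
    edits: list[Edit] = field(default_factory=list)

    def __post_init__(self) -> None:
        indices = [e.codon_index for e in self.edits]
        if indices != sorted(set(indices)):
            raise ValueError("edit ledger codon indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.edits)

    def __iter__(self):
        return iter(self.edits)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("codon_index_1based\tnt_start_1based\told_codon\tnew_codon\tcategory\n")
            for e in self.edits:
                fh.write(f"{e.codon_index + 1}\t{3 * e.codon_index + 1}\t"
                         f"{e.old_codon}\t{e.new_codon}\t{e.category}\n")

    @classmethod
    def from_tsv(cls, path) -> "EditLedger":
        edits = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:1] != ["codon_index_1based"]:
                raise ParseError(f"{path}: not an edit-ledger TSV")
            for line in fh:
                if not line.strip():
                    continue
                idx1, _nt, old, new, category = line.rstrip("\n").split("\t")
                edits.append(Edit(int(idx1) - 1, old, new, category))
        return cls(edits=edits)


# ---------------------------------------------------------------------------
# genome parsing

def _feature_id(feature, default: str) -> str:
    for key in ("locus_tag", "gene", "protein_id", "product"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return default


def _anticodon_from_trna_feature(feature, record_seq) -> Optional[str]:
    """Anticodon from an explicit qualifier or a trnX-NNN gene-name suffix."""
    q = feature.qualifiers
    if "anticodon" in q:
        raw = q["anticodon"][0]
        # either a bare triplet or "(pos:..,aa:..,seq:taa)" GenBank syntax
        if "seq:" in raw:
            raw = raw.split("seq:")[1].strip(") ")
        return normalize_dna(raw)
    for key in ("gene", "locus_tag", "product"):
        for value in q.get(key, []):
            if "-" in value:
                suffix = value.rsplit("-", 1)[1]
                if len(suffix) == 3 and all(
                        b in "ACGTU" for b in suffix.upper()):
                    return normalize_dna(suffix)
    return None


_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "fMet": "M",
}


def _trna_amino_acid(feature, anticodon: str, code: GeneticCode) -> str:
    for value in feature.qualifiers.get("product", []):
        # e.g. "tRNA-Leu"
        for name, one in _AA3TO1.items():
            if value.endswith(name):
                return one
    # fall back: translate the Watson-Crick codon of the anticodon
    from .codon_model import reverse_complement
    return code.amino_acid(reverse_complement(anticodon))


def parse_genome(path, format: str = "genbank", feature_table=None,
                 code: GeneticCode = STANDARD_CODE,
                 ) -> tuple[list[CDSRecord], list[TRNAGene]]:
    """Parse an annotated genome into CDS and tRNA records.

    ``format`` is ``"genbank"`` or ``"fasta+table"``; the latter needs
    ``feature_table``, a TSV of intervals with columns
    (contig, start_0based, end, strand, type, id).

    Minus-strand and multi-exon (join) CDS features are extracted on the
    coding strand.  Per-record problems (length not divisible by 3,
    ambiguity codes, missing stop) are collected on the record's
    ``issues`` field rather than aborting the whole parse.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if format == "genbank":
        try:
            records = list(SeqIO.parse(str(path), "genbank"))
        except Exception as exc:  # biopython raises assorted ValueError subclasses
            raise ParseError(f"{path}: malformed GenBank file: {exc}") from exc
        if not records:
            raise ParseError(f"{path}: no GenBank records found")
        return _extract_features(records, code)
    if format == "fasta+table":
        if feature_table is None:
            raise ParseError("fasta+table format requires a feature_table path")
        contigs = {r.id: r for r in SeqIO.parse(str(path), "fasta")}
        if not contigs:
            raise ParseError(f"{path}: no FASTA records found")
        return _extract_from_table(contigs, feature_table, code)
    raise ParseError(f"unknown format {format!r}")


def _checked_cds(record: CDSRecord, code: GeneticCode) -> CDSRecord:
    issues = []
    if len(record.seq) % 3:
        issues.append(f"length {len(record.seq)} not divisible by 3")
    bad = set(record.seq) - set(BASES)
    if bad:
        issues.append(f"ambiguous bases {sorted(bad)}")
    if not issues and not record.no_stop and not code.is_stop(record.seq[-3:]):
        issues.append(f"last codon {record.seq[-3:]} is not a stop")
    record.issues = tuple(issues)
    return record


def _extract_features(records, code: GeneticCode):
    cds_list: list[CDSRecord] = []
    trnas: list[TRNAGene] = []
    for rec in records:
        for i, feature in enumerate(rec.features):
            if feature.type == "CDS":
                seq = str(feature.extract(rec.seq)).upper()
                start = int(feature.location.start)
                end = int(feature.location.end)
                strand = feature.location.strand or 1
                cds = CDSRecord(
                    id=_feature_id(feature, f"{rec.id}_CDS{i}"),
                    seq=seq,
                    product=feature.qualifiers.get("product", [""])[0],
                    source_interval=(rec.id, start, end, strand),
                )
                cds_list.append(_checked_cds(cds, code))
            elif feature.type == "tRNA":
                anticodon = _anticodon_from_trna_feature(feature, rec.seq)
                if anticodon is None:
                    raise ParseError(
                        f"{rec.id}: tRNA feature at {feature.location} has no "
                        f"recoverable anticodon (qualifier or trnX-NNN name)")
                aa = _trna_amino_acid(feature, anticodon, code)
                # bacterial/plastid tRNA-Ile(CAU) carries lysidine at
                # position 34 and reads ATA, not ATG
                override = frozenset({"ATA"}) if (aa == "I" and
                                                  anticodon == "CAT") else None
                trnas.append(TRNAGene(
                    id=_feature_id(feature, f"{rec.id}_tRNA{i}"),
                    amino_acid=aa,
                    anticodon=anticodon,
                    codon_override=override,
                ))
    return cds_list, trnas


def _extract_from_table(contigs, table_path, code: GeneticCode):
    cds_list: list[CDSRecord] = []
    trnas: list[TRNAGene] = []
    with open(table_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("contig\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"{table_path}:{lineno}: expected 6 columns")
            contig, start, end, strand, ftype, fid = parts
            if contig not in contigs:
                raise ParseError(f"{table_path}:{lineno}: unknown contig {contig!r}")
            start, end, strand = int(start), int(end), int(strand)
            sub = str(contigs[contig].seq[start:end]).upper()
            if strand == -1:
                sub = str(Seq(sub).reverse_complement())
            if ftype == "CDS":
                cds = CDSRecord(id=fid, seq=sub,
                                source_interval=(contig, start, end, strand))
                cds_list.append(_checked_cds(cds, code))
            elif ftype == "tRNA":
                suffix = fid.rsplit("-", 1)[-1]
                trnas.append(TRNAGene(
                    id=fid,
                    amino_acid=code.amino_acid(
                        str(Seq(normalize_dna(suffix)).reverse_complement())),
                    anticodon=suffix,
                ))
    return cds_list, trnas


# ---------------------------------------------------------------------------
# writing

def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write (id, seq) pairs as FASTA wrapped at ``width`` columns."""
    seqrecords = [SeqRecord(Seq(seq), id=name, description="")
                  for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_recoding_report(result, out_prefix) -> dict:
    """Write recoded FASTA, TSV edit ledger, and JSON summary.

    ``out_prefix`` may be a directory (files named after the CDS id) or a
    path prefix.  Returns the summary dict.
    """
    out_prefix = Path(out_prefix)
    if out_prefix.is_dir():
        out_prefix = out_prefix / result.original.id
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    write_fasta([(result.original.id + "_recoded", result.recoded)],
                out_prefix.with_suffix(".recoded.fasta"))
    result.ledger.to_tsv(out_prefix.with_suffix(".edits.tsv"))
    summary = {
        "cds_id": result.original.id,
        "length_nt": len(result.recoded),
        "codons_changed": result.stats["codons_changed"],
        "bases_changed": result.stats["bases_changed"],
        "base_fraction": result.stats["base_fraction"],
        "edit_categories": {
            cat: sum(1 for e in result.ledger if e.category == cat)
            for cat in sorted({e.category for e in result.ledger})
        },
    }
    with open(out_prefix.with_suffix(".summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    return summary


# ---------------------------------------------------------------------------
# tRNA roster config (YAML)

def load_roster(path) -> list[TRNAGene]:
    """Load a tRNA roster from YAML: a list of {id, aa, anticodon, ...}."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    roster = []
    for entry in entries:
        roster.append(TRNAGene(
            id=entry["id"],
            amino_acid=entry["aa"],
            anticodon=entry["anticodon"],
            superwobble=bool(entry.get("superwobble", False)),
            codon_override=(frozenset(entry["codon_override"])
                            if entry.get("codon_override") else None),
        ))
    return roster


def dump_roster(roster: Sequence[TRNAGene], path) -> None:
    entries = []
    for t in roster:
        entry = {"id": t.id, "aa": t.amino_acid, "anticodon": t.anticodon}
        if t.superwobble:
            entry["superwobble"] = True
        if t.codon_override:
            entry["codon_override"] = sorted(t.codon_override)
        entries.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
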