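"""Derive and validate genetic-code compression schemes.

A compression scheme eliminates, for each amino acid served by two
isoacceptor tRNAs (Leu, Ile, Ser, Arg, Gly in the plastid roster), the
entire codon box of the less-used tRNA, mapping every eliminated codon
to the most frequent codon of the retained box.  All stop codons except
one canonical stop are eliminated as well.  On the plastome this yields
the 51-codon code: 11 sense codons plus the amber (TAG) and opal (TGA)
stops go, 51 codons remain, and the five tRNAs reading only eliminated
boxes become deletable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .codon_model import (
    CODONS,
    CodonBox,
    GeneticCode,
    STANDARD_CODE,
    UsageTable,
    normalize_dna,
)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def expand_degenerate(codon: str) -> frozenset[str]:
    """Expand an IUPAC 3-mer (e.g. CGN) to its concrete codon set."""
    codon = normalize_dna(codon)
    if len(codon) != 3 or any(b not in _IUPAC for b in codon):
        raise ValueError(f"invalid degenerate codon {codon!r}")
    return frozenset(a + b + c
                     for a in _IUPAC[codon[0]]
                     for b in _IUPAC[codon[1]]
                     for c in _IUPAC[codon[2]])


class SchemeError(ValueError):
    """A compression scheme cannot be derived or is inconsistent."""


@dataclass
class CompressionScheme:
    """Eliminated codons, their replacements, and the retained alphabet."""

    eliminated_sense: frozenset[str]
    eliminated_stops: frozenset[str]
    replacement: dict[str, str]
    stop_replacement: dict[str, str]
    permitted: dict[str, frozenset[str]]
    name: str = "compression"

    def validate(self, code: GeneticCode = STANDARD_CODE) -> None:
        for old, new in self.replacement.items():
            if code.amino_acid(old) != code.amino_acid(new):
                raise SchemeError(f"replacement {old}->{new} changes the amino acid")
            if new in self.eliminated_sense:
                raise SchemeError(f"replacement target {new} is itself eliminated")
        for old, new in self.stop_replacement.items():
            if not (code.is_stop(old) and code.is_stop(new)):
                raise SchemeError(f"stop replacement {old}->{new} involves a sense codon")
            if new in self.eliminated_stops:
                raise SchemeError(f"stop replacement target {new} is eliminated")
        if set(self.replacement) != set(self.eliminated_sense):
            raise SchemeError("replacement map must cover exactly the eliminated sense codons")
        if set(self.stop_replacement) != set(self.eliminated_stops):
            raise SchemeError("stop_replacement must cover exactly the eliminated stops")
        for aa, codons in self.permitted.items():
            if codons & self.eliminated_sense:
                raise SchemeError(f"permitted set for {aa} overlaps eliminated codons")
            for c in codons:
                if code.amino_acid(c) != aa:
                    raise SchemeError(f"permitted codon {c} does not encode {aa}")
        if len(self.eliminated_sense) + len(self.eliminated_stops) + self.retained_count != 64:
            raise SchemeError("eliminated + retained must partition the 64 codons")

    @property
    def eliminated(self) -> frozenset[str]:
        return self.eliminated_sense | self.eliminated_stops

    @property
    def retained_count(self) -> int:
        return 64 - len(self.eliminated_sense) - len(self.eliminated_stops)

    @property
    def retained_stops(self) -> frozenset[str]:
        return frozenset(STANDARD_CODE.stops) - self.eliminated_stops

    def is_eliminated(self, codon: str) -> bool:
        return normalize_dna(codon) in self.eliminated

    def to_json(self, path=None) -> str:
        payload = {
            "name": self.name,
            "eliminated_sense": sorted(self.eliminated_sense),
            "eliminated_stops": sorted(self.eliminated_stops),
            "replacement": dict(sorted(self.replacement.items())),
            "stop_replacement": dict(sorted(self.stop_replacement.items())),
            "permitted": {aa: sorted(c) for aa, c in sorted(self.permitted.items())},
        }
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CompressionScheme":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            eliminated_sense=frozenset(payload["eliminated_sense"]),
            eliminated_stops=frozenset(payload["eliminated_stops"]),
            replacement=dict(payload["replacement"]),
            stop_replacement=dict(payload["stop_replacement"]),
            permitted={aa: frozenset(c) for aa, c in payload["permitted"].items()},
            name=payload.get("name", "compression"),
        )


def _argmax_codon(retained: Iterable[str], usage: UsageTable) -> str:
    """Most frequent codon; ties broken by alphabetical order (first wins)."""
    return min(sorted(retained), key=lambda c: (-usage.count(c), c))


def derive_defined_scheme(usage: UsageTable,
                          boxes: Mapping[str, list[CodonBox]],
                          canonical_stop: str = "TAA",
                          code: GeneticCode = STANDARD_CODE,
                          name: str = "defined-compression",
                          overrides: Optional[Mapping[str, object]] = None,
                          ) -> CompressionScheme:
    """Derive the defined compression scheme from usage and box structure.

    For every dual-box amino acid the box with lower summed usage is
    eliminated and each of its codons maps to the single most frequent
    codon of the retained box.  ``overrides`` (amino acid -> box to
    eliminate, as an IUPAC 3-mer like ``"CGN"`` or an explicit codon set)
    forces the choice regardless of usage, enabling e.g. the 46-codon
    extension that eliminates Arg CGN, Ile ATY and Ser TCN.

    All stops except ``canonical_stop`` are eliminated and mapped to it —
    including stops with zero usage, so the eliminated set is a property
    of the scheme, not of the data.

    Tie-breaks (equal box usage): eliminate the box with fewer codons,
    then the lexicographically smaller codon set.
    """
    canonical_stop = normalize_dna(canonical_stop)
    if canonical_stop not in code.stops:
        raise SchemeError(f"canonical stop {canonical_stop} is not a stop codon")
    overrides = {aa: spec for aa, spec in (overrides or {}).items()}

    eliminated_sense: set[str] = set()
    replacement: dict[str, str] = {}
    permitted: dict[str, frozenset[str]] = {}

    for aa in sorted({c for c in boxes}):
        aa_boxes = boxes[aa]
        if len(aa_boxes) != 2:
            if aa in overrides:
                raise SchemeError(f"override given for non-dual amino acid {aa}")
            permitted[aa] = frozenset().union(*(b.codons for b in aa_boxes))
            continue
        if aa in overrides:
            spec = overrides[aa]
            target = (expand_degenerate(spec) if isinstance(spec, str)
                      else frozenset(normalize_dna(c) for c in spec))
            matches = [b for b in aa_boxes if b.codons == target]
            if not matches:
                raise SchemeError(
                    f"override for {aa} ({sorted(target)}) matches neither box: "
                    f"{[sorted(b.codons) for b in aa_boxes]}")
            loser = matches[0]
        else:
            usages = [usage.box_usage(b.codons) for b in aa_boxes]
            if sum(usages) == 0:
                raise SchemeError(f"dual amino acid {aa} has no usage data")
            def sort_key(b: CodonBox):
                return (usage.box_usage(b.codons), len(b.codons),
                        tuple(sorted(b.codons)))
            loser = min(aa_boxes, key=sort_key)
        winner = next(b for b in aa_boxes if b is not loser)
        best = _argmax_codon(winner.codons, usage)
        for codon in sorted(loser.codons):
            eliminated_sense.add(codon)
            replacement[codon] = best
        permitted[aa] = frozenset(winner.codons)

    # amino acids with no tRNA boxes supplied keep their full family
    for codon in CODONS:
        aa = code.amino_acid(codon)
        if aa == "*" or aa in permitted:
            continue
        permitted[aa] = code.synonymous_family(aa)

    eliminated_stops = frozenset(code.stops) - {canonical_stop}
    scheme = CompressionScheme(
        eliminated_sense=frozenset(eliminated_sense),
        eliminated_stops=eliminated_stops,
        replacement=replacement,
        stop_replacement={s: canonical_stop for s in eliminated_stops},
        permitted=permitted,
        name=name,
    )
    scheme.validate(code)
    return scheme


def apply_box_overrides(usage: UsageTable,
                        boxes: Mapping[str, list[CodonBox]],
                        overrides: Mapping[str, object],
                        canonical_stop: str = "TAA",
                        code: GeneticCode = STANDARD_CODE,
                        name: str = "override-compression") -> CompressionScheme:
    """Derive a scheme forcing named boxes out regardless of usage."""
    return derive_defined_scheme(usage, boxes, canonical_stop=canonical_stop,
                                 code=code, name=name, overrides=overrides)


def deletable_trnas(scheme: CompressionScheme,
                    boxes: Mapping[str, list[CodonBox]]) -> list[str]:
    """tRNA ids whose entire codon box is eliminated by the scheme.

    Deletability is judged on the box partition (post superwobble
    precedence): a superwobbling tRNA whose residual box is eliminated is
    redundant even though its raw decoding overlaps retained codons.
    """
    ids = []
    for aa_boxes in boxes.values():
        for box in aa_boxes:
            if box.codons and box.codons <= scheme.eliminated_sense:
                ids.append(box.trna_id)
    return sorted(ids)


@dataclass
class SchemeSummary:
    n_modified: int
    fraction_modified: float
    retained_count: int
    deletable_trna_ids: list[str] = field(default_factory=list)


def scheme_summary(scheme: CompressionScheme, usage: UsageTable,
                   boxes: Optional[Mapping[str, list[CodonBox]]] = None,
                   ) -> SchemeSummary:
    """Count how many codons of a CDS set the scheme would modify.

    ``usage`` must include stop codons if eliminated-stop occurrences are
    to be counted (the plastome's four amber stops count toward the
    published 2,136 target codons).
    """
    n_modified = sum(usage.count(c) for c in scheme.eliminated)
    total = usage.total
    return SchemeSummary(
        n_modified=n_modified,
        fraction_modified=n_modified / total if total else 0.0,
        retained_count=scheme.retained_count,
        deletable_trna_ids=deletable_trnas(scheme, boxes) if boxes else [],
    )
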