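"""Combinatorial randomization of compression targets.

Instead of replacing each target codon with one defined codon, every
target position may take any codon from its amino acid's retained
(permitted) set, producing a library of synonymous variants.  With the
51-codon plastid scheme the permitted sets are Leu TTR (2), Ile ATY (2),
Ser TCN (4), Arg CGN (4) and Gly GGY (2); a gene with 22 Leu + 2 Ser +
1 Arg + 1 Gly targets therefore spans 2^22 * 4^2 * 4 * 2 = 536,870,912
variants.  Positions are encoded as IUPAC degenerate codons for
degenerate-oligo synthesis, and sampled variants can be scored by
target-restricted CAI and frequent:rare codon ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from typing import Iterator, Optional, Sequence

import numpy as np

from .codon_model import (
    CAIModel,
    GeneticCode,
    STANDARD_CODE,
    cai_score,
    classify_codon_frequency_class,
    codons_of,
    normalize_dna,
)
from .genome_io import CDSRecord
from .scheme import CompressionScheme, _IUPAC


class LibraryError(ValueError):
    pass


_IUPAC_REVERSE = {frozenset(bases): letter for letter, bases in _IUPAC.items()}


def degenerate_codon(codon_set) -> str:
    """Minimal IUPAC 3-mer expanding to exactly the given codon set.

    The set must be "rectangular": the cartesian product of its
    per-position base sets (e.g. {TTA,TTG} -> TTR, TCN for the four
    serine codons).  Non-rectangular sets like {TTA, TCG} admit no exact
    positionwise code and raise :class:`LibraryError`.
    """
    codons = sorted(normalize_dna(c) for c in codon_set)
    if not codons or any(len(c) != 3 for c in codons):
        raise LibraryError(f"invalid codon set {codon_set!r}")
    per_pos = [frozenset(c[i] for c in codons) for i in range(3)]
    if len(per_pos[0]) * len(per_pos[1]) * len(per_pos[2]) != len(set(codons)):
        raise LibraryError(
            f"codon set {codons} is not a positionwise (rectangular) product; "
            f"no exact degenerate codon exists")
    return "".join(_IUPAC_REVERSE[s] for s in per_pos)


@dataclass
class LibraryDesign:
    """Randomized target positions with their permitted codon sets."""

    cds_id: str
    positions: list[int]                       # codon indices, ascending
    permitted_per_position: list[tuple[str, ...]]
    degenerate_per_position: list[Optional[str]]
    size: int

    def validate(self, scheme: Optional[CompressionScheme] = None,
                 code: GeneticCode = STANDARD_CODE) -> None:
        if not (len(self.positions) == len(self.permitted_per_position)
                == len(self.degenerate_per_position)):
            raise LibraryError("per-position lists must have equal length")
        if self.positions != sorted(set(self.positions)):
            raise LibraryError("positions must be strictly increasing")
        expected = 1
        for perm in self.permitted_per_position:
            expected *= len(perm)
            aas = {code.amino_acid(c) for c in perm}
            if len(aas) != 1:
                raise LibraryError(f"permitted set {perm} is not synonymous")
        if expected != self.size:
            raise LibraryError(f"size {self.size} != product of set sizes {expected}")
        if scheme is not None:
            for perm in self.permitted_per_position:
                aa = code.amino_acid(perm[0])
                extra = set(perm) - set(scheme.permitted[aa]) - set(scheme.replacement)
                if extra:
                    raise LibraryError(
                        f"permitted set {perm} contains codons outside the "
                        f"scheme for {aa}: {sorted(extra)}")

    def to_json(self, path=None) -> str:
        payload = {
            "cds_id": self.cds_id,
            "positions": self.positions,
            "permitted_per_position": [list(p) for p in self.permitted_per_position],
            "degenerate_per_position": self.degenerate_per_position,
            "size": self.size,
        }
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LibraryDesign":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            cds_id=payload["cds_id"],
            positions=list(payload["positions"]),
            permitted_per_position=[tuple(p) for p in payload["permitted_per_position"]],
            degenerate_per_position=list(payload["degenerate_per_position"]),
            size=int(payload["size"]),
        )


def design_combinatorial_library(cds: CDSRecord, scheme: CompressionScheme,
                                 include_native: bool = False,
                                 code: GeneticCode = STANDARD_CODE,
                                 ) -> LibraryDesign:
    """Design a combinatorial library over a CDS's target codons.

    Target positions are codons in the scheme's eliminated sense set;
    each may take any codon of the amino acid's retained permitted set.
    With ``include_native`` the eliminated wild-type codon is kept as an
    additional option (useful for troubleshooting genes that fail to
    recode); note the augmented set may then have no exact degenerate
    encoding, recorded as ``None``.

    ``size`` is an exact arbitrary-precision integer.
    """
    cds.validate(code)
    positions: list[int] = []
    permitted: list[tuple[str, ...]] = []
    degenerate: list[Optional[str]] = []
    size = 1
    for i, codon in enumerate(cds.codons()):
        if codon not in scheme.eliminated_sense:
            continue
        aa = code.amino_acid(codon)
        options = set(scheme.permitted[aa])
        if include_native:
            options.add(codon)
        options_t = tuple(sorted(options))
        positions.append(i)
        permitted.append(options_t)
        try:
            degenerate.append(degenerate_codon(options_t))
        except LibraryError:
            degenerate.append(None)
        size *= len(options_t)
    design = LibraryDesign(cds_id=cds.id, positions=positions,
                           permitted_per_position=permitted,
                           degenerate_per_position=degenerate, size=size)
    design.validate(scheme, code)
    return design


def degenerate_sequence(design: LibraryDesign, base_cds: CDSRecord) -> str:
    """The base CDS with design positions replaced by IUPAC codons."""
    codons = base_cds.codons()
    for pos, deg in zip(design.positions, design.degenerate_per_position):
        if deg is None:
            raise LibraryError(
                f"position {pos} has no exact degenerate codon; "
                f"emit the permitted set explicitly instead")
        codons[pos] = deg
    return "".join(codons)


def _build_variant(codons: list[str], design: LibraryDesign,
                   choice: Sequence[str]) -> str:
    out = list(codons)
    for pos, codon in zip(design.positions, choice):
        out[pos] = codon
    return "".join(out)


def enumerate_variants(design: LibraryDesign, base_cds: CDSRecord) -> Iterator[str]:
    """Yield every variant sequence (use only for small designs)."""
    codons = base_cds.codons()
    for choice in product(*design.permitted_per_position):
        yield _build_variant(codons, design, choice)


def sample_variants(design: LibraryDesign, base_cds: CDSRecord, k: int,
                    seed: int) -> list[str]:
    """Draw ``k`` variants uniformly over codon choices, with replacement.

    Uniform-per-codon matches degenerate-oligo synthesis of rectangular
    sets; the draw is deterministic under ``seed``.
    """
    if k < 1:
        raise LibraryError("k must be >= 1")
    rng = np.random.default_rng(seed)
    codons = base_cds.codons()
    variants = []
    for _ in range(k):
        choice = [perm[rng.integers(len(perm))]
                  for perm in design.permitted_per_position]
        variants.append(_build_variant(codons, design, choice))
    return variants


def variant_target_metrics(variant: str, design: LibraryDesign,
                           cai_model: CAIModel,
                           code: GeneticCode = STANDARD_CODE) -> dict:
    """Target-restricted CAI and frequent/rare counts for one variant.

    A codon at a design position outside its permitted set is an error —
    it flags non-synonymous contamination of the variant.
    """
    codons = codons_of(variant)
    n_frequent = 0
    for pos, perm in zip(design.positions, design.permitted_per_position):
        codon = codons[pos]
        if codon not in perm:
            raise LibraryError(
                f"codon {codon} at position {pos} is outside the permitted "
                f"set {perm}")
        if classify_codon_frequency_class(codon) == "frequent":
            n_frequent += 1
    target_cai = cai_score(codons, cai_model, positions=design.positions,
                           code=code)
    return {
        "target_cai": target_cai,
        "n_frequent": n_frequent,
        "n_rare": len(design.positions) - n_frequent,
    }
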