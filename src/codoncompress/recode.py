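"""Apply a compression scheme to a CDS and manage identity side-constraints.

Synonymous recoding leaves long stretches of the gene identical to the
wild type.  Because the polyploid chloroplast genome recombines
efficiently between identical sequences down to roughly 200 bp, such
runs can act as internal homology arms and regenerate chimeric
WT/recoded alleles.  ``break_homology_runs`` inserts extra synonymous
edits until every identity run is below a configurable threshold, and
``diversify_termini`` adds edits near the ends of a CDS where flanking
untouched UTRs would otherwise extend the identical region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .codon_model import GeneticCode, STANDARD_CODE, UsageTable, codons_of
from .genome_io import CDSRecord, Edit, EditLedger
from .scheme import CompressionScheme


class RecodingError(ValueError):
    pass


@dataclass
class HomologyRun:
    """Maximal run of positionwise identity between two equal-length strings."""

    start: int  # nt offset, 0-based
    end: int    # half-open

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RecodingResult:
    original: CDSRecord
    recoded: str
    ledger: EditLedger
    stats: dict = field(default_factory=dict)

    def validate(self, scheme: Optional[CompressionScheme] = None,
                 code: GeneticCode = STANDARD_CODE) -> None:
        if len(self.recoded) != len(self.original.seq):
            raise RecodingError("recoded length differs from original")
        wt_protein = code.translate(self.original.seq)
        new_protein = code.translate(self.recoded)
        if wt_protein != new_protein:
            raise RecodingError("recoding changed the protein sequence")
        if scheme is not None:
            for codon in codons_of(self.recoded):
                if scheme.is_eliminated(codon):
                    raise RecodingError(f"eliminated codon {codon} survives recoding")
        expected = diff_stats(self.original.seq, self.recoded)
        if expected != self.stats:
            raise RecodingError("stats disagree with a direct diff")


def diff_stats(wt: str, variant: str) -> dict:
    """Codon- and base-level differences between two equal-length CDSs."""
    if len(wt) != len(variant):
        raise RecodingError("sequences differ in length")
    if len(wt) % 3:
        raise RecodingError("length not divisible by 3")
    bases_changed = sum(1 for a, b in zip(wt, variant) if a != b)
    codons_changed = sum(1 for a, b in zip(codons_of(wt), codons_of(variant))
                         if a != b)
    return {
        "codons_changed": codons_changed,
        "bases_changed": bases_changed,
        "base_fraction": bases_changed / len(wt) if wt else 0.0,
    }


def recode_cds(cds: CDSRecord, scheme: CompressionScheme,
               code: GeneticCode = STANDARD_CODE) -> RecodingResult:
    """Replace every eliminated codon by its scheme replacement.

    Eliminated sense codons take their ``replacement`` (category
    ``target``); eliminated stops take ``stop_replacement`` (category
    ``stop``); everything else is untouched.
    """
    cds.validate(code)
    out = []
    edits = []
    for i, codon in enumerate(cds.codons()):
        if codon in scheme.replacement:
            new = scheme.replacement[codon]
            edits.append(Edit(i, codon, new, "target"))
        elif codon in scheme.stop_replacement:
            new = scheme.stop_replacement[codon]
            edits.append(Edit(i, codon, new, "stop"))
        else:
            new = codon
        out.append(new)
    recoded = "".join(out)
    result = RecodingResult(original=cds, recoded=recoded,
                            ledger=EditLedger(edits),
                            stats=diff_stats(cds.seq, recoded))
    result.validate(scheme, code)
    return result


def find_identity_runs(a: str, b: str) -> list[HomologyRun]:
    """Maximal runs of positionwise identity between equal-length strings."""
    if len(a) != len(b):
        raise RecodingError("sequences differ in length")
    runs = []
    start = None
    for i, (x, y) in enumerate(zip(a, b)):
        if x == y:
            if start is None:
                start = i
        elif start is not None:
            runs.append(HomologyRun(start, i))
            start = None
    if start is not None:
        runs.append(HomologyRun(start, len(a)))
    return runs


def _merge_ledger(ledger: EditLedger, edit: Edit) -> EditLedger:
    edits = sorted(ledger.edits + [edit], key=lambda e: e.codon_index)
    return EditLedger(edits)


def _swap_codon(seq: str, index: int, new: str) -> str:
    return seq[: 3 * index] + new + seq[3 * index + 3 :]


def _synonym_candidates(codon: str, scheme: CompressionScheme,
                        code: GeneticCode) -> list[str]:
    aa = code.amino_acid(codon)
    if aa == "*":
        return []
    return sorted(c for c in scheme.permitted.get(aa, ()) if c != codon)


def break_homology_runs(result: RecodingResult, scheme: CompressionScheme,
                        usage: UsageTable, max_run_bp: int = 200,
                        code: GeneticCode = STANDARD_CODE) -> RecodingResult:
    """Add synonymous edits until all WT-identity runs are < ``max_run_bp``.

    Candidates are codon positions fully inside an offending run whose
    amino acid has at least two permitted synonyms; the start codon and
    the stop are never touched.  The chosen position maximizes the usage
    gain of the swap (rare -> frequent preferred, mirroring a Lys
    AAG -> AAA style fix), then proximity to the run midpoint (splitting
    the run most efficiently), then the lowest index; the codon is
    swapped to the highest-usage permitted synonym that differs from it.
    """
    if max_run_bp < 3:
        raise RecodingError("max_run_bp must be >= 3")
    recoded = result.recoded
    ledger = result.ledger
    wt = result.original.seq
    n_codons = len(wt) // 3

    while True:
        offending = [r for r in find_identity_runs(wt, recoded)
                     if r.length >= max_run_bp]
        if not offending:
            break
        run = offending[0]
        first_codon = -(-run.start // 3)          # first codon fully inside
        last_codon = run.end // 3                  # one past last fully inside
        candidates = []
        mid = (run.start + run.end) / 2
        for i in range(first_codon, last_codon):
            if i == 0 or i == n_codons - 1:
                continue  # never edit start or stop codons here
            codon = recoded[3 * i : 3 * i + 3]
            synonyms = _synonym_candidates(codon, scheme, code)
            if not synonyms:
                continue
            best = min(synonyms, key=lambda c: (-usage.count(c), c))
            gain = usage.count(best) - usage.count(codon)
            center = 3 * i + 1.5
            candidates.append((-gain, abs(center - mid), i, best))
        if not candidates:
            raise RecodingError(
                f"identity run [{run.start}, {run.end}) of {run.length} bp "
                f"has no synonymous codon available to break it")
        _, _, index, new = min(candidates)
        old = recoded[3 * index : 3 * index + 3]
        recoded = _swap_codon(recoded, index, new)
        ledger = _merge_ledger(ledger, Edit(index, old, new, "homology_break"))

    out = RecodingResult(original=result.original, recoded=recoded,
                         ledger=ledger, stats=diff_stats(wt, recoded))
    out.validate(scheme, code)
    return out


def diversify_termini(result: RecodingResult, scheme: CompressionScheme,
                      usage: UsageTable, n_codons: int,
                      ends: str = "both",
                      code: GeneticCode = STANDARD_CODE) -> RecodingResult:
    """Add synonymous edits within the first/last ``n_codons`` of the CDS.

    Untouched flanking UTRs extend WT identity into the gene body; edits
    near the termini shorten those runs.  Each still-unedited codon in
    the window (excluding the start and stop codons) whose amino acid has
    a permitted synonym is swapped to the highest-usage synonym differing
    from it.  Codons already altered (target or homology edits) are left
    alone — they no longer match the wild type.
    """
    if n_codons < 0:
        raise RecodingError("n_codons must be >= 0")
    if ends not in {"left", "right", "both"}:
        raise RecodingError(f"ends must be left|right|both, got {ends!r}")
    recoded = result.recoded
    ledger = result.ledger
    wt = result.original.seq
    total = len(wt) // 3

    window: set[int] = set()
    if ends in {"left", "both"}:
        window |= set(range(1, min(1 + n_codons, total - 1)))
    if ends in {"right", "both"}:
        window |= set(range(max(1, total - 1 - n_codons), total - 1))
    for i in sorted(window):
        codon = recoded[3 * i : 3 * i + 3]
        if codon != wt[3 * i : 3 * i + 3]:
            continue  # already diverged from WT
        synonyms = _synonym_candidates(codon, scheme, code)
        if not synonyms:
            continue
        new = min(synonyms, key=lambda c: (-usage.count(c), c))
        recoded = _swap_codon(recoded, i, new)
        ledger = _merge_ledger(ledger, Edit(i, codon, new, "terminal"))

    out = RecodingResult(original=result.original, recoded=recoded,
                         ledger=ledger, stats=diff_stats(wt, recoded))
    out.validate(scheme, code)
    return out
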