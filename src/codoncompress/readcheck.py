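"""Verify recoding from sequencing reads.

After replacing a locus with its recoded allele, amplicon sequencing is
used to confirm that every target position carries the recoded base and
the wild-type base is absent (beyond sequencing error).  Matching is
alignment-free: each differing site gets a pair of exact "signatures" —
the site base plus ``anchor_k`` flanking bases shared by both references
— and reads are classified by which signature they contain.  Amplicons
are short and edits dense, so exact substring matching resolves sites
without read mapping; a SAM/pileup ingestion path would be a natural
extension but is not core.

Also provides locus-independent primer-window discovery (stretches
conserved between WT and recoded alleles) and a substitution-error read
simulator used as the module's test bed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codon_model import reverse_complement
from .recode import find_identity_runs


class ReadCheckError(ValueError):
    pass


def find_conserved_windows(wt: str, recoded: str, window_len: int
                           ) -> list[tuple[int, int]]:
    """Identity runs of length >= ``window_len`` (candidate primer sites).

    Primers placed in these windows anneal to both alleles, so the assay
    cannot preferentially amplify one — the quantification is
    locus-independent.
    """
    return [(r.start, r.end) for r in find_identity_runs(wt, recoded)
            if r.length >= window_len]


def differing_sites(wt: str, recoded: str) -> list[int]:
    """Nucleotide offsets where the two alleles differ."""
    if len(wt) != len(recoded):
        raise ReadCheckError("alleles differ in length")
    return [i for i, (a, b) in enumerate(zip(wt, recoded)) if a != b]


def simulate_reads(template_a: str, template_b: str, mixture_p: float,
                   error_rate: float, n_reads: int, read_len: int,
                   seed: int) -> list[str]:
    """Simulate substitution-error reads from a two-allele mixture.

    Each read picks template A with probability ``mixture_p``, a uniform
    start, copies ``read_len`` bases, substitutes each base with
    probability ``error_rate`` to a uniform different base, and is
    reverse-complemented with probability 1/2.  Deterministic under
    ``seed``.
    """
    if not 0 <= mixture_p <= 1:
        raise ReadCheckError("mixture_p must be in [0, 1]")
    if not 0 <= error_rate < 0.25:
        raise ReadCheckError("error_rate must be in [0, 0.25)")
    if read_len > min(len(template_a), len(template_b)):
        raise ReadCheckError("read_len exceeds template length")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    reads = []
    for _ in range(n_reads):
        template = template_a if rng.random() < mixture_p else template_b
        start = int(rng.integers(len(template) - read_len + 1))
        read = list(template[start : start + read_len])
        errs = np.flatnonzero(rng.random(read_len) < error_rate)
        for i in errs:
            alternatives = [b for b in bases if b != read[i]]
            read[i] = alternatives[rng.integers(3)]
        seq = "".join(read)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append(seq)
    return reads


@dataclass
class TargetSiteCall:
    """Per-site recoded/WT base counts and frequencies over resolved reads."""

    site: int                 # nt offset, 0-based, WT coordinates
    wt_base: str
    recoded_base: str
    counts: dict = field(default_factory=dict)
    freq_recoded: float = 0.0
    freq_wt: float = 0.0
    flank_used: int = 0       # symmetric flank length actually used

    @property
    def n_resolved(self) -> int:
        return self.counts["recoded"] + self.counts["wt"] + self.counts["other"]

    @property
    def freq_other(self) -> float:
        n = self.n_resolved
        return self.counts["other"] / n if n else 0.0


@dataclass
class _SiteSignatures:
    wt_sig: str
    rec_sig: str
    other_sigs: list[str]
    flanks: list[str]        # k-mers flanking the site, for overlap evidence
    flank_used: int


def _site_signatures(wt_ref: str, recoded_ref: str, site: int, anchor_k: int
                     ) -> Optional[_SiteSignatures]:
    """Exact-match signatures for one differing site.

    The WT and recoded class signatures are the site base plus
    ``anchor_k`` flanking bases taken from the *respective* reference
    (clipped at sequence ends), so neighbouring edits inside the window
    are part of the signature rather than a reason to shrink it — a
    signature shorter than the anchor would start matching spuriously.
    "Other" signatures substitute the two bases that are neither the WT
    nor the recoded base into both contexts, measuring per-base
    sequencing error at the site.  Returns None when the site has no
    flanking sequence at all (degenerate single-base references).
    """
    lo = max(0, site - anchor_k)
    hi = min(len(wt_ref), site + anchor_k + 1)
    if hi - lo < 2:
        return None
    wt_sig = wt_ref[lo:hi]
    rec_sig = recoded_ref[lo:hi]
    center = site - lo
    wt_base, rec_base = wt_ref[site], recoded_ref[site]
    third = [b for b in "ACGT" if b not in (wt_base, rec_base)]
    other_sigs = []
    for context in (rec_sig, wt_sig):
        for b in third:
            sig = context[:center] + b + context[center + 1 :]
            if sig not in other_sigs:
                other_sigs.append(sig)
    flanks = []
    for context in (wt_sig, rec_sig):
        left, right = context[:center], context[center + 1 :]
        for f in (left, right):
            if len(f) >= min(anchor_k, 5) and f not in flanks:
                flanks.append(f)
    return _SiteSignatures(wt_sig=wt_sig, rec_sig=rec_sig,
                           other_sigs=other_sigs, flanks=flanks,
                           flank_used=min(center, hi - site - 1))


def classify_target_sites(reads: Sequence[str], wt_ref: str, recoded_ref: str,
                          sites: Optional[Sequence[int]] = None,
                          anchor_k: int = 10) -> list[TargetSiteCall]:
    """Count recoded/WT/other bases at each differing site across reads.

    A read (in either orientation) containing exactly one of the site's
    signatures increments that class; a flank match with a third base at
    the site counts as ``other``; a read matching one flank but no full
    signature is ``unresolved``.  Frequencies are over resolved reads.
    Sites whose flanks cannot be made identical at any length are
    skipped.
    """
    if anchor_k < 5:
        raise ReadCheckError("anchor_k must be >= 5")
    if sites is None:
        sites = differing_sites(wt_ref, recoded_ref)
    calls = []
    oriented = [(r, reverse_complement(r)) for r in reads]
    for site in sites:
        if wt_ref[site] == recoded_ref[site]:
            raise ReadCheckError(f"site {site}: references agree, not a target site")
        sig = _site_signatures(wt_ref, recoded_ref, site, anchor_k)
        if sig is None:
            continue  # no flanking sequence at all; site skipped
        counts = {"recoded": 0, "wt": 0, "other": 0, "unresolved": 0}
        for fwd, rev in oriented:
            for read in (fwd, rev):
                if sig.rec_sig in read:
                    counts["recoded"] += 1
                elif sig.wt_sig in read:
                    counts["wt"] += 1
                elif any(s in read for s in sig.other_sigs):
                    counts["other"] += 1
                elif any(f in read for f in sig.flanks):
                    counts["unresolved"] += 1
                else:
                    continue
                break  # classified in this orientation; don't double count
        n_resolved = counts["recoded"] + counts["wt"] + counts["other"]
        calls.append(TargetSiteCall(
            site=site,
            wt_base=wt_ref[site],
            recoded_base=recoded_ref[site],
            counts=counts,
            freq_recoded=counts["recoded"] / n_resolved if n_resolved else 0.0,
            freq_wt=counts["wt"] / n_resolved if n_resolved else 0.0,
            flank_used=sig.flank_used,
        ))
    return calls


def write_site_table(calls: Sequence[TargetSiteCall], path) -> None:
    """Per-site TSV (1-based positions in the human-facing output)."""
    with open(path, "w") as fh:
        fh.write("site_1based\twt_base\trecoded_base\tn_recoded\tn_wt\t"
                 "n_other\tn_unresolved\tfreq_recoded\tfreq_wt\n")
        for c in calls:
            fh.write(f"{c.site + 1}\t{c.wt_base}\t{c.recoded_base}\t"
                     f"{c.counts['recoded']}\t{c.counts['wt']}\t"
                     f"{c.counts['other']}\t{c.counts['unresolved']}\t"
                     f"{c.freq_recoded:.6f}\t{c.freq_wt:.6f}\n")
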