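# Methods

## The compression model

A plastid-style translation system reads the 64-codon table with a small
tRNA roster. We model each tRNA's decoding capacity from its anticodon:
the codon's first two bases are the Watson–Crick complement of anticodon
bases 2–3, and the third codon base is set by the wobble class of the
anticodon's 5′ base (position 34):

| anticodon base 34 | third codon bases read |
|---|---|
| G | C, T |
| C | G |
| U (unmodified, superwobble) | A, C, G, T |
| U (restricted) | A, G |
| A | T |

Superwobble is an explicit per-tRNA flag because whether a U34 tRNA
reads two or four codons depends on base modification state, which no
annotation format records. Chemically modified anticodons that escape
this table entirely — lysidine-modified tRNA-Ile(CAU) reading ATA,
inosine-34 tRNA-Arg(ACG) reading CGN — are expressed as explicit
`codon_override` sets; the override mechanism is the roster's escape
hatch for any modified-base chemistry. When a genome is parsed without a
curated roster, the lysidine Ile(CAU) case is applied automatically
(otherwise the anticodon would decode ATG, a different amino acid);
superwobble flags cannot be inferred from annotation and must come from
a roster config.

Decoded codon sets are partitioned into **isoacceptor boxes** per amino
acid. Duplicated genes (identical anticodon and modifiers, e.g.
inverted-repeat copies or the initiator/elongator Met pair) merge into
one box. One overlap case arises in real rosters: a superwobbling
4-codon box (Gly GGN via trnG-UCC) overlapping a 2-codon wobble box
(GGY via trnG-GCC). The overlap is assigned to the non-superwobble tRNA
and the superwobble box keeps the remainder (GGR); this reproduces the
dual Gly boxes implied by the deletability of trnG-UCC once GGR is
eliminated. Overlaps between two boxes of equal superwobble status are
an error — they indicate an inconsistent roster, not a resolvable
ambiguity.

An amino acid with exactly two disjoint boxes is **dual**. The defined
compression scheme eliminates, for each dual amino acid, the box with
the lower summed usage over the reference CDS set, and maps every
eliminated codon to the single most frequent codon of the retained box.
All stop codons except the canonical stop (default TAA) are eliminated
and mapped to it; an unused stop (TGA in AT-rich plastomes) is
eliminated even at zero usage, so the eliminated set is a property of
the scheme rather than of the data. On a roster with the five dual
families this removes 11 sense codons + 2 stops = 13 codons, leaving a
51-codon code. Tie-breaks are deterministic: equal box usage eliminates
the box with fewer codons, then the lexicographically smaller codon
set; equal replacement counts pick the alphabetically first codon.

Forced-box overrides (amino acid → box to eliminate, e.g.
`{"R": "CGN", "I": "ATY", "S": "TCN"}`) derive more radical schemes
such as a 46-codon code, at the cost of more codon swaps.

A tRNA is reported **deletable** when its box-partition codon set is
entirely eliminated. The partitioned set, not the raw decoded set, is
the right basis: a superwobbling tRNA whose residual box is eliminated
is redundant even though its chemistry could still read retained codons
that another tRNA covers.

## Recoding and identity constraints

`recode_cds` is a pure codon substitution under the scheme; every edit
is ledgered with its 0-based codon index, old/new codon and category
(`target`, `stop`, `homology_break`, `terminal`). Human-facing TSV
output is 1-based. Invariants enforced after every operation: length
preserved, protein sequence preserved (stops equivalent), no eliminated
codon present, and stats equal to a direct diff.

Long stretches of WT identity in a recoded gene can act as homology
arms for recombination; organelle genomes recombine efficiently between
identical runs down to roughly 200 bp, so `max_run_bp` defaults to 200
and is configurable below it (observed problem cases are shorter).
`break_homology_runs` repeatedly finds the first offending run and
edits one codon inside it: among codons fully inside the run whose
amino acid has a permitted synonym, it picks the candidate maximizing
usage gain (rare → frequent swaps preferred), then proximity to the run
midpoint (splitting the run most efficiently), then the lowest index;
the codon swaps to the highest-usage permitted synonym differing from
it. Start codons are never edited (ATG/GTG initiation nuance); stop
codons change only via the scheme's stop replacement. A run containing
only Met/Trp/no-alternative codons raises an error naming the run.

`diversify_termini` edits codons within the first/last *n* codons
(excluding start and stop) to their highest-usage differing synonym,
but only codons still identical to the WT: an already-edited codon has
diverged, and re-editing it would both do nothing for homology and put
two entries at one ledger index. Homology is assessed positionwise
against the same-locus WT only; genome-wide repeat scanning is out of
scope.

## CAI

Relative adaptiveness is w(c) = f(c) / max f within each synonymous
family, computed from a reference usage table; the CAI of a sequence
(or of a restricted position set, e.g. the library's target positions)
is the geometric mean of w over included positions. Met, Trp and stops
are excluded (single-codon families are uninformative). Codons
unobserved in the reference receive a floor of 0.5/max-count
(configurable) to keep geometric means finite; a family entirely absent
from the reference raises an error naming the amino acid when scored.
The reference set is a free choice — whole-genome CDS usage by default,
any UsageTable in general.

## Combinatorial libraries

Target positions are codons in the eliminated sense set; each may take
any codon of its amino acid's retained permitted set. Library size is
the exact arbitrary-precision product of per-position set sizes.
Degenerate encodings are minimal IUPAC 3-mers whose expansion equals
the permitted set exactly; sets that are not a positionwise product
(possible with `include_native`, which adds the eliminated WT codon as
a troubleshooting option, off by default) have no exact encoding and
are recorded as such. Sampling is uniform over codon choices, matching
degenerate-oligo synthesis of rectangular sets — not uniform over
nucleotides; synthesis skew could be modeled by per-position weights
but is not, since the uniform model is the design intent.

## Read verification

Classification is alignment-free. For every site where WT and recoded
references differ, the WT and recoded signatures are the site base plus
`anchor_k` (default 10) flanking bases from the *respective* reference,
clipped at sequence ends. Neighbouring edits inside the window are part
of the signature — shrinking the window to an identical flank core
would produce signatures short enough to match spuriously. "Other"
signatures substitute the two bases that are neither WT nor recoded
into both contexts, so the other-base frequency estimates per-base
sequencing error (≈ 2e/3 for substitution rate e). A read (either
orientation) containing the recoded signature counts as recoded, else
WT, else other; a read containing a flank k-mer but no full signature
is unresolved. Frequencies are over resolved reads. Quality trimming is
assumed done upstream; the error model is substitution-only.

The read simulator draws each read's template Bernoulli(p), a uniform
start, per-base substitution errors at rate e, and a random orientation,
all from one seeded generator.

## Synthetic data

The generator emulates the features the pipeline depends on: an AT-rich
codon-usage profile with dual-isoacceptor families of strongly unequal
box usage, a 29-gene roster, genes on both strands of one contig, and a
canonical-stop-dominated stop profile with the opal stop absent. The
built-in TOY_USAGE profile fixes the five dual families' counts
explicitly (e.g. Leu TTA:90 TTG:10 vs CTN:5 each; stop TAA:60 TAG:4
TGA:0) and biases all other families 3:1 toward codons ending A/T.
Amino-acid composition is uniform over the 19 non-Met amino acids plus
an ATG start; gene lengths are Poisson around `length_mean` with a
floor of 30 codons. Every emitted codon is logged in an emission
record, which is the exact oracle for usage counting.

What the generator does not emulate: inverted repeats and dispersed
repeats, introns and trans-splicing, real amino-acid composition,
intergenic regulatory structure, and indel/quality structure in reads.
Tests passing on these fixtures therefore validate the algorithms and
their invariants, not performance on any particular real genome.

Default problem sizes: the shared test fixture uses 20 genes of ~150
codons (≈3,000 codons), enough that each dual family's sampled box
ordering matches the profile with wide margin; the acceptance script
uses 40 genes of ~200 codons for extra margin across seeds. Property
suites run 100 generated CDSs across 10 seeds.

## Known limitations

- Homology breaking is greedy; it finds a sufficient, not minimal, set
  of extra edits.
- Read classification requires exact signature matches, so it degrades
  with indel-rich reads; a SAM/pileup ingestion path is the documented
  extension for that regime.
- Box partition supports at most the overlap patterns that arise from
  one superwobble tRNA per family; exotic rosters with three-way
  overlaps are rejected rather than resolved.
- GenBank parsing concatenates `join()` CDS features in annotation
  order; trans-spliced genes should be supplied pre-joined by the
  caller.
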