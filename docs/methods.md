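# Methods

## Coordinate and strand conventions

All coordinates are 1-based, inclusive, on a circular molecule annotated so
that no feature wraps the origin (the last feature ends at the genome end);
wrap-around features are rejected with a clear error rather than silently
re-sliced. Strands are labelled H (the published strand) and L; the coding
(mRNA-sense) sequence of an L feature is the reverse complement of the
published-strand substring. N bases are allowed: they count toward lengths
but toward no base tally, and frequencies are normalized by the number of
unambiguous bases.

## Composition and skews

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C), computed from counts on
whichever strand a unit is read from; a zero denominator yields NaN rather
than an exception. Per-gene statistics use the coding strand — the only
convention that reproduces the observed sign structure in insect
mitogenomes, where genes read from opposite strands show GC skews of
opposite sign — while the genome-wide Total uses the published strand as
is. Tabular output rounds to 3 decimals; full precision is kept
internally. Recomputing skews from published *rounded* frequencies
reproduces some printed values exactly and others only to ±0.004 (the
inputs are rounded to 3 decimals), so table-wide checks use a ±0.005
tolerance and exactness is asserted only for the two anchor values (the
atp8 AT-skew 0.092 and genome-wide GC-skew −0.217) that are exact at 3 dp.
The genome-wide A+T content is reported at full precision; published
roundings of the same quantity differ in the second decimal between
sources, and no specific rounding is forced.

## Codon usage and RSCU

The genetic code is fixed to NCBI translation table 5 (invertebrate
mitochondrial), taken from Biopython's code tables; it is configurable only
by explicit argument. Synonymous families follow the code itself: serine is
one 8-codon family (UCN + AGN) and leucine one 6-codon family (UUR + CUN);
the common table layout that splits them into boxes is presentation only.
RSCU(c) = N(c)·k / Σ_family N with k the family size; an unused codon in a
used family scores 0, a wholly unused family scores 0 throughout. Amino
acid usage is the family count share of the total in percent.

Codon extraction excludes the final terminator, so a gene of length L with
a complete stop contributes L/3 − 1 codons; a trailing remainder of T or TA
is treated as an incomplete stop completed by polyadenylation, flagged, and
excluded from counts. Stop triplets encountered mid-gene (possible in
synthetic sequence where reading frames overlap) are tallied separately and
never counted as sense codons. Counts are held in the DNA alphabet
internally and rendered with U in table output.

## Circular layout

The signed spacer between consecutive features in start order is
start(next) − end(prev) − 1; the wrap pair (last→first) closes the circle
with (genome_length − end(last)) + (start(first) − 1). Strand is irrelevant
to the arithmetic (overlaps may cross strands). Zero-length spacers count
in neither total. The control region participates in adjacency like any
feature: it is never itself a spacer, but its flanking gaps are counted.
Nested or duplicated spans are layout errors listing the offenders.

## Rearrangement classification

Anchors are the 13 PCGs plus the two rRNAs, with the control region as an
additional fixed boundary marker (never a movable gene). The rRNAs are
included because no tRNA crosses them in any of the three shipped orders;
orders whose anchors themselves disagree are rejected as unsupported input,
since the translocation/inversion/shuffling taxonomy covers tRNA moves
only.

Per tRNA, the anchor interval is the ordered pair of nearest flanking
anchors. Translocation ⇔ the interval differs from the reference;
inversion ⇔ the strand sign differs; shuffling is an *attribution* problem:
when the comparable tRNAs of an interval appear in a different relative
order, the genes reported as shuffled are the minimal set whose relocation
explains the reorder — the complement of a longest common subsequence
between the reference-side and observed-side orders — with ties broken by
keeping the lexicographically smallest gene-name tuple. The same rule is
applied to groups of tRNAs translocated together between the same pair of
intervals, so a block that moves intact yields pure translocations while
members that also changed order within the block are flagged as shuffled.
This is the weakest rule we found that reproduces all the worked honeybee
statements simultaneously (trnS1 translocated-only in *A. cerana* but
translocated-and-shuffled in *A. mellifera*; the trnA repositioning
relative to trnS1/trnE attributed to trnA alone) — a single pairwise-order
rule cannot. Under it the two honeybee orders share exactly eight
rearranged tRNAs versus the ancestral arrangement; since the underlying
enumeration of "events" versus "genes" is partly a judgement call (a block
reversal can be counted once or per member), reports carry per-gene event
types so either accounting can be read off.

Two events are *shared* between genomes when gene, destination interval and
inversion status agree; shuffling status may legitimately differ and is
kept per side. The ancestral pancrustacean order ships as the standard
Drosophila-like ground plan; *A. cerana*'s order is derived from its
annotation table, and *A. mellifera*'s differs only by the trnS1/trnE swap.

## tRNA structures and the control region

Cloverleaf structures are inputs (arm-span tables or dot-bracket strings);
no thermodynamic folding is attempted, since structures in this literature
come from tRNAscan-SE plus inspection. The dot-bracket converter assumes a
flat cloverleaf (outermost helix = acceptor; hairpins assigned 5′→3′ as D,
anticodon, T; with two hairpins the D arm is taken as missing unless told
otherwise) and rejects bulged helices. A stem pair is a mismatch when it is
not Watson–Crick; G·U wobble counts as a mismatch by default, matching how
mitochondrial tRNA audits are usually phrased, with an explicit wobble mode
that accepts it. The published 6-mismatch total for the real genome cannot
be recomputed without the deposited sequence, so it is emulated (the
synthetic generator plants six mismatches) rather than asserted. Acceptor
stem and loop sizes are reported in nucleotides; published ranges quoted in
"bp" for those regions are ambiguous and are not asserted.

Control-region scanner defaults (all explicit parameters echoed into
reports): polyT = maximal T runs ≥ 5; [TA(A)]n = maximal greedy runs of
TAA/TA units with ≥ 3 units (mixed units allowed — an interpretation of
"TA(A)n-like"); TATA = exact occurrences (overlaps included); G(A)nT with
n ≥ 1; G+A-rich = merged 20-nt windows with G+A fraction ≥ 0.8; stem-loop =
outward-maximal inverted repeats with stem ≥ 6 and loop 3–20. Every
reported hit satisfies its defining predicate when its span is re-extracted
(self-verifying reports). Shared-motif search is exact k-mer intersection
with positions, k ≥ 4.

## Alignment, distances, trees

Global alignment is Needleman–Wunsch via Biopython's PairwiseAligner with
defaults match +1, mismatch 0, gap −1 (linear); identity = 100 ·
matches / alignment columns with gap columns in the denominator, switchable
to ungapped columns. These defaults are stated, logged and overridable, but
are *not* claimed to reproduce identity percentages computed with other
aligners' defaults; published per-gene identity tables are treated as
documentation, not as recovery targets. p-distance is the mismatch fraction
over columns ungapped in both sequences; per-gene alignments are
concatenated into a supermatrix only when taxon sets agree exactly.

Neighbor joining is the canonical Saitou–Nei agglomeration on the Q
criterion, hand-written for full determinism: ties break toward the
lexicographically lowest cluster pair, and negative branch lengths are
clamped to zero with a warning. On additive matrices it recovers the
generating topology and total tree length exactly (verified against random
additive trees and against an independent NJ implementation). Bootstrap
resamples supermatrix columns with replacement (numpy Generator seeded
explicitly); support is the percentage of replicate trees containing each
internal bipartition of the point-estimate tree. Maximum likelihood and
maximum parsimony are out of scope; supermatrices can be exported for
external tools.

## Synthetic data

The generator's default plan is the published honeybee gene plan itself —
the same names, lengths, strands and signed spacers — so layout statistics
are recovered exactly by construction, and the codon total implied by the
planted PCG lengths is 3,672. PCGs are sampled codon-by-codon from a codon
weight vector (default: the published codon-count spectrum, which fixes
both RSCU and amino-acid usage up to multinomial noise), with planted ATN
starts and TAA stops re-stamped after assembly. All non-coding fill is
drawn i.i.d. from an H-strand background (default: the published
genome-wide frequencies, A .423 / G .063 / T .416 / C .098), which gives
L-strand units the mirrored GC skew. The control-region background uses an
AT-rich vector (~95% A+T) matching what is reported for real A+T-rich
regions.

Where two PCGs overlap, one stretch of sequence serves two reading frames,
so the generator repairs any in-frame internal stop that arises there
(middle-base edit TAA→TTA / TAG→TTG, iterated to a fixed point); tRNAs
whose spans overlap a PCG keep the PCG sequence, and the truth object
records that their planted structures are not guaranteed (three of the 22
in the default plan). Planted control-region elements are written at exact
offsets with guard bases so background cannot extend a hit; spurious
background polyT runs and stem-loops (at the planted-stem stringency,
stem ≥ 8) are repaired away, so recovery is exclusive for those two kinds,
while pervasive soft motifs (TATA, TA(A)n, G+A-rich) are left to occur
naturally in the background — exactly as they do in real regions — and are
checked by recall at the planted coordinates only.

Divergence applies i.i.d. per-site substitutions at rate p_sub (uniform
over the three alternative bases), optionally protecting PCG start/stop
triplets; the expected protein identity under this model is computed
exactly by enumerating all 64 mutated outcomes per codon, giving a sharp
oracle for identity tests (~±2% at 11 kb of CDS). Protein evolution down a
user-specified tree (per-branch substitution probabilities) provides
ground-truth topologies for NJ and bootstrap tests; planted rearrangements
are constructed so the classifier's attribution is provably unambiguous
(shuffles cross at least two neighbors; co-translocations land after
distinct anchors).

All randomness flows from one explicit seed through a single numpy
Generator; identical seeds give byte-identical genomes, and the truth is
serializable as JSON next to the FASTA/TSV.

What the synthetic data does *not* emulate: indels and length variation,
secondary-structure-aware rRNA sequence, strand-specific codon usage
differences between H- and L-strand PCGs, and site-rate heterogeneity.
Passing recovery tests therefore demonstrates correctness of the
accounting and inference machinery under the stated generative model, not
performance on the quirks of real sequencing data.

## Problem sizes and numerical choices

Tests run at the genome's natural scale (~16 kb, 38 features, 3,672
codons) plus small randomized instances: exhaustive alignment oracles up to
8 residues, additive NJ recovery up to 10 leaves, bootstrap checks at
50–200 replicates, parameter-recovery at single-genome scale; the whole
suite completes in a few seconds. Frequencies and RSCU are checked within
binomial 3σ bands plus a small start-codon allowance; layout, rearrangement
and element recovery are exact. Report files embed the tool version and a
config hash so outputs are traceable to their settings.
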