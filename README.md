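# mitolens

Characterization toolkit for animal mitochondrial genomes, built around the
honeybee (*Apis*) case: a ~16 kb circular molecule carrying 13 protein-coding
genes (PCGs), 22 tRNAs, 2 rRNAs and one A+T-rich control region. The package
is aimed at people annotating and comparing mitogenomes who want the standard
descriptive statistics and comparative analyses as reusable, tested code
rather than one-off spreadsheets:

- **Composition & skews** — per-gene base composition on the coding strand,
  A+T content, and strand skews, AT-skew = (A−T)/(A+T),
  GC-skew = (G−C)/(G+C).
- **Codon usage & RSCU** — codon extraction under the invertebrate
  mitochondrial code (NCBI table 5: UGA→Trp, AUA→Met, AGA/AGG→Ser),
  start/stop identification (including incomplete T/TA stops), codon counts
  N, relative synonymous codon usage RSCU(c) = N(c)·k / Σ<sub>family</sub>N
  with k the synonymous family size, and per-amino-acid usage.
- **Circular layout** — signed spacers between consecutive genes
  (gap > 0, overlap < 0) including the wrap pair that closes the circle,
  with totals and the conservation identity
  Σ lengths + Σ gaps − Σ overlaps = genome length.
- **tRNA rearrangements** — classification of gene-order changes against a
  reference (ancestral pancrustacean) order as translocation (moved across
  a protein-coding gene), inversion (strand switch) and/or shuffling (local
  reorder), plus the shared-event intersection between two genomes. The
  ancestral, *A. cerana* and *A. mellifera* orders ship as constants.
- **tRNA structure audit** — cloverleaf arm census and stem-mismatch
  counting (G·U counts as a mismatch by default; wobble mode optional).
- **Control-region scan** — the five canonical A+T-rich-region elements:
  5′ polyT stretch, [TA(A)]<sub>n</sub> repeat, stem-loop (inverted repeat),
  TATA and G(A)<sub>n</sub>T motifs, G+A-rich stretches; plus shared-motif
  search in homologous spacers.
- **Protein identity & phylogenetics** — Needleman–Wunsch global alignment
  identity, p-distances on concatenated protein alignments, Saitou–Nei
  neighbor joining with deterministic tie-breaking, and column-resampling
  bootstrap supports.
- **Synthetic mitogenomes** — a generator that emulates the honeybee genome
  plan (planted layout, codon spectrum, control-region elements, cloverleaf
  structures with chosen mismatch counts, rearrangements, divergence at a
  chosen substitution rate) with full ground truth, so every analysis stage
  is testable offline.

The published *A. cerana* annotation (GenBank GQ162109), its per-gene
nucleotide frequencies and its codon-usage counts are bundled as plain
coordinate/count tables in `mitolens.reference`; all statistics about them
are recomputed at run time.

## Worked example

```python
from mitolens import adjacency_spacers, summarize_layout, rscu, aa_usage
from mitolens.codon_usage import total_codons_from_lengths
from mitolens.reference import apis_cerana_annotation, APIS_CERANA_CODON_COUNTS

genome = apis_cerana_annotation()
totals = summarize_layout(adjacency_spacers(genome.features, genome.length))
print(genome.length, totals.total_intergenic, totals.n_intergenic_regions,
      totals.total_overlap, totals.n_overlap_locations, totals.longest_spacer)
print(total_codons_from_lengths(genome.features))
print(round(rscu(APIS_CERANA_CODON_COUNTS)["TTA"], 2),
      round(aa_usage(APIS_CERANA_CODON_COUNTS)["L"], 2))
```

prints

```
15895 705 22 27 4 231
3672
5.08 15.52
```

i.e. a 15,895 bp circle whose genes are separated by 705 bp of spacer spread
over 22 regions and overlap by 27 bp at 4 locations (longest spacer 231 bp);
its 13 PCGs encode 3,672 codons excluding terminators; leucine's UUA codon
carries an RSCU of 5.08 out of a possible 6, and leucine itself is 15.52% of
all residues — the signature of an extremely A+T-biased genome.

The `examples/` directory holds one short narrative script per capability
(layout, RSCU, skews, rearrangements, control region + tRNA audit,
identity + NJ). Each builds or loads a small input, runs the method, and
prints what the numbers mean. A thin CLI mirrors the library:
`mitolens layout|skew|codon|rearrange|control-region|trna-audit|identity|nj|simulate|report`.

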