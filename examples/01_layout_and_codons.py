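"""Circular layout accounting and codon totals from coordinates alone.

Uses the bundled A. cerana annotation table (no sequence needed): signed
spacers between consecutive genes around the circle, gap/overlap totals,
and the codon total implied by the protein-coding gene lengths.
"""

from mitolens import adjacency_spacers, check_conservation, summarize_layout
from mitolens.codon_usage import total_codons_from_lengths
from mitolens.reference import apis_cerana_annotation

genome = apis_cerana_annotation()
report = adjacency_spacers(genome.features, genome.length)
totals = summarize_layout(report)

print(f"genome length: {genome.length} bp, {len(genome.features)} features")
print(f"intergenic: {totals.total_intergenic} bp over "
      f"{totals.n_intergenic_regions} regions")
print(f"overlap: {totals.total_overlap} bp at {totals.n_overlap_locations} locations")
print(f"longest spacer: {totals.longest_spacer} bp between "
      f"{totals.longest_spacer_pair[0]} and {totals.longest_spacer_pair[1]}")
print(f"length conserved (genes + gaps - overlaps == genome): "
      f"{check_conservation(totals)}")
print(f"codons encoded by the 13 PCGs (terminators excluded): "
      f"{total_codons_from_lengths(genome.features)}")

# The 705/27 totals and the 3672-codon count are the genome's architecture
# in two numbers each: how loosely genes are packed, and how much protein
# the molecule encodes.
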