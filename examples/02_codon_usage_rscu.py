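"""Relative synonymous codon usage from published codon counts.

RSCU(c) = N(c) * k / sum of family counts, with k the synonymous family
size under the invertebrate mitochondrial code (leucine 6, serine 8).
Values > 1 mark codons used more often than expected under uniform use.
"""

from mitolens.codon_usage import FAMILIES, aa_usage, rscu
from mitolens.reference import APIS_CERANA_CODON_COUNTS

values = rscu(APIS_CERANA_CODON_COUNTS)
usage = aa_usage(APIS_CERANA_CODON_COUNTS)

print("leucine family (one 6-codon family):")
for codon in FAMILIES["L"]:
    rna = codon.replace("T", "U")
    print(f"  {rna}: N={APIS_CERANA_CODON_COUNTS[codon]:4d}  RSCU={values[codon]:.2f}")
print(f"family RSCU sum: {sum(values[c] for c in FAMILIES['L']):.2f} (= family size)")
print()
top = sorted(usage.items(), key=lambda kv: -kv[1])[:5]
print("most used amino acids:",
      ", ".join(f"{aa} {pct:.2f}%" for aa, pct in top))

# UUA at RSCU ~5 of a possible 6 shows the extreme A+T bias of the genome:
# nearly every leucine is written with the most AT-rich codon available.
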