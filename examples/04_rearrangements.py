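"""Classify honeybee tRNA rearrangements against the ancestral gene order.

Translocation = moved across a protein-coding gene; inversion = switched
strand; shuffling = reordered locally.  Both Apis orders are compared to
the ancestral pancrustacean arrangement, then intersected.
"""

from mitolens import GeneOrder, classify_rearrangements, shared_events
from mitolens.reference import (
    ANCESTRAL_PANCRUSTACEAN_ORDER,
    APIS_CERANA_ORDER,
    APIS_MELLIFERA_ORDER,
)

anc = GeneOrder(ANCESTRAL_PANCRUSTACEAN_ORDER, "ancestral")
cerana = GeneOrder(APIS_CERANA_ORDER, "A. cerana")
mellifera = GeneOrder(APIS_MELLIFERA_ORDER, "A. mellifera")

ev_c = classify_rearrangements(cerana, anc)
ev_m = classify_rearrangements(mellifera, anc)

print("A. cerana vs ancestral:")
for e in ev_c:
    print(f"  {e.gene:6s} {'+'.join(sorted(e.event_types)):26s} "
          f"{e.from_interval[0]}..{e.from_interval[1]} -> "
          f"{e.to_interval[0]}..{e.to_interval[1]}")

s1_m = next(e for e in ev_m if e.gene == "trnS1")
print(f"\nA. mellifera trnS1: {'+'.join(sorted(s1_m.event_types))}")
print(f"shared rearrangements between the two honeybees: "
      f"{len(shared_events(ev_c, ev_m))}")

# trnS1 is the one difference between the two bees: translocated only in
# A. cerana, but additionally swapped with trnE (shuffled) in A. mellifera.
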