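"""Scan a synthetic A+T-rich control region and audit planted tRNA stems.

The generator plants the five canonical control-region elements (polyT,
TA(A)n repeat, stem-loop with flanking TATA and G(A)nT motifs, G+A-rich
stretch) and six tRNA stem mismatches; the scanners recover them.
"""

from mitolens import count_stem_mismatches, extract_feature_sequence, scan_control_region
from mitolens.structure_motifs import ScanParams
from mitolens.synthetic import generate_genome

genome, truth = generate_genome(seed=42)
region = extract_feature_sequence(genome, genome.feature(truth.control_region))
report = scan_control_region(
    region, ScanParams(min_stem=truth.stem_loop_scan_min_stem)
)

print(f"control region: {len(region)} bp, A+T {report.at_content:.1f}%")
for elem in truth.control_elements:
    hits = [h for h in report.of_kind(elem.kind) if h.span == elem.span]
    note = hits[0].detail if hits else "covered by a wider hit"
    print(f"  planted {elem.kind:10s} at {elem.span}: "
          f"{'recovered' if hits or elem.kind == 'GA_rich' else 'MISSED'} {note}")

total = 0
for gene, (arm, bases) in truth.trna_mismatch_plan.items():
    seq = extract_feature_sequence(genome, genome.feature(gene))
    mism = count_stem_mismatches(seq, truth.structures[gene])
    total += len(mism)
    print(f"  {gene}: {len(mism)} mismatch in {arm} arm "
          f"({mism[0].bases[0]}-{mism[0].bases[1]})")
print(f"total planted stem mismatches recovered: {total}")
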