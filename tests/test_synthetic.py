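import math

import numpy as np
import pytest

from mitolens.codon_usage import SENSE_CODONS, codon_usage_table, translate_cds
from mitolens.compare_phylo import global_align
from mitolens.genome_model import extract_feature_sequence
from mitolens.layout import adjacency_spacers, check_conservation, summarize_layout
from mitolens.structure_motifs import ScanParams, count_stem_mismatches, scan_control_region
from mitolens.synthetic import (
    FeaturePlan,
    SyntheticError,
    apis_cerana_plan,
    diverge_genome,
    expected_protein_identity,
    generate_genome,
    make_cloverleaf,
    sample_cds,
)


def test_same_seed_is_byte_identical():
    g1, _ = generate_genome(seed=3)
    g2, _ = generate_genome(seed=3)
    assert g1.sequence == g2.sequence
    g3, _ = generate_genome(seed=4)
    assert g3.sequence != g1.sequence


def test_plan_reproduces_published_layout(synthetic_bundle):
    genome, _ = synthetic_bundle
    totals = summarize_layout(adjacency_spacers(genome.features, genome.length))
    assert genome.length == 15895
    assert totals.total_intergenic == 705 and totals.n_intergenic_regions == 22
    assert totals.total_overlap == 27 and totals.n_overlap_locations == 4
    assert check_conservation(totals)


def test_codon_totals_follow_planted_lengths(synthetic_bundle):
    genome, _ = synthetic_bundle
    table = codon_usage_table(genome)
    assert table.total_codons == 3672


def test_codon_spectrum_recovers_planted_profile(synthetic_bundle):
    genome, truth = synthetic_bundle
    table = codon_usage_table(genome)
    n = table.total_codons
    total_w = sum(truth.codon_weights.values())
    for codon in SENSE_CODONS:
        p = truth.codon_weights.get(codon, 0) / total_w
        obs = table.counts[codon] / n
        # binomial sampling band plus the 13 planted start codons
        band = 3 * math.sqrt(max(p, 1e-6) * (1 - p) / n) + 14 / n
        assert abs(obs - p) <= band, codon


def test_control_region_elements_recovered(synthetic_bundle):
    genome, truth = synthetic_bundle
    region = extract_feature_sequence(genome, genome.feature(truth.control_region))
    rep = scan_control_region(region, ScanParams(min_stem=truth.stem_loop_scan_min_stem))
    for elem in truth.control_elements:
        hits = rep.of_kind(elem.kind)
        if elem.kind == "GA_rich":
            assert any(h.start <= elem.span[0] and h.end >= elem.span[1] for h in hits)
        else:
            assert elem.span in [h.span for h in hits], elem
    # exclusivity holds for the repaired kinds
    assert [h.span for h in rep.of_kind("polyT")] == [
        e.span for e in truth.control_elements if e.kind == "polyT"
    ]
    assert [h.span for h in rep.of_kind("stem_loop")] == [
        e.span for e in truth.control_elements if e.kind == "stem_loop"
    ]


def test_planted_trna_mismatch_counts_recovered(synthetic_bundle):
    genome, truth = synthetic_bundle
    total = 0
    for gene, (arm, bases) in truth.trna_mismatch_plan.items():
        seq = extract_feature_sequence(genome, genome.feature(gene))
        mism = count_stem_mismatches(seq, truth.structures[gene])
        assert len(mism) == 1
        assert mism[0].arm == arm and mism[0].bases == bases
        total += len(mism)
    assert total == 6
    # guaranteed tRNAs without a planted mismatch audit clean
    for gene, ok in truth.structure_guaranteed.items():
        if ok and gene not in truth.trna_mismatch_plan:
            seq = extract_feature_sequence(genome, genome.feature(gene))
            assert count_stem_mismatches(seq, truth.structures[gene]) == []


def test_cloverleaf_template_spans_trna_length_range():
    for length in range(60, 79):
        cl = make_cloverleaf(length, with_d_arm=length != 60)
        indices = [i for pairs in cl.arms.values() for ij in pairs for i in ij]
        assert max(indices) < length and min(indices) >= 0


def test_infeasible_layout_rejected():
    plan = [
        FeaturePlan("a", "tRNA", "H", 60, spacer_after=-70),
        FeaturePlan("b", "tRNA", "H", 60, spacer_after=0),
    ]
    with pytest.raises(SyntheticError):
        generate_genome(plan=plan, seed=0)


def test_sample_cds_structure():
    rng = np.random.default_rng(0)
    cds = sample_cds(300, rng, start_codon="ATG")
    assert len(cds) == 300
    assert cds.startswith("ATG") and cds.endswith("TAA")
    assert "*" not in translate_cds(cds)


def test_truth_json_serializes(synthetic_bundle):
    _, truth = synthetic_bundle
    blob = truth.to_json()
    import json

    payload = json.loads(blob)
    assert payload["genome_length"] == 15895
    assert payload["seed"] == 7


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------


def test_zero_divergence_keeps_identity():
    genome, _ = generate_genome(seed=5)
    rel = diverge_genome(genome, p_sub=0.0, seed=1)
    assert rel.sequence == genome.sequence


def test_divergence_matches_binomial_expectation():
    genome, _ = generate_genome(seed=6)
    p_sub = 0.05
    rel = diverge_genome(genome, p_sub=p_sub, seed=2)
    pcgs = [f for f in genome.features_of_class("PCG")]
    total_aa = 0
    expected_weighted = 0.0
    matches = 0.0
    for f in pcgs:
        cds = extract_feature_sequence(genome, f)
        prot_a = translate_cds(cds)
        prot_b = translate_cds(extract_feature_sequence(rel, f))
        res = global_align(prot_a, prot_b)
        matches += res.matches
        total_aa += len(prot_a)
        expected_weighted += expected_protein_identity(cds, p_sub) * len(prot_a)
    measured = 100.0 * matches / total_aa
    expected = expected_weighted / total_aa
    assert abs(measured - expected) < 2.0   # ~11 kb of CDS


def test_independent_seeds_give_different_mutations():
    genome, _ = generate_genome(seed=8)
    r1 = diverge_genome(genome, 0.05, seed=1)
    r2 = diverge_genome(genome, 0.05, seed=2)
    assert r1.sequence != r2.sequence
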