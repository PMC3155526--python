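import numpy as np
import pytest
from hypothesis import given, strategies as st

from mitolens.genome_model import revcomp
from mitolens.structure_motifs import (
    ARM_NAMES,
    Cloverleaf,
    ScanParams,
    StructureError,
    WATSON_CRICK,
    WOBBLE,
    arm_census,
    cloverleaf_from_dotbracket,
    count_stem_mismatches,
    find_shared_motifs,
    find_stem_loops,
    scan_control_region,
)
from mitolens.synthetic import make_cloverleaf, sample_trna


def hairpin(stem5: str, loop: str) -> tuple[str, Cloverleaf]:
    seq = stem5 + loop + revcomp(stem5)
    n = len(stem5)
    pairs = tuple((i, len(seq) - 1 - i) for i in range(n))
    return seq, Cloverleaf(arms={"acceptor": pairs})


def test_watson_crick_hairpin_has_no_mismatches():
    seq, cl = hairpin("GATTACA", "AAAA")
    assert count_stem_mismatches(seq, cl) == []


def test_gt_pair_is_mismatch_by_default_but_not_in_wobble_mode():
    seq, cl = hairpin("GATTACA", "AAAA")
    seq = seq[:17] + "T"              # final position pairs with the leading G
    mism = count_stem_mismatches(seq, cl)
    assert len(mism) == 1 and mism[0].bases == ("G", "T")
    assert count_stem_mismatches(seq, cl, WOBBLE) == []


def test_out_of_range_indices_rejected():
    _, cl = hairpin("GATTACA", "AAAA")
    with pytest.raises(StructureError):
        count_stem_mismatches("ACGT", cl)


def test_random_stems_match_bruteforce_pair_check():
    rng = np.random.default_rng(2)
    for _ in range(25):
        stem5 = "".join(rng.choice(list("ACGT"), size=6))
        seq, cl = hairpin(stem5, "AAAA")
        # corrupt a few 3' positions
        seq = list(seq)
        for idx in rng.choice(range(10, 16), size=2, replace=False):
            seq[idx] = rng.choice(list("ACGT"))
        seq = "".join(seq)
        expected = {
            (i, j) for i, j in cl.arms["acceptor"]
            if (seq[i], seq[j]) not in WATSON_CRICK
        }
        observed = {(m.i, m.j) for m in count_stem_mismatches(seq, cl)}
        assert observed == expected


def test_arm_census_classification():
    full = make_cloverleaf(66, with_d_arm=True)
    census = arm_census(full)
    assert census.is_cloverleaf and census.missing == frozenset()
    no_d = make_cloverleaf(60, with_d_arm=False)
    census = arm_census(no_d)
    assert not census.is_cloverleaf and census.missing == {"D"}
    empty = arm_census(Cloverleaf(arms={}))
    assert empty.missing == frozenset(ARM_NAMES)


def test_dotbracket_converter_assigns_arms():
    db = "((((((..((((.....))))((((.......))))..((((.....)))))))))).."
    cl = cloverleaf_from_dotbracket(db)
    assert cl.present_arms == frozenset(ARM_NAMES)
    # acceptor is the outermost helix
    assert cl.arms["acceptor"][0] == (0, 56)
    two_hairpins = "((((..((((.......))))..((((.....)))))))).."
    cl2 = cloverleaf_from_dotbracket(two_hairpins)
    assert arm_census(cl2).missing == {"D"}


def test_planted_trna_audits_clean_or_one_mismatch():
    rng = np.random.default_rng(9)
    freqs = {"A": 0.4, "G": 0.1, "T": 0.4, "C": 0.1}
    seq, cl, n = sample_trna(66, rng, freqs)
    assert n == 0
    assert count_stem_mismatches(seq, cl) == []
    seq, cl, n = sample_trna(66, rng, freqs, mismatch=("acceptor", ("G", "T")))
    mism = count_stem_mismatches(seq, cl)
    assert n == 1 and len(mism) == 1 and mism[0].arm == "acceptor"


# ---------------------------------------------------------------------------
# control-region scanning
# ---------------------------------------------------------------------------


def test_constructed_region_polyt_and_taa():
    region = "AAATTTTTTTATATAATAATAAGGCC"
    rep = scan_control_region(region)
    polyt = rep.of_kind("polyT")
    assert [h.span for h in polyt] == [(3, 10)]
    taa = rep.of_kind("TAA_repeat")
    assert any(h.detail["units"] >= 3 for h in taa)
    assert rep.of_kind("TATA")


def test_gant_and_ga_rich():
    rep = scan_control_region("CCGAAATCC" + "GA" * 15 + "CC")
    gant = rep.of_kind("GAnT")
    assert gant[0].span == (2, 7) and gant[0].detail["n"] == 3
    assert rep.of_kind("GA_rich")


def test_planted_stem_loop_found_exactly():
    stem = "GCATGCAT"
    # flanks chosen so the planted stem cannot extend outward
    region = "ACCAAC" + stem + "AAAAAA" + revcomp(stem) + "CAACCA"
    hits = find_stem_loops(region, ScanParams(min_stem=6))
    assert len(hits) == 1
    assert hits[0].span == (6, 6 + 22)
    assert hits[0].detail["stem"] == 8 and hits[0].detail["loop"] == 6


def test_stem_loop_absent_without_inverted_repeat():
    assert find_stem_loops("ACACACACACACACACACAC", ScanParams(min_stem=6)) == []


def test_empty_region_rejected():
    with pytest.raises(StructureError):
        scan_control_region("")


def test_reported_elements_are_self_verifying(synthetic_bundle):
    from mitolens.genome_model import extract_feature_sequence

    genome, truth = synthetic_bundle
    region = extract_feature_sequence(genome, genome.feature(truth.control_region))
    rep = scan_control_region(region, ScanParams(min_stem=truth.stem_loop_scan_min_stem))
    for h in rep.hits:
        piece = region[h.start : h.end]
        if h.kind == "polyT":
            assert set(piece) == {"T"} and len(piece) >= rep.params.min_polyT
        elif h.kind == "TATA":
            assert piece == "TATA"
        elif h.kind == "GAnT":
            assert piece[0] == "G" and piece[-1] == "T" and set(piece[1:-1]) == {"A"}
        elif h.kind == "stem_loop":
            s = h.detail["stem"]
            assert piece[:s] == revcomp(piece[-s:])
        elif h.kind == "TAA_repeat":
            assert piece.startswith("TA") and set(piece) <= {"T", "A"}
        elif h.kind == "GA_rich":
            w = rep.params.ga_window
            frac = max(
                sum(c in "GA" for c in piece[i : i + w]) / w
                for i in range(0, max(1, len(piece) - w + 1))
            )
            assert frac >= rep.params.ga_fraction


def test_shared_motif_published_example():
    a = "TTTACTTAAAAATTTT"
    b = "AGATACTTATTAA"
    motifs = find_shared_motifs(a, b, 6)
    assert any(m == "TACTTA" for m, _, _ in motifs)


def test_shared_motifs_disjoint_alphabets_empty():
    assert find_shared_motifs("AAAAAA", "CCCCCC", 4) == []


@given(
    st.text(alphabet="ACGT", min_size=8, max_size=40),
    st.text(alphabet="ACGT", min_size=8, max_size=40),
)
def test_shared_motifs_match_set_intersection(a, b):
    k = 5
    observed = {m for m, _, _ in find_shared_motifs(a, b, k)}
    brute = {a[i : i + k] for i in range(len(a) - k + 1)} & {
        b[i : i + k] for i in range(len(b) - k + 1)
    }
    assert observed == brute


def test_shared_motifs_k_longer_than_spacer_warns():
    with pytest.warns(UserWarning):
        assert find_shared_motifs("ACGTA", "ACGTA", 6) == []
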