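import math

import numpy as np
import pytest

from mitolens.compare_phylo import (
    DistanceMatrix,
    PhyloError,
    bootstrap_support,
    concatenate_alignments,
    global_align,
    neighbor_joining,
    nj_tree_from_alignment,
    p_distance,
    p_distance_matrix,
)
from mitolens.synthetic import AA_ALPHABET, evolve_proteins, random_protein

# ---------------------------------------------------------------------------
# alignment & identity
# ---------------------------------------------------------------------------


def brute_force_best_score(a, b, match=1.0, mismatch=0.0, gap=-1.0):
    """Enumerate every global alignment path recursively (tiny inputs only)."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def test_identical_sequences_full_identity():
    res = global_align("MKVLH", "MKVLH")
    assert res.identity == 100.0
    assert "-" not in res.aligned_a + res.aligned_b


def test_single_substitution_identity():
    res = global_align("MKV", "MRV")
    assert round(res.identity, 1) == 66.7


def test_empty_sequence_rejected():
    with pytest.raises(PhyloError):
        global_align("", "MKV")


def test_identity_is_symmetric():
    rng = np.random.default_rng(4)
    for _ in range(10):
        a = random_protein(int(rng.integers(5, 30)), rng)
        b = random_protein(int(rng.integers(5, 30)), rng)
        assert math.isclose(global_align(a, b).identity, global_align(b, a).identity)


def test_alignment_score_matches_exhaustive_enumeration():
    rng = np.random.default_rng(8)
    for _ in range(12):
        a = random_protein(int(rng.integers(1, 7)), rng)
        b = random_protein(int(rng.integers(1, 7)), rng)
        assert math.isclose(global_align(a, b).score, brute_force_best_score(a, b))


def test_ungapped_denominator_flag():
    res = global_align("MKVAA", "MKV", count_gap_columns=False)
    assert res.columns == 3 and res.identity == 100.0


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def test_p_distance_basics():
    assert p_distance("AAAAAAAAAA", "AAAAAAAAAA") == 0.0
    assert p_distance("AAAAAAAAAA", "CCCAAAAAAA") == 0.3
    assert p_distance("A-AAA", "ACAAA") == 0.0       # gap column skipped


def test_p_distance_matrix_matches_bruteforce():
    rng = np.random.default_rng(12)
    aln = {f"t{i}": random_protein(40, rng) for i in range(5)}
    dm = p_distance_matrix(aln)
    for a in aln:
        for b in aln:
            brute = sum(x != y for x, y in zip(aln[a], aln[b])) / 40
            assert math.isclose(dm.get(a, b), brute)


def test_concatenation_rejects_mismatched_taxa():
    with pytest.raises(PhyloError):
        concatenate_alignments([{"a": "MK", "b": "MK"}, {"a": "MK", "c": "MK"}])


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def random_additive_tree(n_leaves, rng):
    """Random binary tree; returns (distance dict, bipartitions, total length)."""
    subtrees = [{f"t{i}": 0.0} for i in range(n_leaves)]  # leaf -> dist to node
    dist = {}
    splits = set()
    all_leaves = frozenset(f"t{i}" for i in range(n_leaves))
    anchor = min(all_leaves)
    total = 0.0
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        bi, bj = float(rng.uniform(0.05, 0.6)), float(rng.uniform(0.05, 0.6))
        total += bi + bj
        left, right = subtrees[i], subtrees[j]
        for la, da in left.items():
            for lb, db in right.items():
                dist[frozenset((la, lb))] = da + bi + db + bj
        merged = {l: d + bi for l, d in left.items()}
        merged.update({l: d + bj for l, d in right.items()})
        below = frozenset(merged)
        if 1 < len(below) < n_leaves - 1:
            splits.add(below if anchor not in below else all_leaves - below)
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)] + [merged]
    return dist, splits, total


def to_matrix(dist, n):
    taxa = tuple(f"t{i}" for i in range(n))
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = dist[frozenset((taxa[i], taxa[j]))]
    return DistanceMatrix(taxa=taxa, matrix=m)


def test_three_taxon_closed_form():
    m = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = neighbor_joining(DistanceMatrix(taxa=("a", "b", "c"), matrix=m))
    lengths = {child.label: bl for child, bl in tree.children}
    assert math.isclose(lengths["a"], 0.5 * (0.3 + 0.5 - 0.6))
    assert math.isclose(lengths["b"], 0.5 * (0.3 + 0.6 - 0.5))
    assert math.isclose(lengths["c"], 0.5 * (0.5 + 0.6 - 0.3))


def test_four_taxon_additive_quartet():
    # tree ((a:1,b:2):1,(c:3,d:4)) -> unique quartet ab|cd
    dist = {
        frozenset("ab"): 3.0,
        frozenset("ac"): 5.0, frozenset("ad"): 6.0,
        frozenset("bc"): 6.0, frozenset("bd"): 7.0,
        frozenset("cd"): 7.0,
    }
    taxa = ("a", "b", "c", "d")
    m = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i != j:
                m[i, j] = dist[frozenset((taxa[i], taxa[j]))]
    tree = neighbor_joining(DistanceMatrix(taxa=taxa, matrix=m))
    assert tree.find_clade({"a", "b"}) or tree.find_clade({"c", "d"})


@pytest.mark.parametrize("seed,n", [(0, 5), (1, 7), (2, 8), (3, 10)])
def test_nj_exact_on_additive_matrices(seed, n):
    rng = np.random.default_rng(seed)
    dist, true_splits, total = random_additive_tree(n, rng)
    tree = neighbor_joining(to_matrix(dist, n))
    assert tree.bipartitions() == true_splits
    # NJ reproduces the total length of an additive tree
    recovered = 0.0

    def walk(node):
        nonlocal recovered
        for child, bl in node.children:
            recovered += bl
            walk(child)

    walk(tree)
    assert math.isclose(recovered, total, rel_tol=1e-9)


def test_nj_topology_agrees_with_dendropy():
    dendropy = pytest.importorskip("dendropy")
    from io import StringIO

    rng = np.random.default_rng(6)
    n = 8
    dist, true_splits, _ = random_additive_tree(n, rng)
    taxa = [f"t{i}" for i in range(n)]
    lines = ["," + ",".join(taxa)]
    for a in taxa:
        row = [a] + [
            "0" if a == b else str(dist[frozenset((a, b))]) for b in taxa
        ]
        lines.append(",".join(row))
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=StringIO("\n".join(lines)), delimiter=","
    )
    dtree = pdm.nj_tree()
    all_leaves = frozenset(taxa)
    anchor = min(all_leaves)
    dsplits = set()
    for nd in dtree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        if 1 < len(below) < n - 1:
            dsplits.add(below if anchor not in below else all_leaves - below)
    assert dsplits == true_splits  # and therefore equals our NJ topology


def test_nj_rejects_fewer_than_three_taxa():
    m = np.zeros((2, 2))
    with pytest.raises(PhyloError):
        neighbor_joining(DistanceMatrix(taxa=("a", "b"), matrix=m))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

SISTER_TREE = [
    ([("A_one", 0.01), ("A_two", 0.01)], 0.25),
    ([("B_one", 0.12), ("B_two", 0.12), ([("C_one", 0.05), ("C_two", 0.05)], 0.2)], 0.25),
]


def test_bootstrap_deterministic_for_fixed_seed():
    rng = np.random.default_rng(0)
    root = random_protein(300, rng)
    aln = evolve_proteins(root, SISTER_TREE, seed=5)
    t1 = bootstrap_support([aln], n_replicates=30, seed=11)
    t2 = bootstrap_support([aln], n_replicates=30, seed=11)
    assert t1.to_newick() == t2.to_newick()


def test_single_replicate_supports_are_zero_or_hundred():
    rng = np.random.default_rng(1)
    root = random_protein(200, rng)
    aln = evolve_proteins(root, SISTER_TREE, seed=2)
    tree = bootstrap_support([aln], n_replicates=1, seed=3)
    sups = []

    def collect(node):
        if node.support is not None:
            sups.append(node.support)
        for c, _ in node.children:
            collect(c)

    collect(tree)
    assert sups and all(s in (0.0, 100.0) for s in sups)


def test_clearly_separated_sisters_get_high_support():
    rng = np.random.default_rng(2)
    root = random_protein(400, rng)
    aln = evolve_proteins(root, SISTER_TREE, seed=7)
    tree = bootstrap_support([aln], n_replicates=100, seed=13)
    assert tree.find_clade({"A_one", "A_two"})

    def support_of(node, labels):
        for c, _ in node.children:
            r = support_of(c, labels)
            if r is not None:
                return r
        if not node.is_leaf and set(node.leaves()) == labels:
            return node.support
        return None

    assert support_of(tree, {"A_one", "A_two"}) > 95


def test_sixteen_taxon_sister_pair_recovered():
    # two near-identical taxa inside a 16-taxon radiation come out as sisters
    rng = np.random.default_rng(3)
    root = random_protein(350, rng)
    others = [(f"x{i:02d}", 0.10 + 0.01 * i) for i in range(14)]
    tree_spec = [
        ([("sister_a", 0.01), ("sister_b", 0.01)], 0.2),
        ([(name, p) for name, p in others], 0.05),
    ]
    aln = evolve_proteins(root, tree_spec, seed=9)
    assert len(aln) == 16
    tree = nj_tree_from_alignment(aln)
    assert tree.find_clade({"sister_a", "sister_b"})
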