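"""Pairwise protein identity and neighbor-joining phylogenetics.

Identity between homologous mitochondrial proteins is computed from a
Needleman-Wunsch global alignment (default scoring: match +1, mismatch 0,
gap -1) as ``100 * matches / alignment columns`` with gap columns included
in the denominator (switchable).  Trees are built by the canonical
Saitou-Nei neighbor-joining agglomeration on p-distances, with
deterministic tie-breaking and non-parametric bootstrap over alignment
columns for branch support.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# global alignment & identity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float            # percent
    matches: int
    columns: int


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def global_align(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
    count_gap_columns: bool = True,
) -> AlignmentResult:
    """Optimal global alignment and percent identity of two proteins."""
    if not seq_a or not seq_b:
        raise PhyloError("empty sequence")
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(a, b))
    columns = len(a) if count_gap_columns else sum(
        x != "-" and y != "-" for x, y in zip(a, b)
    )
    return AlignmentResult(
        aligned_a=a,
        aligned_b=b,
        score=aln.score,
        identity=100.0 * matches / columns if columns else 0.0,
        matches=matches,
        columns=columns,
    )


def pairwise_identity_table(genes: dict[str, tuple[str, str]], **scoring):
    """Per-gene identity between two genomes' homologous proteins.

    ``genes`` maps gene name -> (protein_a, protein_b).
    """
    import pandas as pd

    rows = []
    for gene, (pa, pb) in genes.items():
        res = global_align(pa, pb, **scoring)
        rows.append({"gene": gene, "aa_a": len(pa), "aa_b": len(pb),
                     "identity": round(res.identity, 1)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise PhyloError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise PhyloError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise PhyloError("nonzero diagonal")

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.matrix[i, j])


def concatenate_alignments(alignments: list[dict[str, str]]) -> dict[str, str]:
    """Concatenate per-gene alignments sharing one taxon set (supermatrix)."""
    if not alignments:
        raise PhyloError("no alignments")
    taxa = set(alignments[0])
    for aln in alignments:
        if set(aln) != taxa:
            raise PhyloError(f"taxon sets differ: {sorted(set(aln) ^ taxa)}")
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            raise PhyloError("ragged alignment block")
    return {t: "".join(aln[t] for aln in alignments) for t in sorted(taxa)}


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites over columns ungapped in both."""
    comparable = mismatches = 0
    for x, y in zip(seq_a, seq_b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        mismatches += x != y
    if comparable == 0:
        raise PhyloError("no comparable columns")
    return mismatches / comparable


def p_distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """Pairwise p-distances from one (super)alignment, taxa sorted."""
    taxa = tuple(sorted(alignment))
    n = len(taxa)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = p_distance(alignment[taxa[i]], alignment[taxa[j]])
        m[i, j] = m[j, i] = d
    return DistanceMatrix(taxa=taxa, matrix=m)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of an (unrooted) phylogeny; the root is the final NJ join."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode, length: float | None) -> str:
            if node.is_leaf:
                body = node.label
            else:
                inner = ",".join(fmt(c, bl) for c, bl in node.children)
                sup = ""
                if with_support and node.support is not None:
                    sup = f"{node.support:g}"
                body = f"({inner}){sup}"
            return body if length is None else f"{body}:{length:.6f}"

        return fmt(self, None) + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized as one leaf-label side."""
        all_leaves = frozenset(self.leaves())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                splits.add(side)
            return below

        walk(self)
        return splits

    def find_clade(self, labels: set[str]) -> bool:
        """True when some edge separates exactly ``labels`` from the rest."""
        side = frozenset(labels)
        all_leaves = frozenset(self.leaves())
        anchor = min(all_leaves)
        want = side if anchor not in side else all_leaves - side
        return want in self.bipartitions()


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken toward the lexicographically lowest
    cluster-label pair; negative branch lengths are clamped to zero with a
    warning.
    """
    n = len(dm.taxa)
    if n < 3:
        raise PhyloError("neighbor joining needs >= 3 taxa")
    nodes: dict[str, TreeNode] = {t: TreeNode(label=t) for t in dm.taxa}
    # cluster key -> sorted leaf tuple used for deterministic tie-breaks
    keys: dict[str, tuple[str, ...]] = {t: (t,) for t in dm.taxa}
    d: dict[tuple[str, str], float] = {}
    active = list(dm.taxa)
    for i, a in enumerate(dm.taxa):
        for j, b in enumerate(dm.taxa):
            d[(a, b)] = float(dm.matrix[i, j])

    def clamp(x: float, context: str) -> float:
        if x < -1e-12:
            warnings.warn(f"negative branch length {x:.4g} clamped to 0 ({context})",
                          stacklevel=3)
        return max(x, 0.0)

    counter = itertools.count()
    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active, key=lambda t: keys[t]), 2):
            q = (m - 2) * d[(a, b)] - r[a] - r[b]
            cand = (q, keys[a], keys[b], a, b)
            if best is None or cand[:3] < best[:3]:
                best = cand
        _, _, _, a, b = best
        dab = d[(a, b)]
        la = clamp(0.5 * dab + (r[a] - r[b]) / (2 * (m - 2)), f"{a}")
        lb = clamp(dab - la, f"{b}")
        new = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        key = f"__nj{next(counter)}"
        nodes[key] = new
        keys[key] = tuple(sorted(keys[a] + keys[b]))
        for c in active:
            if c in (a, b):
                continue
            d[(key, c)] = d[(c, key)] = 0.5 * (d[(a, c)] + d[(b, c)] - dab)
        d[(key, key)] = 0.0
        active = [c for c in active if c not in (a, b)] + [key]
    a, b, c = sorted(active, key=lambda t: keys[t])
    la = clamp(0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)]), a)
    lb = clamp(0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)]), b)
    lc = clamp(0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)]), c)
    return TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])


def nj_tree_from_alignment(alignment: dict[str, str]) -> TreeNode:
    return neighbor_joining(p_distance_matrix(alignment))


def bootstrap_support(
    alignments: list[dict[str, str]],
    n_replicates: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """NJ tree on the concatenated alignment, internal edges annotated with
    bootstrap support (percent of column-resampled replicates containing the
    same bipartition)."""
    if n_replicates < 1:
        raise PhyloError("n_replicates must be >= 1")
    supermatrix = concatenate_alignments(alignments)
    taxa = sorted(supermatrix)
    if len(taxa) < 4:
        warnings.warn("fewer than 4 taxa: no internal bipartitions to support",
                      stacklevel=2)
    tree = nj_tree_from_alignment(supermatrix)
    ncols = len(next(iter(supermatrix.values())))
    rows = {t: np.frombuffer(supermatrix[t].encode(), dtype="S1") for t in taxa}
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncols, size=ncols)
        resampled = {t: rows[t][cols].tobytes().decode() for t in taxa}
        rep = nj_tree_from_alignment(resampled)
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    def annotate(node: TreeNode, all_leaves: frozenset[str], anchor: str) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(annotate(c, all_leaves, anchor) for c, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            node.support = 100.0 * counts[side] / n_replicates
        return below

    leaves = frozenset(tree.leaves())
    annotate(tree, leaves, min(leaves))
    return tree


__all__ = [
    "PhyloError",
    "AlignmentResult",
    "global_align",
    "pairwise_identity_table",
    "DistanceMatrix",
    "concatenate_alignments",
    "p_distance",
    "p_distance_matrix",
    "TreeNode",
    "neighbor_joining",
    "nj_tree_from_alignment",
    "bootstrap_support",
]
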