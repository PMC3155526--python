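"""tRNA cloverleaf auditing and A+T-rich control-region element scanning.

Cloverleaf structures are *inputs* (arm span tables or dot-bracket
strings); no folding is attempted.  A stem pair is a mismatch when the two
bases are not a Watson-Crick pair — G.T wobble counts as a mismatch by
default, matching how mitochondrial tRNA stem mismatches are usually
tallied, with an optional wobble mode that accepts it.

The control-region scanner looks for the five canonical elements of the
insect A+T-rich region: a 5' polyT stretch, a [TA(A)]n-like repeat, a
stem-loop (inverted repeat), TATA and G(A)nT motifs, and G+A-rich
stretches.  Thresholds are explicit parameters echoed into reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .composition import base_composition
from .genome_model import revcomp

WATSON_CRICK = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})
WOBBLE = WATSON_CRICK | {("G", "T"), ("T", "G")}

ARM_NAMES = ("acceptor", "D", "anticodon", "T")


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class Cloverleaf:
    """tRNA secondary structure as per-arm paired index lists (0-based).

    Each arm maps to a list of (i, j) pairs with i on the 5' side (strictly
    increasing) and j on the 3' side (strictly decreasing).  Absent arms are
    simply missing from ``arms``.
    """

    arms: dict[str, tuple[tuple[int, int], ...]]
    loops: dict[str, tuple[int, int]] = field(default_factory=dict)
    anticodon_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        used: set[int] = set()
        for arm, pairs in self.arms.items():
            if arm not in ARM_NAMES:
                raise StructureError(f"unknown arm {arm!r}")
            five = [i for i, _ in pairs]
            three = [j for _, j in pairs]
            if five != sorted(five) or len(set(five)) != len(five):
                raise StructureError(f"{arm}: 5' indices not strictly increasing")
            if three != sorted(three, reverse=True) or len(set(three)) != len(three):
                raise StructureError(f"{arm}: 3' indices not strictly decreasing")
            for idx in five + three:
                if idx in used:
                    raise StructureError(f"index {idx} used twice")
                used.add(idx)

    @property
    def present_arms(self) -> frozenset[str]:
        return frozenset(a for a, pairs in self.arms.items() if pairs)


@dataclass(frozen=True)
class StemMismatch:
    arm: str
    pair_index: int
    i: int
    j: int
    bases: tuple[str, str]


def count_stem_mismatches(
    trna_seq: str,
    structure: Cloverleaf,
    allowed_pairs: frozenset[tuple[str, str]] = WATSON_CRICK,
) -> list[StemMismatch]:
    """Audit every stem pair of a tRNA against an allowed-pair alphabet."""
    seq = trna_seq.upper().replace("U", "T")
    out = []
    for arm in ARM_NAMES:
        for k, (i, j) in enumerate(structure.arms.get(arm, ())):
            if not (0 <= i < len(seq) and 0 <= j < len(seq)):
                raise StructureError(f"{arm} pair ({i},{j}) outside sequence of length {len(seq)}")
            bases = (seq[i], seq[j])
            if bases not in allowed_pairs:
                out.append(StemMismatch(arm=arm, pair_index=k, i=i, j=j, bases=bases))
    return out


@dataclass(frozen=True)
class ArmCensus:
    present: frozenset[str]
    missing: frozenset[str]
    is_cloverleaf: bool


def arm_census(structure: Cloverleaf) -> ArmCensus:
    """Classify a structure as a full cloverleaf or degenerate (missing arms)."""
    present = structure.present_arms
    missing = frozenset(ARM_NAMES) - present
    return ArmCensus(present=present, missing=missing, is_cloverleaf=not missing)


def cloverleaf_from_dotbracket(dotbracket: str, missing_arm: str | None = None) -> Cloverleaf:
    """Convert a flat dot-bracket string into a Cloverleaf.

    The outermost stem is the acceptor; the hairpins are assigned 5'->3' as
    D, anticodon, T arms.  With only two hairpins the D arm is taken as the
    missing one unless ``missing_arm`` says otherwise.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise StructureError("unbalanced dot-bracket")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise StructureError(f"bad dot-bracket character {ch!r}")
    if stack:
        raise StructureError("unbalanced dot-bracket")
    pairs.sort()
    # group pairs into helices: maximal runs of directly stacked pairs
    helices: list[list[tuple[int, int]]] = []
    for p in pairs:
        last = helices[-1][-1] if helices else None
        if last and p == (last[0] + 1, last[1] - 1):
            helices[-1].append(p)
        else:
            helices.append([p])
    if not helices:
        raise StructureError("no pairs in structure")
    acceptor = helices[0]
    hairpins = helices[1:]
    for h in hairpins:
        inner = h[-1]
        if any(inner[0] < p[0] < inner[1] for p in pairs if p not in h):
            raise StructureError("unsupported structure: nested/bulged helices")
    if len(hairpins) == 3:
        names = ["D", "anticodon", "T"]
    elif len(hairpins) == 2:
        absent = missing_arm or "D"
        names = [a for a in ("D", "anticodon", "T") if a != absent]
    else:
        names = ["anticodon"][: len(hairpins)]
    arms = {"acceptor": tuple(acceptor)}
    loops = {}
    for name, helix in zip(names, hairpins):
        arms[name] = tuple(helix)
        inner = helix[-1]
        loops[name] = (inner[0] + 1, inner[1] - 1)
    anticodon_span = None
    if "anticodon" in loops:
        lo, hi = loops["anticodon"]
        mid = (lo + hi) // 2
        anticodon_span = (mid - 1, mid + 1)
    return Cloverleaf(arms=arms, loops=loops, anticodon_span=anticodon_span)


# ---------------------------------------------------------------------------
# control-region element scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanParams:
    min_polyT: int = 5
    min_taa_units: int = 3
    ga_window: int = 20
    ga_fraction: float = 0.8
    min_stem: int = 6
    min_loop: int = 3
    max_loop: int = 20


@dataclass(frozen=True)
class ElementHit:
    kind: str                  # polyT | TAA_repeat | TATA | GAnT | GA_rich | stem_loop
    start: int                 # 0-based, inclusive
    end: int                   # 0-based, exclusive
    detail: dict = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ControlRegionReport:
    hits: list[ElementHit]
    at_content: float
    params: ScanParams

    def of_kind(self, kind: str) -> list[ElementHit]:
        return [h for h in self.hits if h.kind == kind]


def _scan_polyt(seq: str, params: ScanParams):
    for m in re.finditer(r"T+", seq):
        if m.end() - m.start() >= params.min_polyT:
            yield ElementHit("polyT", m.start(), m.end(),
                             {"length": m.end() - m.start()})


def _scan_taa(seq: str, params: ScanParams):
    # greedy runs of TAA/TA units; [TA(A)]n-like means mixed units allowed
    for m in re.finditer(r"(?:TAA|TA)+", seq):
        text = m.group(0)
        units = 0
        i = 0
        while i < len(text):
            if text.startswith("TAA", i):
                i += 3
            else:
                i += 2
            units += 1
        if units >= params.min_taa_units:
            yield ElementHit("TAA_repeat", m.start(), m.end(), {"units": units})


def _scan_tata(seq: str):
    i = seq.find("TATA")
    while i != -1:
        yield ElementHit("TATA", i, i + 4)
        i = seq.find("TATA", i + 1)


def _scan_gant(seq: str):
    for m in re.finditer(r"GA+T", seq):
        yield ElementHit("GAnT", m.start(), m.end(), {"n": m.end() - m.start() - 2})


def _scan_ga_rich(seq: str, params: ScanParams):
    w = params.ga_window
    if len(seq) < w:
        return
    hot = [i for i in range(len(seq) - w + 1)
           if sum(c in "GA" for c in seq[i : i + w]) / w >= params.ga_fraction]
    # merge overlapping qualifying windows into maximal segments
    start = None
    prev = None
    for i in hot:
        if start is None:
            start, prev = i, i
        elif i <= prev + w:
            prev = i
        else:
            yield ElementHit("GA_rich", start, prev + w)
            start, prev = i, i
    if start is not None:
        yield ElementHit("GA_rich", start, prev + w)


def find_stem_loops(seq: str, params: ScanParams) -> list[ElementHit]:
    """Maximal inverted repeats: stem >= min_stem, loop within bounds.

    A hit spans ``[i, i + 2*stem + loop)``; only outward-maximal stems are
    reported (extending one more pair on the outside fails or leaves the
    sequence), and inner-contained duplicates of the same loop are dropped.
    """
    n = len(seq)
    hits = []
    pair = lambda a, b: (a, b) in WATSON_CRICK
    for loop in range(params.min_loop, params.max_loop + 1):
        for mid in range(n):
            # mid = start of loop; stem grows outward from (mid-1, mid+loop)
            stem = 0
            while (
                mid - stem - 1 >= 0
                and mid + loop + stem < n
                and pair(seq[mid - stem - 1], seq[mid + loop + stem])
            ):
                stem += 1
            if stem >= params.min_stem:
                start = mid - stem
                end = mid + loop + stem
                hits.append(
                    ElementHit("stem_loop", start, end,
                               {"stem": stem, "loop": loop})
                )
    # drop hits strictly contained in a longer hit with >= stem
    keep = []
    for h in hits:
        contained = any(
            o is not h
            and o.start <= h.start
            and o.end >= h.end
            and (o.detail["stem"], o.end - o.start) >= (h.detail["stem"], h.end - h.start)
            and (o.start, o.end) != (h.start, h.end)
            for o in hits
        )
        if not contained and h.span not in {k.span for k in keep}:
            keep.append(h)
    keep.sort(key=lambda h: (h.start, h.end))
    return keep


def scan_control_region(seq: str, params: ScanParams | None = None) -> ControlRegionReport:
    """Scan an A+T-rich region for its characteristic elements."""
    if not seq:
        raise StructureError("empty control-region sequence")
    params = params or ScanParams()
    s = seq.upper().replace("U", "T")
    hits: list[ElementHit] = []
    hits.extend(_scan_polyt(s, params))
    hits.extend(_scan_taa(s, params))
    hits.extend(_scan_tata(s))
    hits.extend(_scan_gant(s))
    hits.extend(_scan_ga_rich(s, params))
    hits.extend(find_stem_loops(s, params))
    hits.sort(key=lambda h: (h.start, h.end, h.kind))
    _, freqs = base_composition(s)
    return ControlRegionReport(
        hits=hits,
        at_content=100.0 * (freqs["A"] + freqs["T"]),
        params=params,
    )


def find_shared_motifs(spacer_a: str, spacer_b: str, k: int
                       ) -> list[tuple[str, list[int], list[int]]]:
    """All k-mers shared by two spacer sequences, with positions in each."""
    if k < 4:
        raise StructureError("k must be >= 4")
    if not spacer_a or not spacer_b:
        raise StructureError("empty spacer sequence")
    a, b = spacer_a.upper(), spacer_b.upper()
    if k > min(len(a), len(b)):
        import warnings

        warnings.warn(f"k={k} exceeds shortest spacer; no motifs possible", stacklevel=2)
        return []

    def kmer_positions(s: str) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i in range(len(s) - k + 1):
            out.setdefault(s[i : i + k], []).append(i)
        return out

    pa, pb = kmer_positions(a), kmer_positions(b)
    return [(m, pa[m], pb[m]) for m in sorted(set(pa) & set(pb))]


__all__ = [
    "WATSON_CRICK",
    "WOBBLE",
    "ARM_NAMES",
    "StructureError",
    "Cloverleaf",
    "StemMismatch",
    "count_stem_mismatches",
    "ArmCensus",
    "arm_census",
    "cloverleaf_from_dotbracket",
    "ScanParams",
    "ElementHit",
    "ControlRegionReport",
    "scan_control_region",
    "find_stem_loops",
    "find_shared_motifs",
]
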