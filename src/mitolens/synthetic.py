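"""Synthetic annotated mitogenomes with known ground truth.

The generator emulates the statistical structure of a honeybee-like
mitogenome: a ~16 kb circle carrying 13 protein-coding genes, 22 tRNAs,
2 rRNAs and one A+T-rich control region, with ~84% A+T, strand-asymmetric
GC skew, codon usage sampled from a published codon-count spectrum, exact
planted gaps/overlaps, planted control-region elements, planted tRNA
cloverleaves with a chosen number of stem mismatches, and planted
rearrangements relative to a reference gene order.  Every random draw flows
from one explicit seed; the truth object is serializable as JSON so tests
never re-derive it.

Layout defaults reproduce the published A. cerana gene plan (lengths,
strands, signed spacers), so layout statistics are recovered exactly by
construction.  Where a tRNA span overlaps a protein-coding gene the PCG
sequence wins, so that tRNA's planted structure is not guaranteed; the
truth records which structure truths hold.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import reference
from .codon_usage import CODON_TO_AA, SENSE_CODONS, translate_codon
from .genome_model import GeneFeature, MitoGenome, revcomp
from .rearrangement import GeneOrder, plant_inversion, plant_move
from .structure_motifs import (
    Cloverleaf,
    ScanParams,
    WATSON_CRICK,
    find_stem_loops,
    scan_control_region,
)

_COMPL = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: H-strand background frequencies outside coding sequence (published Total)
DEFAULT_BACKGROUND = {"A": 0.423, "G": 0.063, "T": 0.416, "C": 0.098}
#: control-region background (the real region is ~95% A+T)
DEFAULT_CR_BACKGROUND = {"A": 0.48, "G": 0.02, "T": 0.475, "C": 0.025}


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class FeaturePlan:
    """One feature slot: identity, length and the signed spacer to the next."""

    name: str
    feature_class: str
    strand: str
    length: int
    spacer_after: int = 0
    start_codon: str = "ATT"
    anticodon: str | None = None


def apis_cerana_plan() -> list[FeaturePlan]:
    """The published A. cerana gene plan as a FeaturePlan list."""
    genome = reference.apis_cerana_annotation()
    feats = genome.features
    plans = []
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        if i + 1 < len(feats):
            spacer = nxt.start - f.end - 1
        else:
            spacer = (genome.length - f.end) + (nxt.start - 1)
        start_codon = reference.APIS_CERANA_START_STOP.get(f.name, ("ATT", "TAA"))[0]
        plans.append(
            FeaturePlan(
                name=f.name,
                feature_class=f.feature_class,
                strand=f.strand,
                length=f.length,
                spacer_after=spacer,
                start_codon=start_codon,
                anticodon=f.anticodon,
            )
        )
    return plans


@dataclass(frozen=True)
class PlantedElement:
    kind: str
    offset: int                # 0-based within the control region
    length: int
    detail: dict = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        return (self.offset, self.offset + self.length)


def default_control_elements() -> list[PlantedElement]:
    """A five-element plan mirroring the canonical insect A+T-rich layout:
    5' polyT, then a [TA(A)]n stretch, a stem-loop flanked by TATA and
    G(A)nT motifs, and a G+A-rich stretch downstream."""
    return [
        PlantedElement("polyT", 6, 9),
        PlantedElement("TAA_repeat", 30, 12, {"units": 4}),       # TAA x4
        PlantedElement("TATA", 60, 4),
        PlantedElement("stem_loop", 80, 22, {"stem": 8, "loop": 6}),
        PlantedElement("GAnT", 120, 6, {"n": 4}),
        PlantedElement("GA_rich", 150, 20),
    ]


#: default planted stem mismatches: six, on overlap-free tRNAs
DEFAULT_TRNA_MISMATCHES = {
    "trnA": ("acceptor", ("G", "T")),
    "trnQ": ("acceptor", ("T", "T")),
    "trnV": ("anticodon", ("T", "T")),
    "trnH": ("D", ("G", "T")),
    "trnP": ("D", ("G", "T")),
    "trnT": ("D", ("G", "T")),
}


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for exact downstream recovery."""

    seed: int
    genome_length: int
    coordinates: dict[str, tuple[int, int]]
    strands: dict[str, str]
    spacers: dict[str, int]                  # upstream feature -> signed spacer
    codon_weights: dict[str, int]
    background: dict[str, float]
    cr_background: dict[str, float]
    control_elements: list[PlantedElement]
    control_region: str | None               # feature name
    trna_mismatch_plan: dict[str, tuple[str, tuple[str, str]]]
    structure_guaranteed: dict[str, bool]
    structures: dict[str, Cloverleaf] = field(default_factory=dict)
    stem_loop_scan_min_stem: int = 8

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["structures"] = {
            g: {arm: list(map(list, pairs)) for arm, pairs in cl.arms.items()}
            for g, cl in self.structures.items()
        }
        payload["control_elements"] = [dataclasses.asdict(e) for e in self.control_elements]
        return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# cloverleaf templates
# ---------------------------------------------------------------------------

_SEGMENTS = ("acc5", "link1", "d5", "dloop", "d3", "link2", "ac5", "acloop",
             "ac3", "var", "t5", "tloop", "t3", "acc3")


def _template_sizes(length: int, with_d_arm: bool) -> dict[str, int]:
    sizes = {
        "acc5": 7, "link1": 2, "d5": 4, "dloop": 5, "d3": 4, "link2": 1,
        "ac5": 5, "acloop": 7, "ac3": 5, "var": 4, "t5": 5, "tloop": 5,
        "t3": 5, "acc3": 7,
    }
    if not with_d_arm:
        sizes["d5"] = sizes["d3"] = 0
        sizes["dloop"] = 4          # unpaired D-replacement loop
    delta = length - sum(sizes.values())
    grow = [("dloop", 10), ("tloop", 10), ("var", 7), ("acloop", 9), ("link1", 4)]
    shrink = [("var", 2), ("dloop", 4 if with_d_arm else 3), ("tloop", 4), ("link1", 1)]
    while delta > 0:
        progressed = False
        for seg, cap in grow:
            if delta == 0:
                break
            if sizes[seg] < cap:
                sizes[seg] += 1
                delta -= 1
                progressed = True
        if delta > 0 and not progressed:
            sizes["tloop"] += delta      # very long tRNAs: pad the T loop
            delta = 0
    while delta < 0:
        progressed = False
        for seg, floor in shrink:
            if delta == 0:
                break
            if sizes[seg] > floor:
                sizes[seg] -= 1
                delta += 1
                progressed = True
        if delta < 0 and not progressed:
            raise SyntheticError(f"cannot fit cloverleaf into {length} nt")
    return sizes


def make_cloverleaf(length: int, with_d_arm: bool = True) -> Cloverleaf:
    """Parametric cloverleaf with arm spans fitted to a tRNA length."""
    sz = _template_sizes(length, with_d_arm)
    pos = {}
    cursor = 0
    for seg in _SEGMENTS:
        pos[seg] = (cursor, cursor + sz[seg])
        cursor += sz[seg]
    assert cursor == length

    def stem(seg5: str, seg3: str) -> tuple[tuple[int, int], ...]:
        s5, e5 = pos[seg5]
        s3, e3 = pos[seg3]
        n = e5 - s5
        return tuple((s5 + k, e3 - 1 - k) for k in range(n))

    arms = {"acceptor": stem("acc5", "acc3"),
            "anticodon": stem("ac5", "ac3"),
            "T": stem("t5", "t3")}
    loops = {"anticodon": (pos["acloop"][0], pos["acloop"][1] - 1),
             "T": (pos["tloop"][0], pos["tloop"][1] - 1)}
    if with_d_arm:
        arms["D"] = stem("d5", "d3")
        loops["D"] = (pos["dloop"][0], pos["dloop"][1] - 1)
    mid = (pos["acloop"][0] + pos["acloop"][1] - 1) // 2
    return Cloverleaf(arms=arms, loops=loops, anticodon_span=(mid - 1, mid + 1))


# ---------------------------------------------------------------------------
# sequence builders
# ---------------------------------------------------------------------------


def _draw(rng: np.random.Generator, freqs: dict[str, float], n: int) -> str:
    bases = np.array(list(freqs))
    p = np.array([freqs[b] for b in bases], dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(bases, size=n, p=p))


def sample_cds(
    length: int,
    rng: np.random.Generator,
    codon_weights: dict[str, int] | None = None,
    start_codon: str = "ATT",
) -> str:
    """In-frame CDS: planted start, RSCU-profiled middle codons, TAA stop."""
    if length % 3 != 0 or length < 9:
        raise SyntheticError(f"CDS length {length} not a multiple of 3 (>= 9)")
    weights = codon_weights or reference.APIS_CERANA_CODON_COUNTS
    codons = [c for c in SENSE_CODONS if weights.get(c, 0) > 0]
    p = np.array([weights[c] for c in codons], dtype=float)
    p /= p.sum()
    n_middle = length // 3 - 2
    middle = rng.choice(np.array(codons), size=n_middle, p=p)
    return start_codon + "".join(middle) + "TAA"


def sample_trna(
    length: int,
    rng: np.random.Generator,
    freqs: dict[str, float],
    with_d_arm: bool = True,
    mismatch: tuple[str, tuple[str, str]] | None = None,
) -> tuple[str, Cloverleaf, int]:
    """tRNA sequence realizing a cloverleaf; optionally one planted mismatch.

    Returns (sequence, structure, n_planted_mismatches).
    """
    structure = make_cloverleaf(length, with_d_arm=with_d_arm)
    seq = list(_draw(rng, freqs, length))
    for arm, pairs in structure.arms.items():
        for i, j in pairs:
            seq[j] = _COMPL[seq[i]]
    planted = 0
    if mismatch is not None:
        arm, (b5, b3) = mismatch
        pairs = structure.arms.get(arm)
        if not pairs:
            raise SyntheticError(f"no {arm} arm to plant a mismatch in")
        i, j = pairs[len(pairs) // 2]
        seq[i], seq[j] = b5, b3
        if (b5, b3) in WATSON_CRICK:
            raise SyntheticError(f"{b5}-{b3} is not a mismatch")
        planted = 1
    return "".join(seq), structure, planted


def _element_payload(elem: PlantedElement, rng: np.random.Generator) -> str:
    kind = elem.kind
    if kind == "polyT":
        return "T" * elem.length
    if kind == "TAA_repeat":
        units = elem.detail.get("units", elem.length // 3)
        if units * 3 != elem.length:
            raise SyntheticError("TAA_repeat length must be 3 * units")
        return "TAA" * units
    if kind == "TATA":
        return "TATA"
    if kind == "GAnT":
        n = elem.detail.get("n", elem.length - 2)
        return "G" + "A" * n + "T"
    if kind == "GA_rich":
        return "".join(rng.choice(np.array(["G", "A"]), size=elem.length, p=[0.3, 0.7]))
    if kind == "stem_loop":
        stem = elem.detail.get("stem", 8)
        loop = elem.detail.get("loop", elem.length - 2 * stem)
        if 2 * stem + loop != elem.length:
            raise SyntheticError("stem_loop length must be 2*stem + loop")
        for _ in range(100):
            five = "".join(rng.choice(np.array(["A", "C", "G", "T"]), size=stem,
                                      p=[0.3, 0.2, 0.2, 0.3]))
            # avoid homopolymer runs that would double as polyT/polyA hits
            if any(b * 4 in five for b in "ACGT"):
                continue
            return five + "A" * loop + revcomp(five)
        raise SyntheticError("could not sample a run-free stem")
    raise SyntheticError(f"unknown element kind {kind!r}")


def build_control_region(
    length: int,
    elements: list[PlantedElement],
    rng: np.random.Generator,
    freqs: dict[str, float] | None = None,
    stem_loop_min_stem: int = 8,
    max_repair_rounds: int = 200,
) -> str:
    """AT-rich region carrying the planted elements at exact offsets.

    Background polyT runs and stem-loops (at the planted-stem stringency)
    outside planted spans are repaired away so those two element kinds are
    recoverable exclusively; pervasive soft motifs (TATA, TA(A)n, GA-rich)
    are left to occur naturally in the background as they do in real
    regions.
    """
    freqs = freqs or DEFAULT_CR_BACKGROUND
    seq = list(_draw(rng, freqs, length))
    protected = np.zeros(length, dtype=bool)
    spans = sorted(e.span for e in elements)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if e1 + 2 > s2:                       # +2 leaves room for guard bases
            raise SyntheticError("planted elements overlap or touch")
    if spans and spans[-1][1] + 2 > length:
        raise SyntheticError("planted element past region end")
    for elem in elements:
        payload = _element_payload(elem, rng)
        s, e = elem.span
        if len(payload) != e - s:
            raise SyntheticError(f"{elem.kind}: payload length mismatch")
        seq[s:e] = payload
        protected[s:e] = True
        # guard bases stop background from extending a planted hit
        for g in (s - 2, s - 1, e, e + 1):
            if 0 <= g < length and not protected[g]:
                seq[g] = "C" if elem.kind != "stem_loop" else "A"
                protected[g] = True

    params = ScanParams(min_stem=stem_loop_min_stem)
    planted_spans = {e.span for e in elements}
    for _ in range(max_repair_rounds):
        dirty = False
        text = "".join(seq)
        report = scan_control_region(text, params)
        for hit in report.of_kind("polyT"):
            if hit.span in planted_spans:
                continue
            free = [i for i in range(hit.start, hit.end) if not protected[i]]
            if not free:
                raise SyntheticError("spurious polyT entirely within planted spans")
            mid = free[len(free) // 2]
            seq[mid] = "A" if rng.random() < 0.5 else "C"
            dirty = True
        for hit in find_stem_loops(text, params):
            if hit.span in planted_spans:
                continue
            stem = hit.detail["stem"]
            broken = False
            for k in range(stem):
                for idx in (hit.start + k, hit.end - 1 - k):
                    if not protected[idx]:
                        partner = seq[hit.end - 1 - k if idx == hit.start + k
                                      else hit.start + k]
                        seq[idx] = "C" if partner != "G" else "A"
                        dirty = broken = True
                        break
                if broken:
                    break
            if not broken:
                raise SyntheticError("spurious stem-loop entirely within planted spans")
        if not dirty:
            break
    else:
        raise SyntheticError("control-region repair did not converge")
    return "".join(seq)


# ---------------------------------------------------------------------------
# whole-genome assembly
# ---------------------------------------------------------------------------


def generate_genome(
    plan: list[FeaturePlan] | None = None,
    seed: int = 0,
    codon_weights: dict[str, int] | None = None,
    background: dict[str, float] | None = None,
    cr_background: dict[str, float] | None = None,
    control_elements: list[PlantedElement] | None = None,
    trna_mismatches: dict[str, tuple[str, tuple[str, str]]] | None = None,
    name: str = "synthetic_mitogenome",
) -> tuple[MitoGenome, SyntheticTruth]:
    """Assemble a circular annotated genome honoring every planted property."""
    rng = np.random.default_rng(seed)
    plan = plan if plan is not None else apis_cerana_plan()
    background = background or DEFAULT_BACKGROUND
    cr_background = cr_background or DEFAULT_CR_BACKGROUND
    if control_elements is None:
        control_elements = default_control_elements()
    if trna_mismatches is None:
        trna_mismatches = dict(DEFAULT_TRNA_MISMATCHES)

    # resolve coordinates
    coords: dict[str, tuple[int, int]] = {}
    start = 1
    for fp in plan:
        end = start + fp.length - 1
        if start < 1:
            raise SyntheticError(f"{fp.name}: overlap pushes start before origin")
        coords[fp.name] = (start, end)
        start = end + fp.spacer_after + 1
    genome_length = coords[plan[-1].name][1] + plan[-1].spacer_after
    prev_end = None
    for fp in plan:
        s, e = coords[fp.name]
        if prev_end is not None and e <= prev_end:
            raise SyntheticError(f"{fp.name}: nested within previous feature")
        prev_end = e
    if genome_length < coords[plan[-1].name][1]:
        raise SyntheticError("negative wrap spacer")

    seq = np.full(genome_length, "", dtype=object)

    def write(span: tuple[int, int], strand: str, coding: str, force: bool) -> bool:
        """Write coding-sense sequence; returns True if fully written."""
        s, e = span
        text = coding if strand == "H" else revcomp(coding)
        clean = True
        for off, ch in enumerate(text):
            idx = s - 1 + off
            if seq[idx] == "" or force:
                seq[idx] = ch
            else:
                clean = False
        return clean

    structures: dict[str, Cloverleaf] = {}
    guaranteed: dict[str, bool] = {}
    cr_name = None

    for fp in plan:                                   # PCGs claim first
        if fp.feature_class == "PCG":
            write(coords[fp.name], fp.strand,
                  sample_cds(fp.length, rng, codon_weights, fp.start_codon), force=False)
    for fp in plan:
        if fp.feature_class == "tRNA":
            mism = trna_mismatches.get(fp.name)
            with_d = fp.name != "trnS1"
            trna_seq, structure, _ = sample_trna(
                fp.length, rng, background, with_d_arm=with_d, mismatch=mism
            )
            clean = write(coords[fp.name], fp.strand, trna_seq, force=False)
            structures[fp.name] = structure
            guaranteed[fp.name] = clean
    for fp in plan:
        if fp.feature_class == "noncoding":
            cr_name = fp.name
            cr_seq = build_control_region(
                fp.length, control_elements, rng, cr_background
            )
            write(coords[fp.name], "H", cr_seq, force=False)
    # rRNA spans and all remaining positions: background on the H strand
    free = [idx for idx in range(genome_length) if seq[idx] == ""]
    fill = _draw(rng, background, len(free))
    for idx, ch in zip(free, fill):
        seq[idx] = ch
    # re-stamp PCG start/stop codons so boundary truths always hold
    for fp in plan:
        if fp.feature_class == "PCG":
            s, e = coords[fp.name]
            if fp.strand == "H":
                seq[s - 1 : s + 2] = list(fp.start_codon)
                seq[e - 3 : e] = list("TAA")
            else:
                seq[e - 3 : e] = list(revcomp(fp.start_codon))
                seq[s - 1 : s + 2] = list(revcomp("TAA"))
    # overlap regions serve two reading frames; repair any in-frame internal
    # stop that arises there so codon totals follow the planted lengths
    pcgs = [fp for fp in plan if fp.feature_class == "PCG"]
    for _ in range(50):
        dirty = False
        for fp in pcgs:
            s, e = coords[fp.name]
            sub = "".join(seq[s - 1 : e])
            coding = sub if fp.strand == "H" else revcomp(sub)
            for k in range(1, fp.length // 3 - 1):
                if coding[3 * k : 3 * k + 3] in ("TAA", "TAG"):
                    off = 3 * k + 1          # middle base: TAA->TTA, TAG->TTG
                    if fp.strand == "H":
                        seq[s - 1 + off] = "T"
                    else:
                        seq[e - 1 - off] = "A"
                    dirty = True
        if not dirty:
            break
    else:
        raise SyntheticError("internal-stop repair did not converge")

    features = [
        GeneFeature(
            name=fp.name,
            start=coords[fp.name][0],
            end=coords[fp.name][1],
            strand=fp.strand,
            feature_class=fp.feature_class,
            anticodon=fp.anticodon,
        )
        for fp in plan
    ]
    genome = MitoGenome(
        name=name, length=genome_length, sequence="".join(seq), features=features
    )
    truth = SyntheticTruth(
        seed=seed,
        genome_length=genome_length,
        coordinates=coords,
        strands={fp.name: fp.strand for fp in plan},
        spacers={fp.name: fp.spacer_after for fp in plan},
        codon_weights=dict(codon_weights or reference.APIS_CERANA_CODON_COUNTS),
        background=dict(background),
        cr_background=dict(cr_background),
        control_elements=list(control_elements),
        control_region=cr_name,
        trna_mismatch_plan={
            g: m for g, m in trna_mismatches.items() if guaranteed.get(g, False)
        },
        structure_guaranteed=guaranteed,
        structures=structures,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------


def diverge_genome(
    genome: MitoGenome,
    p_sub: float,
    seed: int = 0,
    protect_boundaries: bool = True,
    name_suffix: str = "_relative",
) -> MitoGenome:
    """Per-site substitutions at rate ``p_sub``; annotation carried over.

    ``protect_boundaries`` keeps every PCG's start and stop triplet intact
    so boundary reports remain valid for the relative.
    """
    if not 0 <= p_sub < 1:
        raise SyntheticError("p_sub must be in [0, 1)")
    rng = np.random.default_rng(seed)
    seq = np.array(list(genome.sequence))
    protected = np.zeros(len(seq), dtype=bool)
    if protect_boundaries:
        for f in genome.features_of_class("PCG"):
            protected[f.start - 1 : f.start + 2] = True
            protected[f.end - 3 : f.end] = True
    hit = (rng.random(len(seq)) < p_sub) & ~protected
    bases = np.array(["A", "C", "G", "T"])
    for idx in np.nonzero(hit)[0]:
        current = seq[idx]
        options = bases[bases != current]
        seq[idx] = options[rng.integers(0, len(options))]
    return MitoGenome(
        name=genome.name + name_suffix,
        length=genome.length,
        sequence="".join(seq),
        features=list(genome.features),
        circular=genome.circular,
    )


def expected_protein_identity(cds: str, p_sub: float) -> float:
    """Exact expected percent amino-acid identity after iid substitution.

    For each codon, enumerate all 64 mutated outcomes (substitutions are
    uniform over the three alternative bases) and sum the probability that
    the encoded amino acid is unchanged.
    """
    from .codon_usage import extract_codons

    codons, _ = extract_codons(cds)
    bases = "ACGT"
    total = 0.0
    for codon in codons:
        aa = translate_codon(codon)
        p_same = 0.0
        for b1 in bases:
            p1 = (1 - p_sub) if b1 == codon[0] else p_sub / 3
            for b2 in bases:
                p2 = (1 - p_sub) if b2 == codon[1] else p_sub / 3
                for b3 in bases:
                    p3 = (1 - p_sub) if b3 == codon[2] else p_sub / 3
                    if translate_codon(b1 + b2 + b3) == aa:
                        p_same += p1 * p2 * p3
        total += p_same
    return 100.0 * total / len(codons)


# ---------------------------------------------------------------------------
# protein evolution along a tree (for NJ / bootstrap tests)
# ---------------------------------------------------------------------------

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(np.array(list(AA_ALPHABET)), size=length))


def mutate_protein(seq: str, p: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < p:
            choices = [a for a in AA_ALPHABET if a != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def evolve_proteins(root: str, tree, seed: int = 0) -> dict[str, str]:
    """Evolve a protein down a tree spec.

    ``tree`` is either a leaf name (str) or a list of ``(subtree, p_branch)``
    pairs; each branch applies iid substitutions at probability ``p_branch``
    per site.  Returns leaf name -> sequence.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}

    def walk(node, seq: str) -> None:
        if isinstance(node, str):
            if node in out:
                raise SyntheticError(f"duplicate leaf {node!r}")
            out[node] = seq
            return
        for subtree, p in node:
            walk(subtree, mutate_protein(seq, p, rng))

    walk(tree, root)
    return out


# ---------------------------------------------------------------------------
# planted rearrangements
# ---------------------------------------------------------------------------


def plant_rearrangements(
    ref: GeneOrder,
    seed: int = 0,
    n_translocations: int = 1,
    n_inversions: int = 1,
    n_shuffles: int = 1,
) -> tuple[GeneOrder, dict[str, frozenset[str]]]:
    """Apply labelled tRNA rearrangements to a reference order.

    Each event touches a distinct tRNA and is constructed so that the
    classifier's attribution is unambiguous (shuffles cross at least two
    neighbors; translocations land alone right after an anchor of a
    different interval).  Returns the rearranged order and the expected
    per-gene event-type map.
    """
    rng = np.random.default_rng(seed)
    order = ref
    expected: dict[str, set[str]] = {}
    used: set[str] = set()
    trnas = list(ref.trnas)

    def pick(candidates: list[str]) -> str:
        free = [g for g in candidates if g not in used]
        if not free:
            raise SyntheticError("not enough tRNAs for requested events")
        g = free[rng.integers(0, len(free))]
        used.add(g)
        return g

    # shuffles first: they need an interval whose residents are all untouched
    for _ in range(n_shuffles):
        # need an untouched interval holding >= 3 untouched tRNAs
        intervals: dict[tuple[str, str], list[str]] = {}
        for g in trnas:
            if g in used:
                continue
            iv = ref.anchor_interval(g)
            if any(t in used for t in ref.interval_residents(iv)):
                continue
            intervals.setdefault(iv, []).append(g)
        eligible = sorted([iv for iv, gs in intervals.items() if len(gs) >= 3])
        if not eligible:
            raise SyntheticError("no interval left for a shuffle")
        iv = eligible[rng.integers(0, len(eligible))]
        residents = list(ref.interval_residents(iv))
        # move the first resident to the end (crosses >= 2 neighbors)
        g = residents[0]
        used.update(residents)
        order = plant_move(order, g, after=residents[-1])
        expected.setdefault(g, set()).add("shuffling")

    for _ in range(n_inversions):
        g = pick(trnas)
        order = plant_inversion(order, g)
        expected.setdefault(g, set()).add("inversion")

    used_anchors: set[str] = set()
    for _ in range(n_translocations):
        g = pick(trnas)
        src = ref.anchor_interval(g)
        anchors = [a for a in ref.anchors if a not in src and a not in used_anchors]
        dest_anchor = anchors[rng.integers(0, len(anchors))]
        used_anchors.add(dest_anchor)
        order = plant_move(order, g, after=dest_anchor)
        expected.setdefault(g, set()).add("translocation")

    return order, {g: frozenset(t) for g, t in expected.items()}


__all__ = [
    "SyntheticError",
    "FeaturePlan",
    "apis_cerana_plan",
    "PlantedElement",
    "default_control_elements",
    "DEFAULT_TRNA_MISMATCHES",
    "DEFAULT_BACKGROUND",
    "DEFAULT_CR_BACKGROUND",
    "SyntheticTruth",
    "make_cloverleaf",
    "sample_cds",
    "sample_trna",
    "build_control_region",
    "generate_genome",
    "diverge_genome",
    "expected_protein_identity",
    "AA_ALPHABET",
    "random_protein",
    "mutate_protein",
    "evolve_proteins",
    "plant_rearrangements",
]
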