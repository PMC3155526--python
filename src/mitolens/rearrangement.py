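"""Classify tRNA gene-order rearrangements against a reference order.

Mitochondrial tRNA rearrangements fall into three categories relative to an
ancestral arrangement: a *translocation* moves a tRNA across a
protein-coding gene (it lands between a different pair of anchor genes); an
*inversion* flips it to the opposite strand; a *shuffling* reorders it
locally, without crossing a protein-coding gene.  Anchors are the 13 PCGs
plus the two rRNAs (no tRNA crosses an rRNA in the honeybee orders), and
the control region acts as an additional fixed boundary marker.

Shuffling needs an attribution rule: when the tRNAs sharing an anchor
interval appear in a different relative order, the genes reported as
shuffled are the minimal set whose relocation explains the reorder (the
complement of a longest common subsequence between the reference-side and
observed-side orders), with ties broken by keeping the lexicographically
smallest gene-name tuple.  The same rule applies to groups of tRNAs
translocated together from one interval to another, so a block that moves
intact is a set of pure translocations, while members that additionally
changed order within the moving block are flagged as shuffled too.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

CONTROL_REGION = "CR"


class RearrangementError(ValueError):
    pass


@dataclass(frozen=True)
class GeneOrder:
    """Circular sequence of signed gene tokens; leading '-' marks the L strand."""

    tokens: tuple[str, ...]
    name: str = "order"

    def __post_init__(self) -> None:
        genes = [t.lstrip("-") for t in self.tokens]
        if len(set(genes)) != len(genes):
            raise RearrangementError(f"{self.name}: duplicate gene tokens")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(t.lstrip("-") for t in self.tokens)

    def sign(self, gene: str) -> int:
        for t in self.tokens:
            if t.lstrip("-") == gene:
                return -1 if t.startswith("-") else 1
        raise KeyError(gene)

    def is_anchor(self, gene: str) -> bool:
        return gene == CONTROL_REGION or not gene.startswith("trn")

    @property
    def anchors(self) -> tuple[str, ...]:
        return tuple(g for g in self.genes if self.is_anchor(g))

    @property
    def trnas(self) -> tuple[str, ...]:
        return tuple(g for g in self.genes if not self.is_anchor(g))

    def anchor_interval(self, gene: str) -> tuple[str, str]:
        """Ordered pair of nearest flanking anchors around a tRNA (circular)."""
        genes = self.genes
        n = len(genes)
        pos = genes.index(gene)
        up = down = None
        for step in range(1, n):
            g = genes[(pos - step) % n]
            if self.is_anchor(g):
                up = g
                break
        for step in range(1, n):
            g = genes[(pos + step) % n]
            if self.is_anchor(g):
                down = g
                break
        if up is None or down is None:
            raise RearrangementError(f"{self.name}: no anchors flanking {gene}")
        return up, down

    def interval_residents(self, interval: tuple[str, str]) -> tuple[str, ...]:
        """tRNAs lying between the two anchors, in circular order."""
        genes = self.genes
        n = len(genes)
        start = genes.index(interval[0])
        out = []
        for step in range(1, n):
            g = genes[(start + step) % n]
            if self.is_anchor(g):
                if g != interval[1]:
                    raise RearrangementError(
                        f"{self.name}: interval {interval} not contiguous"
                    )
                break
            out.append(g)
        return tuple(out)


@dataclass(frozen=True)
class RearrangementEvent:
    gene: str
    event_types: frozenset[str]       # subset of {translocation, inversion, shuffling}
    from_interval: tuple[str, str]
    to_interval: tuple[str, str]
    note: str = ""

    @property
    def translocated(self) -> bool:
        return "translocation" in self.event_types

    @property
    def inverted(self) -> bool:
        return "inversion" in self.event_types

    @property
    def shuffled(self) -> bool:
        return "shuffling" in self.event_types


def _check_comparable(order: GeneOrder, reference: GeneOrder) -> None:
    if set(order.genes) != set(reference.genes):
        raise RearrangementError(
            "token universes differ: "
            f"{sorted(set(order.genes) ^ set(reference.genes))}"
        )
    a, b = order.anchors, reference.anchors
    if set(a) != set(b):
        raise RearrangementError("anchor sets differ")
    # anchors must be in the same circular relative order (rotation allowed)
    doubled = b + b
    for i in range(len(b)):
        if doubled[i : i + len(a)] == a:
            break
    else:
        raise RearrangementError(
            "anchor arrangement differs between orders; the tRNA taxonomy "
            "does not cover PCG/rRNA rearrangements"
        )


def _min_relocation(source: tuple[str, ...], dest: tuple[str, ...]) -> frozenset[str]:
    """Genes to relocate so the rest keep their relative order.

    The kept genes form a longest common subsequence of the two orders;
    among maximum-length choices the lexicographically smallest kept tuple
    wins, which makes attribution deterministic.
    """
    assert set(source) == set(dest)

    # max by length; among equal lengths prefer lexicographically smaller tuple
    def better(a: tuple[int, tuple[str, ...]], b: tuple[int, tuple[str, ...]]):
        if a[0] != b[0]:
            return a if a[0] > b[0] else b
        return a if a[1] <= b[1] else b

    @lru_cache(maxsize=None)
    def solve(i: int, j: int) -> tuple[int, tuple[str, ...]]:
        if i >= len(source) or j >= len(dest):
            return 0, ()
        out = None
        if source[i] == dest[j]:
            ln, kept = solve(i + 1, j + 1)
            out = (ln + 1, (source[i],) + kept)
        for nxt in (solve(i + 1, j), solve(i, j + 1)):
            out = nxt if out is None else better(out, nxt)
        return out

    _, kept = solve(0, 0)
    return frozenset(set(source) - set(kept))


def classify_rearrangements(order: GeneOrder, reference: GeneOrder
                            ) -> list[RearrangementEvent]:
    """Per-tRNA rearrangement events of ``order`` relative to ``reference``."""
    _check_comparable(order, reference)

    intervals_ref = {g: reference.anchor_interval(g) for g in reference.trnas}
    intervals_obs = {g: order.anchor_interval(g) for g in order.trnas}

    shuffled: set[str] = set()

    # residents: tRNAs keeping their interval, compared within that interval
    stay = [g for g in reference.trnas if intervals_ref[g] == intervals_obs[g]]
    for interval in sorted(set(intervals_ref[g] for g in stay)):
        members = [g for g in stay if intervals_ref[g] == interval]
        ref_order = tuple(g for g in reference.interval_residents(interval) if g in members)
        obs_order = tuple(g for g in order.interval_residents(interval) if g in members)
        shuffled |= _min_relocation(ref_order, obs_order)

    # movers: grouped by (source interval, destination interval)
    movers = [g for g in reference.trnas if intervals_ref[g] != intervals_obs[g]]
    routes = sorted(set((intervals_ref[g], intervals_obs[g]) for g in movers))
    for src, dst in routes:
        group = [g for g in movers if intervals_ref[g] == src and intervals_obs[g] == dst]
        if len(group) > 1:
            src_order = tuple(g for g in reference.interval_residents(src) if g in group)
            dst_order = tuple(g for g in order.interval_residents(dst) if g in group)
            shuffled |= _min_relocation(src_order, dst_order)

    events = []
    for g in reference.trnas:
        types = set()
        if intervals_ref[g] != intervals_obs[g]:
            types.add("translocation")
        if reference.sign(g) != order.sign(g):
            types.add("inversion")
        if g in shuffled:
            types.add("shuffling")
        if types:
            events.append(
                RearrangementEvent(
                    gene=g,
                    event_types=frozenset(types),
                    from_interval=intervals_ref[g],
                    to_interval=intervals_obs[g],
                )
            )
    events.sort(key=lambda e: e.gene)
    return events


def shared_events(events_a: list[RearrangementEvent],
                  events_b: list[RearrangementEvent]
                  ) -> list[tuple[RearrangementEvent, RearrangementEvent]]:
    """Events present in both lists (both computed against one reference).

    Two events are shared when gene, destination anchor interval and
    inversion status all agree; shuffling status may differ between the two
    genomes and is preserved per side.
    """
    by_gene_b = {e.gene: e for e in events_b}
    out = []
    for ea in events_a:
        eb = by_gene_b.get(ea.gene)
        if eb is None:
            continue
        if ea.to_interval == eb.to_interval and ea.inverted == eb.inverted:
            out.append((ea, eb))
    return out


# ---------------------------------------------------------------------------
# planting primitives (used by the synthetic generator and property tests)
# ---------------------------------------------------------------------------


def plant_inversion(order: GeneOrder, gene: str) -> GeneOrder:
    tokens = tuple(
        ("-" + t.lstrip("-") if not t.startswith("-") else t.lstrip("-"))
        if t.lstrip("-") == gene else t
        for t in order.tokens
    )
    return GeneOrder(tokens, name=order.name)


def plant_move(order: GeneOrder, gene: str, after: str) -> GeneOrder:
    """Move ``gene`` (keeping its sign) to immediately after ``after``."""
    token = next(t for t in order.tokens if t.lstrip("-") == gene)
    rest = [t for t in order.tokens if t.lstrip("-") != gene]
    idx = next(i for i, t in enumerate(rest) if t.lstrip("-") == after)
    rest.insert(idx + 1, token)
    return GeneOrder(tuple(rest), name=order.name)


__all__ = [
    "CONTROL_REGION",
    "RearrangementError",
    "GeneOrder",
    "RearrangementEvent",
    "classify_rearrangements",
    "shared_events",
    "plant_inversion",
    "plant_move",
]
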