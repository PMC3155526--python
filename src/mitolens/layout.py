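"""Circular gene-layout accounting: signed spacers, overlaps, totals.

On a circular molecule annotated without origin-wrapping features, the
signed spacer between consecutive features (in start order) is
``start(next) - end(prev) - 1``: positive for a gap, zero for abutting
features, negative for an overlap.  The wrap pair (last feature back to the
first) closes the circle, so there are exactly as many adjacency records as
features, and feature lengths, gaps and overlaps conserve the genome
length: sum(lengths) + sum(gaps) - sum(|overlaps|) == genome length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_model import GeneFeature


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class Adjacency:
    upstream: str
    downstream: str
    signed_spacer: int


@dataclass(frozen=True)
class LayoutTotals:
    total_intergenic: int
    n_intergenic_regions: int
    total_overlap: int
    n_overlap_locations: int
    longest_spacer: int
    longest_spacer_pair: tuple[str, str] | None
    genome_length: int
    feature_length_sum: int


@dataclass(frozen=True)
class LayoutReport:
    adjacencies: list[Adjacency]
    genome_length: int
    feature_length_sum: int

    def spacer(self, upstream: str) -> int:
        for a in self.adjacencies:
            if a.upstream == upstream:
                return a.signed_spacer
        raise KeyError(upstream)


def adjacency_spacers(features: list[GeneFeature], genome_length: int) -> LayoutReport:
    """One signed adjacency per consecutive feature pair around the circle."""
    feats = sorted(features, key=lambda f: (f.start, f.end))
    if not feats:
        raise LayoutError("no features")
    offenders = []
    for prev, nxt in zip(feats, feats[1:]):
        if (nxt.start, nxt.end) == (prev.start, prev.end):
            offenders.append(f"{nxt.name} duplicates span of {prev.name}")
        elif nxt.end <= prev.end:
            offenders.append(f"{nxt.name} nested within {prev.name}")
    if offenders:
        raise LayoutError("nested/duplicated spans: " + "; ".join(offenders))
    adjacencies = [
        Adjacency(prev.name, nxt.name, nxt.start - prev.end - 1)
        for prev, nxt in zip(feats, feats[1:])
    ]
    last, first = feats[-1], feats[0]
    if last.end > genome_length:
        raise LayoutError(f"{last.name} ends past genome length {genome_length}")
    wrap = (genome_length - last.end) + (first.start - 1)
    adjacencies.append(Adjacency(last.name, first.name, wrap))
    return LayoutReport(
        adjacencies=adjacencies,
        genome_length=genome_length,
        feature_length_sum=sum(f.length for f in feats),
    )


def summarize_layout(report: LayoutReport) -> LayoutTotals:
    gaps = [a for a in report.adjacencies if a.signed_spacer > 0]
    overlaps = [a for a in report.adjacencies if a.signed_spacer < 0]
    longest = max(report.adjacencies, key=lambda a: a.signed_spacer, default=None)
    return LayoutTotals(
        total_intergenic=sum(a.signed_spacer for a in gaps),
        n_intergenic_regions=len(gaps),
        total_overlap=-sum(a.signed_spacer for a in overlaps),
        n_overlap_locations=len(overlaps),
        longest_spacer=longest.signed_spacer if longest else 0,
        longest_spacer_pair=(longest.upstream, longest.downstream)
        if longest and longest.signed_spacer > 0 else None,
        genome_length=report.genome_length,
        feature_length_sum=report.feature_length_sum,
    )


def check_conservation(totals: LayoutTotals) -> bool:
    """Length conservation: lengths + gaps - overlaps == genome length."""
    return (
        totals.feature_length_sum + totals.total_intergenic - totals.total_overlap
        == totals.genome_length
    )


__all__ = [
    "LayoutError",
    "Adjacency",
    "LayoutTotals",
    "LayoutReport",
    "adjacency_spacers",
    "summarize_layout",
    "check_conservation",
]
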