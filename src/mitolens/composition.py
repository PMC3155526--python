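"""Base composition, A+T content, and strand skews.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), computed on
whichever strand a unit is read from.  Insect mitogenomes show a strong
strand asymmetry: genes on opposite strands show GC skews of opposite sign,
so per-gene statistics are computed on each gene's coding (mRNA-sense)
strand while the genome-wide total is computed on the published (H) strand.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .genome_model import GeneFeature, MitoGenome, extract_feature_sequence


class CompositionError(ValueError):
    pass


@dataclass(frozen=True)
class UnitComposition:
    """Composition record for one sequence unit (a gene or the whole genome)."""

    unit: str
    counts: dict[str, int]
    frequencies: dict[str, float]
    at_content: float          # percent
    at_skew: float             # NaN when A+T == 0
    gc_skew: float             # NaN when G+C == 0


@dataclass(frozen=True)
class CompositionReport:
    units: list[UnitComposition]

    def __getitem__(self, unit: str) -> UnitComposition:
        for u in self.units:
            if u.unit == unit:
                return u
        raise KeyError(unit)


def base_composition(seq: str) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and frequencies of A/C/G/T.

    N bases count toward length but toward no base tally; frequencies are
    normalized by the number of unambiguous bases.
    """
    if not seq:
        raise CompositionError("empty sequence")
    tally = Counter(seq.upper())
    counts = {b: tally.get(b, 0) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise CompositionError("sequence contains no unambiguous bases")
    freqs = {b: counts[b] / denom for b in "ACGT"}
    return counts, freqs


def skews(fA: float, fT: float, fG: float, fC: float) -> tuple[float, float]:
    """AT and GC skew from base frequencies (or percentages, or counts).

    A zero denominator yields NaN rather than an exception.
    """
    at = (fA - fT) / (fA + fT) if (fA + fT) > 0 else math.nan
    gc = (fG - fC) / (fG + fC) if (fG + fC) > 0 else math.nan
    return at, gc


def unit_composition(unit: str, seq: str) -> UnitComposition:
    counts, freqs = base_composition(seq)
    at_skew, gc_skew = skews(freqs["A"], freqs["T"], freqs["G"], freqs["C"])
    return UnitComposition(
        unit=unit,
        counts=counts,
        frequencies=freqs,
        at_content=100.0 * (freqs["A"] + freqs["T"]),
        at_skew=at_skew,
        gc_skew=gc_skew,
    )


def composition_report(
    genome: MitoGenome,
    features: list[GeneFeature] | None = None,
    classes: tuple[str, ...] = ("PCG", "rRNA"),
    include_total: bool = True,
) -> CompositionReport:
    """Per-gene composition (coding strand) plus a published-strand Total."""
    if genome.sequence is None:
        raise CompositionError("composition requires a sequence")
    if features is None:
        features = genome.features_of_class(*classes)
    units = [
        unit_composition(f.name, extract_feature_sequence(genome, f)) for f in features
    ]
    if include_total:
        units.append(unit_composition("Total", genome.sequence))
    return CompositionReport(units=units)


def report_frame(report: CompositionReport):
    """Tabular (pandas) view with 3-decimal rounding, table-output style."""
    import pandas as pd

    rows = []
    for u in report.units:
        rows.append(
            {
                "unit": u.unit,
                "A": round(u.frequencies["A"], 3),
                "G": round(u.frequencies["G"], 3),
                "T": round(u.frequencies["T"], 3),
                "C": round(u.frequencies["C"], 3),
                "pct_AT": round(u.at_content, 1),
                "AT_skew": round(u.at_skew, 3),
                "GC_skew": round(u.gc_skew, 3),
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "CompositionError",
    "UnitComposition",
    "CompositionReport",
    "base_composition",
    "skews",
    "unit_composition",
    "composition_report",
    "report_frame",
]
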