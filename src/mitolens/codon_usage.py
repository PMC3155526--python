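"""Codon extraction, start/stop identification, codon usage and RSCU.

Translation uses the invertebrate mitochondrial genetic code (NCBI table 5):
TGA is tryptophan, ATA methionine, and AGA/AGG serine, so serine has one
8-codon synonymous family and leucine one 6-codon family.  RSCU of a codon
is its observed count divided by the count expected if every member of its
synonymous family were used equally: RSCU(c) = N(c) * k / sum_family(N)
with k the family size.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from Bio.Data import CodonTable

from .genome_model import GeneFeature, MitoGenome, extract_feature_sequence

INVERTEBRATE_MITO_TABLE_ID = 5

_TABLE = CodonTable.unambiguous_dna_by_id[INVERTEBRATE_MITO_TABLE_ID]

#: codon (DNA) -> one-letter amino acid, terminators -> "*"
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))

#: amino acid -> synonymous codon family (family sizes: Leu 6, Ser 8, ...)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    FAMILIES.setdefault(CODON_TO_AA[_codon], ())
FAMILIES = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in FAMILIES
}


class CodonError(ValueError):
    pass


def translate_codon(codon: str, table_id: int = INVERTEBRATE_MITO_TABLE_ID) -> str:
    """One-letter amino acid for a triplet; '*' for stops, 'X' for ambiguity."""
    c = codon.upper().replace("U", "T")
    if len(c) != 3:
        raise CodonError(f"not a triplet: {codon!r}")
    table = CodonTable.unambiguous_dna_by_id[table_id]
    if c in table.stop_codons:
        return "*"
    return table.forward_table.get(c, "X")


def translate_cds(cds: str, table_id: int = INVERTEBRATE_MITO_TABLE_ID) -> str:
    """Protein sequence of an in-frame CDS, excluding a trailing terminator."""
    codons, _ = extract_codons(cds)
    return "".join(translate_codon(c, table_id) for c in codons)


def extract_codons(cds: str) -> tuple[list[str], bool]:
    """Split a coding-strand CDS into codons, excluding the terminator.

    Returns ``(codons, incomplete_stop)``.  A trailing remainder of T or TA
    is interpreted as an incomplete stop completed by polyadenylation; any
    other remainder is truncated with a warning.
    """
    seq = cds.upper().replace("U", "T")
    if len(seq) < 6:
        raise CodonError(f"CDS too short ({len(seq)} nt)")
    remainder = len(seq) % 3
    incomplete = False
    if remainder:
        tail = seq[-remainder:]
        if tail in ("T", "TA"):
            incomplete = True
        else:
            warnings.warn(
                f"CDS length {len(seq)} not divisible by 3; truncating {tail!r}",
                stacklevel=2,
            )
        seq = seq[: len(seq) - remainder]
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if not incomplete and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    elif not incomplete:
        incomplete = True  # no terminator found at all
    return codons, incomplete


@dataclass(frozen=True)
class StartStop:
    gene: str
    start_codon: str
    stop_codon: str            # 3 nt when complete, 1-2 nt when incomplete
    canonical_start: bool      # ATN
    complete_stop: bool        # TAA/TAG
    incomplete_stop: bool      # trailing T / TA


@dataclass(frozen=True)
class StartStopReport:
    genes: list[StartStop]

    def __getitem__(self, gene: str) -> StartStop:
        for g in self.genes:
            if g.gene == gene:
                return g
        raise KeyError(gene)

    def start_histogram(self) -> dict[str, int]:
        return dict(Counter(g.start_codon for g in self.genes))


def start_stop_report(genome: MitoGenome, features: list[GeneFeature] | None = None
                      ) -> StartStopReport:
    """Start and stop codons for every protein-coding gene."""
    if features is None:
        features = genome.features_of_class("PCG")
    out = []
    for f in features:
        cds = extract_feature_sequence(genome, f)
        remainder = len(cds) % 3
        if remainder and cds[-remainder:] in ("T", "TA"):
            stop = cds[-remainder:]
            complete = False
            incomplete = True
        else:
            stop = cds[-3:]
            complete = stop in STOP_CODONS
            incomplete = False
        start = cds[:3]
        out.append(
            StartStop(
                gene=f.name,
                start_codon=start,
                stop_codon=stop,
                canonical_start=start[:2] == "AT",
                complete_stop=complete,
                incomplete_stop=incomplete,
            )
        )
    return StartStopReport(genes=out)


def rscu(counts: dict[str, int]) -> dict[str, float]:
    """Relative synonymous codon usage for all 62 sense codons.

    Terminators are ignored.  A codon unused within a used family gets 0;
    a wholly unused family gets 0 for every member.
    """
    for codon, n in counts.items():
        if n < 0:
            raise CodonError(f"negative count for {codon}")
    values: dict[str, float] = {}
    for aa, family in FAMILIES.items():
        total = sum(counts.get(c, 0) for c in family)
        k = len(family)
        for c in family:
            values[c] = counts.get(c, 0) * k / total if total > 0 else 0.0
    return values


def aa_usage(counts: dict[str, int]) -> dict[str, float]:
    """Percent usage per amino acid, pooling synonymous families."""
    total = sum(counts.get(c, 0) for c in SENSE_CODONS)
    if total == 0:
        raise CodonError("no codons counted")
    return {
        aa: 100.0 * sum(counts.get(c, 0) for c in family) / total
        for aa, family in FAMILIES.items()
    }


@dataclass(frozen=True)
class CodonUsageTable:
    counts: dict[str, int]          # sense codons only (DNA alphabet)
    rscu: dict[str, float]
    aa_usage: dict[str, float]      # percent
    total_codons: int               # terminators excluded
    internal_stop_counts: dict[str, int]

    def as_frame(self, rna: bool = True):
        """Table-shaped pandas view (RNA alphabet by default)."""
        import pandas as pd

        rows = []
        for codon in SENSE_CODONS:
            shown = codon.replace("T", "U") if rna else codon
            rows.append(
                {
                    "aa": CODON_TO_AA[codon],
                    "codon": shown,
                    "N": self.counts.get(codon, 0),
                    "RSCU": round(self.rscu.get(codon, 0.0), 2),
                }
            )
        return pd.DataFrame(rows).sort_values(["aa", "codon"]).reset_index(drop=True)


def codon_usage_table(genome: MitoGenome, features: list[GeneFeature] | None = None
                      ) -> CodonUsageTable:
    """Pooled codon usage over all protein-coding genes.

    Stop triplets occurring internally (possible in synthetic sequence) are
    tallied separately and excluded from the sense-codon total.
    """
    if features is None:
        features = genome.features_of_class("PCG")
    tally: Counter[str] = Counter()
    for f in features:
        codons, _ = extract_codons(extract_feature_sequence(genome, f))
        tally.update(codons)
    counts = {c: tally.get(c, 0) for c in SENSE_CODONS}
    stops = {c: tally.get(c, 0) for c in STOP_CODONS if tally.get(c, 0)}
    return CodonUsageTable(
        counts=counts,
        rscu=rscu(counts),
        aa_usage=aa_usage(counts),
        total_codons=sum(counts.values()),
        internal_stop_counts=stops,
    )


def total_codons_from_lengths(features: list[GeneFeature]) -> int:
    """Codon total (terminators excluded) from PCG lengths alone."""
    return sum(f.length // 3 - 1 for f in features if f.feature_class == "PCG")


__all__ = [
    "INVERTEBRATE_MITO_TABLE_ID",
    "CODON_TO_AA",
    "SENSE_CODONS",
    "STOP_CODONS",
    "FAMILIES",
    "CodonError",
    "translate_codon",
    "translate_cds",
    "extract_codons",
    "StartStop",
    "StartStopReport",
    "start_stop_report",
    "rscu",
    "aa_usage",
    "CodonUsageTable",
    "codon_usage_table",
    "total_codons_from_lengths",
]
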