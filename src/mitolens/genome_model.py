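"""Domain types and IO for annotated circular mitochondrial genomes.

Coordinates are 1-based and inclusive throughout, matching the convention of
published mitogenome annotation tables (a tRNA spanning 1..60 has length 60).
Strands are labelled H ("heavy", the published strand) and L ("light"); the
coding-strand sequence of an L feature is the reverse complement of the
published strand.  Features wrapping the circular origin are rejected: every
genome handled here is annotated so that the last feature ends at the genome
end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "noncoding")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeModelError(ValueError):
    """Base error for annotation/coordinate problems."""


class CoordinateError(GenomeModelError):
    pass


class FeatureTableError(GenomeModelError):
    pass


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on a circular mitogenome.

    ``name`` uses canonical mitochondrial tokens (cox1-3, nad1-6, nad4L,
    atp6, atp8, cob, rrnS, rrnL, trnX with L1/L2/S1/S2 isotype suffixes,
    and CR for the control region).
    """

    name: str
    start: int
    end: int
    strand: str
    feature_class: str
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise GenomeModelError(f"{self.name}: strand must be H or L, got {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise GenomeModelError(
                f"{self.name}: class must be one of {FEATURE_CLASSES}, got {self.feature_class!r}"
            )
        if self.start < 1:
            raise CoordinateError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise CoordinateError(
                f"{self.name}: start > end ({self.start} > {self.end}); "
                "origin-wrapping features are not supported"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MitoGenome:
    """A circular mitogenome: optional sequence plus an ordered feature list.

    Annotation-only instances (``sequence is None``) support every
    coordinate-arithmetic analysis (layout, codon totals from lengths).
    """

    name: str
    length: int
    sequence: str | None = None
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - set("ACGTN")
            if bad:
                raise GenomeModelError(f"{self.name}: non-DNA characters {sorted(bad)}")
            if self.length != len(self.sequence):
                raise GenomeModelError(
                    f"{self.name}: declared length {self.length} != sequence length "
                    f"{len(self.sequence)}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.name in seen:
                raise FeatureTableError(f"duplicate feature name {f.name!r}")
            seen.add(f.name)
            if f.end > self.length:
                raise CoordinateError(
                    f"{f.name}: end {f.end} exceeds genome length {self.length}"
                )
            if f.feature_class == "PCG" and f.length % 3 != 0:
                warnings.warn(
                    f"{f.name}: PCG length {f.length} not divisible by 3", stacklevel=2
                )

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_of_class(self, *classes: str) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_class in classes]


def extract_feature_sequence(genome: MitoGenome, feature: GeneFeature) -> str:
    """Coding-strand (mRNA-sense) sequence of a feature.

    H features return the published-strand substring; L features its reverse
    complement.
    """
    if genome.sequence is None:
        raise GenomeModelError(f"{genome.name}: no sequence available")
    if feature.end > genome.length or feature.start < 1:
        raise CoordinateError(f"{feature.name}: span outside [1, {genome.length}]")
    sub = genome.sequence[feature.start - 1 : feature.end]
    return sub if feature.strand == "H" else revcomp(sub)


# ---------------------------------------------------------------------------
# feature-table TSV (columns: name, start, end, strand, class, anticodon)
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["name", "start", "end", "strand", "class", "anticodon"]


def read_feature_table(path, genome_length: int | None = None, name: str = "genome") -> MitoGenome:
    """Read an annotation-only genome from a TSV feature table.

    The genome length may be supplied either via ``genome_length`` or a
    ``# genome_length=N`` header comment in the file.
    """
    header_length = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                text = line.lstrip("#").strip()
                if text.startswith("genome_length"):
                    header_length = int(text.split("=", 1)[1])
            else:
                break
    if genome_length is None:
        genome_length = header_length
    if genome_length is None:
        raise FeatureTableError(
            "genome length required (flag or '# genome_length=N' header comment)"
        )
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _TABLE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FeatureTableError(f"feature table missing columns {missing}")
    features = []
    for idx, row in df.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError) as exc:
            raise FeatureTableError(f"row {idx + 1} ({row['name']}): bad coordinates") from exc
        anticodon = row.get("anticodon")
        if pd.isna(anticodon) or anticodon == "":
            anticodon = None
        features.append(
            GeneFeature(
                name=str(row["name"]),
                start=start,
                end=end,
                strand=str(row["strand"]),
                feature_class=str(row["class"]),
                anticodon=anticodon,
            )
        )
    return MitoGenome(name=name, length=genome_length, features=features)


def write_feature_table(genome: MitoGenome, path) -> None:
    """Write the Table-2-shaped TSV, including a signed intergenic column.

    The intergenic value on each row is the signed spacer to the *next*
    feature in circular start order (gap > 0, overlap < 0).
    """
    from .layout import adjacency_spacers  # local import to avoid a cycle

    spacers = {
        rec.upstream: rec.signed_spacer
        for rec in adjacency_spacers(genome.features, genome.length).adjacencies
    }
    rows = []
    for f in genome.features:
        rows.append(
            {
                "name": f.name,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "class": f.feature_class,
                "anticodon": f.anticodon or "",
                "length": f.length,
                "intergenic": spacers.get(f.name, ""),
            }
        )
    with open(path, "w") as fh:
        fh.write(f"# genome_length={genome.length}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / GenBank
# ---------------------------------------------------------------------------


def read_fasta(path) -> MitoGenome:
    """Read a single-record FASTA into a feature-less MitoGenome."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise GenomeModelError(f"{path}: no FASTA records")
    if len(records) > 1:
        raise GenomeModelError(f"{path}: expected a single record, found {len(records)}")
    rec = records[0]
    return MitoGenome(name=rec.id, length=len(rec.seq), sequence=str(rec.seq))


def write_fasta(genome: MitoGenome, path) -> None:
    if genome.sequence is None:
        raise GenomeModelError("cannot write FASTA without a sequence")
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i : i + 70] + "\n")


_GENBANK_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "noncoding",
                  "misc_feature": "noncoding"}


def read_genbank(path) -> MitoGenome:
    """Read a single-record GenBank flat file, mapping feature kinds."""
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise GenomeModelError(f"{path}: expected a single record, found {len(records)}")
    rec = records[0]
    features = []
    seen: set[str] = set()
    for feat in rec.features:
        if feat.type == "source":
            continue
        if feat.type not in _GENBANK_CLASS:
            if feat.type == "gene":
                continue
            warnings.warn(f"unknown feature kind {feat.type!r}; classed noncoding", stacklevel=2)
        fclass = _GENBANK_CLASS.get(feat.type, "noncoding")
        quals = feat.qualifiers
        fname = (quals.get("gene") or quals.get("product") or [feat.type])[0]
        if fname in seen:
            continue
        seen.add(fname)
        features.append(
            GeneFeature(
                name=fname,
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand="H" if feat.location.strand != -1 else "L",
                feature_class=fclass,
                anticodon=(quals.get("anticodon") or [None])[0],
            )
        )
    return MitoGenome(
        name=rec.id, length=len(rec.seq), sequence=str(rec.seq), features=features
    )


def with_sequence(genome: MitoGenome, sequence: str) -> MitoGenome:
    """Attach a sequence to an annotation-only genome."""
    return MitoGenome(
        name=genome.name,
        length=len(sequence),
        sequence=sequence,
        features=list(genome.features),
        circular=genome.circular,
    )


__all__ = [
    "GeneFeature",
    "MitoGenome",
    "GenomeModelError",
    "CoordinateError",
    "FeatureTableError",
    "revcomp",
    "extract_feature_sequence",
    "read_feature_table",
    "write_feature_table",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "with_sequence",
]
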