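"""Published reference data for the honeybee mitogenomes.

The Apis cerana annotation (GenBank GQ162109) is transcribed from its
published annotation table: 13 protein-coding genes, 22 tRNAs, 2 rRNAs and
the A+T-rich control region on a 15,895 bp circle.  Alongside it live the
published per-gene nucleotide frequencies, the codon-usage counts of the 13
protein-coding genes (3,672 codons excluding terminators), and the three
circular gene orders used for rearrangement analysis (ancestral
pancrustacean, A. cerana, A. mellifera).

These constants are *inputs*: every statistic the package reports about them
is recomputed from these raw coordinates/counts at run time.
"""

from __future__ import annotations

from .genome_model import GeneFeature, MitoGenome

APIS_CERANA_LENGTH = 15_895

# name, start, end, strand, class, anticodon, start codon, stop codon
_APIS_CERANA_ROWS = [
    ("trnS1", 1, 60, "H", "tRNA", "TCT", None, None),
    ("trnE", 64, 129, "H", "tRNA", "TTC", None, None),
    ("trnM", 164, 229, "H", "tRNA", "CAT", None, None),
    ("trnQ", 461, 522, "H", "tRNA", "TTG", None, None),
    ("trnA", 523, 588, "H", "tRNA", "TGC", None, None),
    ("trnI", 607, 672, "H", "tRNA", "GAT", None, None),
    ("nad2", 673, 1668, "H", "PCG", None, "ATT", "TAA"),
    ("trnC", 1668, 1733, "L", "tRNA", "GCA", None, None),
    ("trnY", 1739, 1807, "L", "tRNA", "GTA", None, None),
    ("trnW", 1824, 1892, "H", "tRNA", "TCA", None, None),
    ("cox1", 1893, 3458, "H", "PCG", None, "ATT", "TAA"),
    ("trnL2", 3454, 3523, "H", "tRNA", "TAA", None, None),
    ("cox2", 3613, 4293, "H", "PCG", None, "ATT", "TAA"),
    ("trnD", 4292, 4359, "H", "tRNA", "GTC", None, None),
    ("trnK", 4366, 4437, "H", "tRNA", "TTT", None, None),
    ("atp8", 4444, 4605, "H", "PCG", None, "ATC", "TAA"),
    ("atp6", 4587, 5264, "H", "PCG", None, "ATG", "TAA"),
    ("cox3", 5282, 6061, "H", "PCG", None, "ATG", "TAA"),
    ("trnG", 6128, 6194, "H", "tRNA", "TCC", None, None),
    ("nad3", 6195, 6548, "H", "PCG", None, "ATT", "TAA"),
    ("trnR", 6568, 6633, "L", "tRNA", "TCG", None, None),
    ("trnN", 6653, 6720, "H", "tRNA", "GTT", None, None),
    ("trnF", 6739, 6809, "L", "tRNA", "GAA", None, None),
    ("nad5", 6816, 8486, "L", "PCG", None, "ATT", "TAA"),
    ("trnH", 8487, 8552, "L", "tRNA", "GTG", None, None),
    ("nad4", 8570, 9898, "L", "PCG", None, "ATA", "TAA"),
    ("nad4L", 9899, 10162, "L", "PCG", None, "ATT", "TAA"),
    ("trnT", 10186, 10252, "H", "tRNA", "TGT", None, None),
    ("trnP", 10268, 10345, "L", "tRNA", "TGG", None, None),
    ("nad6", 10396, 10905, "H", "PCG", None, "ATT", "TAA"),
    ("cob", 10918, 12066, "H", "PCG", None, "ATG", "TAA"),
    ("trnS2", 12090, 12156, "H", "tRNA", "TGA", None, None),
    ("nad1", 12169, 13083, "L", "PCG", None, "ATT", "TAA"),
    ("trnL1", 13084, 13152, "L", "tRNA", "TAG", None, None),
    ("rrnL", 13153, 14480, "L", "rRNA", None, None, None),
    ("trnV", 14481, 14547, "L", "tRNA", "TAC", None, None),
    ("rrnS", 14548, 15333, "L", "rRNA", None, None, None),
    ("CR", 15334, 15895, "H", "noncoding", None, None, None),
]

#: published start/stop codons per protein-coding gene
APIS_CERANA_START_STOP: dict[str, tuple[str, str]] = {
    name: (start_codon, stop_codon)
    for name, *_rest, start_codon, stop_codon in _APIS_CERANA_ROWS
    if start_codon is not None
}


def apis_cerana_annotation() -> MitoGenome:
    """Annotation-only MitoGenome for A. cerana (no sequence bundled)."""
    features = [
        GeneFeature(name=n, start=s, end=e, strand=st, feature_class=c, anticodon=a)
        for n, s, e, st, c, a, _, _ in _APIS_CERANA_ROWS
    ]
    return MitoGenome(name="Apis_cerana_GQ162109", length=APIS_CERANA_LENGTH, features=features)


def write_apis_cerana_table(path) -> None:
    """Write the bundled annotation as a feature-table TSV."""
    from .genome_model import write_feature_table

    write_feature_table(apis_cerana_annotation(), path)


# ---------------------------------------------------------------------------
# Published per-gene nucleotide frequencies and skews (A. cerana)
# gene -> (fA, fG, fT, fC, %A+T, AT-skew, GC-skew), frequencies as printed
# ---------------------------------------------------------------------------

APIS_CERANA_COMPOSITION: dict[str, tuple[float, ...]] = {
    "atp6": (0.366, 0.056, 0.472, 0.106, 83.8, -0.127, -0.309),
    "atp8": (0.475, 0.043, 0.395, 0.086, 87.0, 0.092, -0.333),
    "cox1": (0.347, 0.110, 0.413, 0.130, 76.0, -0.086, -0.085),
    "cox2": (0.385, 0.087, 0.404, 0.125, 78.9, -0.024, -0.181),
    "cox3": (0.360, 0.089, 0.444, 0.108, 80.4, -0.104, -0.098),
    "cob": (0.368, 0.084, 0.442, 0.105, 81.0, -0.091, -0.110),
    "nad1": (0.355, 0.109, 0.480, 0.056, 83.5, -0.149, 0.325),
    "nad2": (0.395, 0.051, 0.469, 0.085, 86.4, -0.086, -0.250),
    "nad3": (0.373, 0.051, 0.475, 0.102, 84.8, -0.120, -0.334),
    "nad4": (0.360, 0.093, 0.491, 0.056, 85.1, -0.153, 0.252),
    "nad4L": (0.345, 0.095, 0.527, 0.034, 87.2, -0.209, 0.470),
    "nad5": (0.379, 0.095, 0.470, 0.056, 84.9, -0.107, 0.257),
    "nad6": (0.431, 0.051, 0.433, 0.084, 86.4, -0.002, -0.246),
    "rrnS": (0.439, 0.125, 0.377, 0.060, 81.6, 0.076, 0.352),
    "rrnL": (0.404, 0.111, 0.428, 0.058, 83.1, -0.029, 0.312),
    "Total": (0.423, 0.063, 0.416, 0.098, 83.9, 0.008, -0.217),
}

# ---------------------------------------------------------------------------
# Published codon usage of the 13 A. cerana protein-coding genes
# (DNA alphabet; counts N, terminators excluded from the 3,672 total)
# ---------------------------------------------------------------------------

APIS_CERANA_CODON_COUNTS: dict[str, int] = {
    "TTT": 336, "TTC": 35, "TTA": 483, "TTG": 10,
    "CTT": 40, "CTC": 1, "CTA": 34, "CTG": 2,
    "ATT": 452, "ATC": 20, "ATA": 312, "ATG": 17,
    "GTT": 83, "GTC": 7, "GTA": 59, "GTG": 1,
    "TCT": 55, "TCC": 9, "TCA": 167, "TCG": 0,
    "CCT": 34, "CCC": 4, "CCA": 67, "CCG": 0,
    "ACT": 38, "ACC": 1, "ACA": 82, "ACG": 0,
    "GCT": 29, "GCC": 4, "GCA": 36, "GCG": 2,
    "TAT": 202, "TAC": 17,
    "CAT": 55, "CAC": 6, "CAA": 39, "CAG": 0,
    "AAT": 223, "AAC": 14, "AAA": 156, "AAG": 7,
    "GAT": 60, "GAC": 2, "GAA": 77, "GAG": 6,
    "TGT": 26, "TGC": 0, "TGA": 84, "TGG": 0,
    "CGT": 9, "CGC": 1, "CGA": 28, "CGG": 0,
    "AGT": 15, "AGC": 0, "AGA": 85, "AGG": 5,
    "GGT": 44, "GGC": 3, "GGA": 82, "GGG": 6,
}

# ---------------------------------------------------------------------------
# Circular gene orders for rearrangement analysis.  Tokens are signed:
# a leading "-" marks the minority (L) strand.  "CR" is the control region,
# used as an anchor-interval boundary marker, never as a movable gene.
# ---------------------------------------------------------------------------

ANCESTRAL_PANCRUSTACEAN_ORDER: tuple[str, ...] = (
    "trnI", "-trnQ", "trnM", "nad2", "trnW", "-trnC", "-trnY", "cox1",
    "trnL2", "cox2", "trnK", "trnD", "atp8", "atp6", "cox3", "trnG",
    "nad3", "trnA", "trnR", "trnN", "trnS1", "trnE", "-trnF", "-nad5",
    "-trnH", "-nad4", "-nad4L", "trnT", "-trnP", "nad6", "cob", "trnS2",
    "-nad1", "-trnL1", "-rrnL", "-trnV", "-rrnS", "CR",
)

APIS_CERANA_ORDER: tuple[str, ...] = (
    "trnS1", "trnE", "trnM", "trnQ", "trnA", "trnI", "nad2", "-trnC",
    "-trnY", "trnW", "cox1", "trnL2", "cox2", "trnD", "trnK", "atp8",
    "atp6", "cox3", "trnG", "nad3", "-trnR", "trnN", "-trnF", "-nad5",
    "-trnH", "-nad4", "-nad4L", "trnT", "-trnP", "nad6", "cob", "trnS2",
    "-nad1", "-trnL1", "-rrnL", "-trnV", "-rrnS", "CR",
)

# identical to A. cerana except trnS1 and trnE swapped positions
APIS_MELLIFERA_ORDER: tuple[str, ...] = (
    "trnE", "trnS1") + APIS_CERANA_ORDER[2:]

__all__ = [
    "APIS_CERANA_LENGTH",
    "APIS_CERANA_START_STOP",
    "APIS_CERANA_COMPOSITION",
    "APIS_CERANA_CODON_COUNTS",
    "ANCESTRAL_PANCRUSTACEAN_ORDER",
    "APIS_CERANA_ORDER",
    "APIS_MELLIFERA_ORDER",
    "apis_cerana_annotation",
    "write_apis_cerana_table",
]
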