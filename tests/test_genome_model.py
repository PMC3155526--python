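import numpy as np
import pytest
from hypothesis import given, strategies as st

from mitolens.genome_model import (
    CoordinateError,
    FeatureTableError,
    GeneFeature,
    GenomeModelError,
    MitoGenome,
    extract_feature_sequence,
    read_fasta,
    read_feature_table,
    read_genbank,
    revcomp,
    write_fasta,
    write_feature_table,
)


def test_feature_length_is_inclusive():
    f = GeneFeature("trnS1", 1, 60, "H", "tRNA", "TCT")
    assert f.length == 60
    assert GeneFeature("cox1", 1893, 3458, "H", "PCG").length == 1566


def test_start_after_end_rejected():
    with pytest.raises(CoordinateError):
        GeneFeature("x", 5, 4, "H", "PCG")


def test_feature_past_genome_end_rejected():
    with pytest.raises(CoordinateError):
        MitoGenome("g", 100, features=[GeneFeature("a", 90, 120, "H", "tRNA")])


def test_duplicate_names_rejected():
    feats = [GeneFeature("a", 1, 10, "H", "tRNA"), GeneFeature("a", 20, 30, "H", "tRNA")]
    with pytest.raises(FeatureTableError):
        MitoGenome("g", 100, features=feats)


def test_pcg_length_not_multiple_of_three_warns():
    with pytest.warns(UserWarning, match="not divisible by 3"):
        MitoGenome("g", 100, features=[GeneFeature("p", 1, 10, "H", "PCG")])


def test_extract_h_and_l_strand():
    g = MitoGenome("g", 6, sequence="AAACGT")
    assert extract_feature_sequence(g, GeneFeature("a", 1, 3, "H", "tRNA")) == "AAA"
    # L strand: reverse complement of the published-strand substring
    assert extract_feature_sequence(g, GeneFeature("b", 4, 6, "L", "tRNA")) == "ACG"


def test_extract_reembed_roundtrip():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    g = MitoGenome("g", 100, sequence=seq)
    for start, end, strand in [(1, 30, "H"), (11, 40, "L"), (95, 100, "H")]:
        f = GeneFeature("f", start, end, strand, "tRNA")
        coding = extract_feature_sequence(g, f)
        assert len(coding) == f.length
        back = coding if strand == "H" else revcomp(coding)
        assert back == seq[start - 1 : end]


@given(st.text(alphabet="ACGTN", min_size=0, max_size=200))
def test_revcomp_is_involution(seq):
    assert revcomp(revcomp(seq)) == seq


def test_feature_table_roundtrip(tmp_path, cerana):
    path = tmp_path / "features.tsv"
    write_feature_table(cerana, path)
    back = read_feature_table(path)
    assert back.length == cerana.length
    assert back.features == cerana.features


def test_feature_table_requires_length(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("name\tstart\tend\tstrand\tclass\tanticodon\na\t1\t10\tH\ttRNA\t\n")
    with pytest.raises(FeatureTableError, match="genome length"):
        read_feature_table(path)
    assert read_feature_table(path, genome_length=50).length == 50


def test_feature_table_bad_coordinates_name_row(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text(
        "# genome_length=50\nname\tstart\tend\tstrand\tclass\tanticodon\n"
        "a\t1\tten\tH\ttRNA\t\n"
    )
    with pytest.raises(FeatureTableError, match="row 1"):
        read_feature_table(path)


def test_fasta_roundtrip_and_errors(tmp_path):
    g = MitoGenome("mito", 150, sequence="ACGT" * 37 + "AC")
    path = tmp_path / "g.fasta"
    write_fasta(g, path)
    back = read_fasta(path)
    assert (back.name, back.length, back.sequence) == (g.name, g.length, g.sequence)

    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    with pytest.raises(GenomeModelError):
        read_fasta(empty)

    multi = tmp_path / "multi.fasta"
    multi.write_text(">a\nACGT\n>b\nACGT\n")
    with pytest.raises(GenomeModelError, match="single record"):
        read_fasta(multi)


def test_genbank_reader_maps_feature_classes(tmp_path):
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    rec = SeqRecord(Seq("ATT" + "AAA" * 30 + "TAA" + "ACGT" * 20), id="toy",
                    annotations={"molecule_type": "DNA"})
    rec.features = [
        SeqFeature(SimpleLocation(0, 96, strand=1), type="CDS",
                   qualifiers={"gene": ["nad2"]}),
        SeqFeature(SimpleLocation(96, 150, strand=-1), type="tRNA",
                   qualifiers={"gene": ["trnC"], "anticodon": ["GCA"]}),
        SeqFeature(SimpleLocation(150, 176, strand=1), type="rRNA",
                   qualifiers={"gene": ["rrnS"]}),
    ]
    path = tmp_path / "toy.gb"
    SeqIO.write([rec], str(path), "genbank")
    g = read_genbank(path)
    assert [f.feature_class for f in g.features] == ["PCG", "tRNA", "rRNA"]
    nad2 = g.feature("nad2")
    assert (nad2.start, nad2.end, nad2.strand) == (1, 96, "H")
    assert g.feature("trnC").strand == "L"
    assert g.feature("trnC").anticodon == "GCA"
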