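"""Genome reading/writing and the packaged strain table."""

import pytest

from pellicle.genome_io import (Contig, GeneFeature, Genome, GenomeError,
                                UnsupportedFeatureError, load_table1_fixture,
                                read_annotated_genome, write_genome)

from _oracles import translate_span

MINIMAL_GBK = """\
LOCUS       testchr                  300 bp    DNA     linear   BCT 01-JAN-1980
DEFINITION  Test chromosome.
ACCESSION   testchr
VERSION     testchr
KEYWORDS    .
SOURCE      .
  ORGANISM  .
FEATURES             Location/Qualifiers
     source          1..300
     CDS             10..48
                     /locus_tag="T_00001"
                     /product="rmlA"
                     /translation="MKVLAWLLRQTAX"
ORIGIN
        1 atgaaagttc tggcttggct gctgcgtcag actgcttaat aagttcacgt acgtacgtac
       61 gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac
      121 gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac
      181 gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac
      241 gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac
//
"""


def test_minimal_genbank_identity(tmp_path):
    path = tmp_path / "mini.gbk"
    path.write_text(MINIMAL_GBK)
    genome = read_annotated_genome(path)
    assert len(genome.contigs) == 1
    assert genome.contigs[0].length == 300
    assert len(genome.features) == 1
    feat = genome.features[0]
    assert (feat.start, feat.end, feat.strand) == (10, 48, "+")
    assert feat.product == "rmlA"
    assert feat.protein == "MKVLAWLLRQTAX"


@pytest.mark.parametrize("fmt", ["genbank", "gff3+fasta"])
def test_round_trip(tmp_path, f_strain, fmt):
    genome, _ = f_strain
    suffix = "gbk" if fmt == "genbank" else "gff3"
    path = tmp_path / f"g.{suffix}"
    write_genome(genome, path, format=fmt)
    reread = read_annotated_genome(path, format=fmt)
    orig = [(f.contig_id, f.start, f.end, f.strand, f.locus_tag, f.product, f.protein)
            for f in genome.sorted_features()]
    back = [(f.contig_id, f.start, f.end, f.strand, f.locus_tag, f.product, f.protein)
            for f in reread.sorted_features()]
    assert orig == back
    assert [c.length for c in reread.contigs] == [c.length for c in genome.contigs]


def test_gff3_translation_matches_codon_oracle(tmp_path, f_strain):
    genome, _ = f_strain
    path = tmp_path / "g.gff3"
    write_genome(genome, path, format="gff3+fasta")
    # strip stored translations so the reader must translate the spans
    lines = []
    for line in path.read_text().splitlines():
        lines.append(";".join(p for p in line.split(";") if not p.startswith("translation=")))
    path.write_text("\n".join(lines) + "\n")
    reread = read_annotated_genome(path, format="gff3+fasta")
    seq = genome.contigs[0].sequence
    strands = set()
    for orig, back in zip(genome.sorted_features(), reread.sorted_features()):
        expected = translate_span(seq, orig.start, orig.end, orig.strand)
        assert back.protein == expected == orig.protein
        strands.add(orig.strand)
    assert strands == {"+", "-"}  # both orientations exercised


def test_duplicate_locus_tags_rejected():
    contig = Contig(id="c1", length=1000)
    feats = [
        GeneFeature("c1", 1, 90, "+", "dup", protein="M" + "A" * 29),
        GeneFeature("c1", 200, 290, "+", "dup", protein="M" + "A" * 29),
    ]
    with pytest.raises(GenomeError, match="duplicate"):
        Genome(id="g", contigs=[contig], features=feats)


def test_origin_spanning_cds_rejected(tmp_path):
    gbk = MINIMAL_GBK.replace("CDS             10..48",
                              "CDS             join(280..300,1..27)")
    path = tmp_path / "wrap.gbk"
    path.write_text(gbk)
    with pytest.raises(UnsupportedFeatureError):
        read_annotated_genome(path)


def test_empty_feature_genome_writes(tmp_path):
    genome = Genome(id="empty", contigs=[Contig(id="c1", length=500)])
    path = tmp_path / "empty.gbk"
    write_genome(genome, path)
    reread = read_annotated_genome(path)
    assert reread.features == []
    assert reread.contigs[0].length == 500


class TestStrainTable:
    def test_record_count(self):
        records = load_table1_fixture()
        assert len(records) == 28
        by_species = {}
        for r in records:
            by_species.setdefault(r.species, []).append(r)
        assert len(by_species["P. laudensis"]) == 21
        assert len(by_species["P. raffinolactis"]) == 7

    def test_every_fragment_obeys_length_convention(self):
        for rec in load_table1_fixture():
            for (s, e), printed in zip(rec.cwps_fragments + rec.eps_fragments,
                                       rec.printed_lengths):
                assert e - s == printed

    def test_reference_strain_coordinates(self):
        rec = next(r for r in load_table1_fixture() if r.strain == "DSM28961")
        assert rec.cwps_genotype == "E"
        assert rec.cwps_fragments == [(182887, 201332)]
        assert rec.cwps_length == 18445

    def test_split_and_eps_free_strains(self):
        records = {r.strain: r for r in load_table1_fixture()}
        for strain in ("T2G5", "T2H4"):
            assert len(records[strain].cwps_fragments) == 2
        for strain in ("T2E11", "Lr_19_5", "APC3967"):
            assert records[strain].eps_genotype is None
            assert records[strain].eps_fragments == []
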