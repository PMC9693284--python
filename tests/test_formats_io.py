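"""I/O layer: FASTA/GFF3/BLAST parsing, BED export, packaged fixtures."""

import pytest

from cdrh.formats_io import (
    PRINTED_TOTALS,
    attach_features,
    expand_homolog_counts,
    read_blast_tabular,
    read_fasta,
    read_gff3_genes,
    strip_transcript_suffix,
    write_bed,
)
from cdrh.model import GeneFeature, RGARecord, Subclass


# ---------------------------------------------------------------- FASTA


def test_read_fasta_single_and_order(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">p1\nMKV\n>p2\nMAA\nGGG\n")
    records = read_fasta(p)
    assert [(r.id, r.residues) for r in records] == [("p1", "MKV"), ("p2", "MAAGGG")]


def test_read_fasta_duplicate_id_names_offender(tmp_path):
    p = tmp_path / "dup.fasta"
    p.write_text(">p1\nMKV\n>p1\nMAA\n")
    with pytest.raises(ValueError, match="p1"):
        read_fasta(p)


def test_read_fasta_empty_file_warns(tmp_path, caplog):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    with caplog.at_level("WARNING"):
        assert read_fasta(p) == []
    assert "no records" in caplog.text


# ---------------------------------------------------------------- GFF3


def test_read_gff3_gene_line(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text("##gff-version 3\nchr1\t.\tgene\t100\t500\t.\t+\t.\tID=g1\n")
    (feat,) = read_gff3_genes(p)
    assert feat == GeneFeature("g1", "chr1", 100, 500, "+")


def test_read_gff3_type_filter_and_alt_attribute(tmp_path, caplog):
    p = tmp_path / "g.gff3"
    p.write_text(
        "##gff-version 3\n"
        "chr1\t.\tmRNA\t100\t500\t.\t+\t.\tID=t1\n"
        "chr1\t.\tgene\t600\t900\t.\t-\t.\tID=x;locus_tag=LOC1\n"
    )
    with caplog.at_level("WARNING"):
        assert read_gff3_genes(tmp_path / "g.gff3", feature_type="CDS") == []
    assert "no 'CDS' features" in caplog.text
    (feat,) = read_gff3_genes(p, id_attribute="locus_tag")
    assert (feat.gene_id, feat.strand) == ("LOC1", "-")


def test_read_gff3_missing_id_attribute_skips_with_warning(tmp_path, caplog):
    p = tmp_path / "g.gff3"
    p.write_text(
        "##gff-version 3\n"
        "chr1\t.\tgene\t10\t20\t.\t+\t.\tName=anon\n"
        "chr1\t.\tgene\t30\t40\t.\t+\t.\tID=g2\n"
    )
    with caplog.at_level("WARNING"):
        feats = read_gff3_genes(p)
    assert [f.gene_id for f in feats] == ["g2"]
    assert "lacks attribute" in caplog.text


# ---------------------------------------------------------------- BLAST tabular

_STD = "rga1\tAt_BAK1\t72.5\t210\t30\t2\t1\t210\t5\t214\t1e-80\t450"


def test_read_blast_with_ppos_takes_similarity_from_positives(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text(_STD + "\t80.1\t480\n")
    (hit,) = read_blast_tabular(p, dialect="std+ppos+qlen")
    assert hit.evalue == 1e-80
    assert hit.alignment_length == 210
    assert hit.similarity == 80.1
    assert hit.identity == 72.5


def test_read_blast_without_ppos_falls_back_to_identity(tmp_path, caplog):
    p = tmp_path / "hits.tsv"
    p.write_text(_STD + "\n")
    with caplog.at_level("WARNING"):
        (hit,) = read_blast_tabular(p, dialect="std")
    assert hit.similarity == hit.identity == 72.5
    assert "falls back to identity" in caplog.text


def test_read_blast_zero_evalue_and_row_errors(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text(_STD.replace("1e-80", "0.0") + "\n")
    (hit,) = read_blast_tabular(p, dialect="std")
    assert hit.evalue == 0.0

    p.write_text(_STD.replace("1e-80", "abc") + "\n")
    with pytest.raises(ValueError, match=r":1: non-numeric evalue"):
        read_blast_tabular(p, dialect="std")

    p.write_text("rga1\tAt_BAK1\t72.5\n")
    with pytest.raises(ValueError, match="missing column 'length'"):
        read_blast_tabular(p, dialect="std")


# ---------------------------------------------------------------- BED


def test_write_bed_converts_to_zero_based_half_open(tmp_path):
    out = tmp_path / "out.bed"
    write_bed([GeneFeature("g1", "chr1", 100, 500)], out)
    assert out.read_text() == "chr1\t99\t500\tg1\n"


def test_write_bed_sorted_and_empty(tmp_path):
    out = tmp_path / "out.bed"
    write_bed(
        [GeneFeature("b", "chr2", 5, 9), GeneFeature("a", "chr1", 900, 1200),
         GeneFeature("c", "chr1", 100, 500)],
        out,
    )
    lines = out.read_text().splitlines()
    assert lines == ["chr1\t99\t500\tc", "chr1\t899\t1200\ta", "chr2\t4\t9\tb"]
    write_bed([], out)
    assert out.read_text() == ""


def test_gff3_to_bed_round_trip_preserves_coordinates(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text("##gff-version 3\nchr1\t.\tgene\t137\t4242\t.\t+\t.\tID=g1\n")
    (feat,) = read_gff3_genes(p)
    out = tmp_path / "g.bed"
    write_bed([feat], out)
    chrom, start0, end, name = out.read_text().split()
    assert (chrom, int(start0) + 1, int(end)) == (feat.chrom, feat.start, feat.end)


# ---------------------------------------------------------------- id glue


def test_strip_transcript_suffix_and_attach():
    assert strip_transcript_suffix("g1.1") == "g1"
    assert strip_transcript_suffix("g1") == "g1"
    assert strip_transcript_suffix("AT1G12345.12") == "AT1G12345"
    rec = RGARecord("g1.1", "Aal", Subclass.TNL)
    n = attach_features([rec], [GeneFeature("g1", "chr1", 1, 10)])
    assert n == 1 and rec.feature.chrom == "chr1"


# ---------------------------------------------------------------- fixtures


def test_fixture_has_49_genes_with_consistent_rows(curated_tables):
    assert len(curated_tables.homolog_counts) == 49
    for row in curated_tables.homolog_counts:
        assert row.retained + row.diversified_total == row.total
        if not row.opaque:
            assert sum(row.diversified.values()) == row.diversified_total


def test_fixture_bak1_and_ndr1_rows(curated_tables):
    bak1 = curated_tables.row("At_BAK1")
    assert bak1.ref_subclass is Subclass.LRR_RLK
    assert bak1.retained == 117
    assert bak1.diversified == {Subclass.OTHER_RLK: 2}
    assert bak1.total == 119
    ndr1 = curated_tables.row("At_NDR1")
    assert ndr1.ref_subclass is Subclass.TM and ndr1.total == 0


def test_fixture_disease_map_examples(curated_tables):
    assert curated_tables.gene_disease_map["At_RLM3"] == {
        "blackleg",
        "grey mould",
        "Alternaria black spot",
    }
    assert curated_tables.gene_disease_map["Bju_WRR1"] == {"white rust"}
    assert curated_tables.gene_disease_map["At_RIN4"] == frozenset()
    assert len(curated_tables.diseases) == 11


def test_fixture_alias_lookup(curated_tables):
    assert curated_tables.cloned_genes["Bna_MPK9"] is curated_tables.cloned_genes["Bna_MAPk"]


def test_fixture_anomaly_registry_contents(curated_tables):
    text = "\n".join(curated_tables.anomalies)
    assert "At_RRS1" in text  # opaque diversified cell
    assert "1180" in text and "1181" in text  # grand-total inconsistency
    for disease in ("bacterial leaf spot", "blackleg", "clubroot"):
        assert disease in text


def test_expansion_matches_printed_total(homolog_records):
    assert len(homolog_records) == PRINTED_TOTALS["total"] == 3172
    opaque = [r for r in homolog_records if r.homolog_subclass is None]
    assert len(opaque) == 15 and {r.gene for r in opaque} == {"At_RRS1"}
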