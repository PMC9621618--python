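"""Promoter extraction from synthetic genome FASTA + GFF3."""

import numpy as np
import pytest

from hsescan.core import reverse_complement
from hsescan.promoters import (
    AnnotationError,
    GeneModel,
    PromoterMode,
    choose_tss,
    extract_promoter,
    load_annotation,
    load_genome,
    read_promoters_fasta,
    write_promoters_fasta,
)

CONTIG_LEN = 12000


@pytest.fixture(scope="module")
def contig_seq():
    rng = np.random.default_rng(99)
    return "".join(rng.choice(list("ACGT"), size=CONTIG_LEN))


@pytest.fixture(scope="module")
def genome(contig_seq, tmp_path_factory):
    path = tmp_path_factory.mktemp("genome") / "toy.fa"
    with open(path, "w") as fh:
        fh.write(">chr1\n")
        for off in range(0, CONTIG_LEN, 60):
            fh.write(contig_seq[off : off + 60] + "\n")
    return load_genome(path)


def _write_gff3(path, lines):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in lines:
            fh.write(line + "\n")


@pytest.fixture(scope="module")
def annotation(tmp_path_factory):
    """Three genes: plus-strand with 64-nt 5' UTR and two splice variants,
    minus-strand with two variants, and a plus-strand gene near the edge."""
    path = tmp_path_factory.mktemp("gff") / "toy.gff3"
    col = "chr1\ttest\t{}\t{}\t{}\t.\t{}\t{}\t{}"
    lines = [
        # gene1 (+): variants start at 6001 (UTR 64) and 6051
        col.format("gene", 6001, 9000, "+", ".", "ID=gene1"),
        col.format("mRNA", 6001, 9000, "+", ".", "ID=gene1.1;Parent=gene1"),
        col.format("exon", 6001, 9000, "+", ".", "Parent=gene1.1"),
        col.format("CDS", 6065, 8800, "+", "0", "Parent=gene1.1"),
        col.format("mRNA", 6051, 9000, "+", ".", "ID=gene1.2;Parent=gene1"),
        col.format("exon", 6051, 9000, "+", ".", "Parent=gene1.2"),
        col.format("CDS", 6065, 8800, "+", "0", "Parent=gene1.2"),
        # gene2 (-): variants end at 4900 and 4950 -> 5'-most TSS is 4950
        col.format("gene", 2000, 4950, "-", ".", "ID=gene2"),
        col.format("mRNA", 2000, 4900, "-", ".", "ID=gene2.1;Parent=gene2"),
        col.format("exon", 2000, 4900, "-", ".", "Parent=gene2.1"),
        col.format("CDS", 2100, 4850, "-", "0", "Parent=gene2.1"),
        col.format("mRNA", 2000, 4950, "-", ".", "ID=gene2.2;Parent=gene2"),
        col.format("exon", 2000, 4950, "-", ".", "Parent=gene2.2"),
        col.format("CDS", 2100, 4850, "-", "0", "Parent=gene2.2"),
        # gene3 (+): TSS at 1500, upstream window truncated at the contig edge
        col.format("gene", 1500, 1800, "+", ".", "ID=gene3"),
        col.format("mRNA", 1500, 1800, "+", ".", "ID=gene3.1;Parent=gene3"),
        col.format("exon", 1500, 1800, "+", ".", "Parent=gene3.1"),
        col.format("CDS", 1500, 1800, "+", "0", "Parent=gene3.1"),
    ]
    _write_gff3(path, lines)
    return load_annotation(path)


def test_choose_tss_picks_5prime_most_variant(annotation):
    gene1 = choose_tss(annotation, "gene1")
    assert (gene1.tss, gene1.cds_start) == (6001, 6065)
    assert gene1.source_transcript == "gene1.1"
    gene2 = choose_tss(annotation, "gene2")
    assert (gene2.tss, gene2.cds_start) == (4950, 4850)
    assert gene2.source_transcript == "gene2.2"
    assert gene2.fiveprime_utr_length == 100


def test_choose_tss_without_transcripts_raises(tmp_path):
    path = tmp_path / "bare.gff3"
    _write_gff3(path, ["chr1\ttest\tgene\t100\t200\t.\t+\t.\tID=lonely"])
    db = load_annotation(path)
    with pytest.raises(AnnotationError):
        choose_tss(db, "lonely")


def test_plus_strand_2kb_is_direct_slice(annotation, genome, contig_seq):
    gene1 = choose_tss(annotation, "gene1")
    region = extract_promoter(gene1, genome, PromoterMode.UPSTREAM_2KB)
    assert region.analyzed_length == 2000
    assert region.fiveprime_utr_length == 0
    assert region.sequence == contig_seq[4000:6000]  # genomic 4001..6000
    assert region.genomic_interval == ("chr1", 4001, 6000, "+")


def test_minus_strand_2kb_is_reverse_complemented(annotation, genome, contig_seq):
    gene2 = choose_tss(annotation, "gene2")
    region = extract_promoter(gene2, genome, PromoterMode.UPSTREAM_2KB)
    assert region.sequence == reverse_complement(contig_seq[4950:6950])
    assert region.genomic_interval == ("chr1", 4951, 6950, "-")


def test_extended_mode_appends_utr(annotation, genome, contig_seq):
    gene1 = choose_tss(annotation, "gene1")
    region = extract_promoter(gene1, genome, PromoterMode.EXTENDED_5KB_PLUS_5UTR)
    # full 5 kb upstream available plus a 64-nt 5' UTR: the printed
    # "total (utr)" convention, here 5064 (64)
    assert region.analyzed_length == 5064
    assert region.fiveprime_utr_length == 64
    assert region.sequence == contig_seq[1000:6000] + contig_seq[6000:6064]
    assert f"{region.analyzed_length} ({region.fiveprime_utr_length})" == "5064 (64)"


def test_extended_mode_minus_strand(annotation, genome, contig_seq):
    gene2 = choose_tss(annotation, "gene2")
    region = extract_promoter(gene2, genome, PromoterMode.EXTENDED_5KB_PLUS_5UTR)
    assert region.fiveprime_utr_length == 100
    assert region.analyzed_length == 5100
    expected = reverse_complement(contig_seq[4950:9950]) + reverse_complement(
        contig_seq[4850:4950]
    )
    assert region.sequence == expected


def test_truncation_at_contig_edge(annotation, genome, contig_seq):
    gene3 = choose_tss(annotation, "gene3")
    region = extract_promoter(gene3, genome, PromoterMode.UPSTREAM_2KB)
    assert region.analyzed_length == 1499  # genomic 1..1499
    assert region.sequence == contig_seq[:1499]


def test_extraction_stays_inside_contig(annotation, genome):
    for gene_id in ("gene1", "gene2", "gene3"):
        model = choose_tss(annotation, gene_id)
        for mode in PromoterMode:
            region = extract_promoter(model, genome, mode)
            _, start, end, _ = region.genomic_interval
            assert 1 <= start and end <= CONTIG_LEN


def test_missing_chromosome_raises(annotation, genome):
    ghost = GeneModel("ghost", "chrZ", "+", 500, 600)
    with pytest.raises(KeyError):
        extract_promoter(ghost, genome, PromoterMode.UPSTREAM_2KB)


def test_assembly_gap_ns_preserved(tmp_path):
    contig = "A" * 100 + "N" * 50 + "G" * 100 + "ATG" + "C" * 47
    fasta = tmp_path / "gap.fa"
    fasta.write_text(">c\n" + contig + "\n")
    genome = load_genome(fasta)
    model = GeneModel("gapgene", "c", "+", 251, 251)
    region = extract_promoter(model, genome, PromoterMode.UPSTREAM_2KB)
    assert region.sequence == contig[:250]
    assert "N" * 50 in region.sequence


def test_promoter_fasta_round_trip(annotation, genome, tmp_path):
    regions = [
        extract_promoter(
            choose_tss(annotation, g), genome, PromoterMode.EXTENDED_5KB_PLUS_5UTR
        )
        for g in ("gene1", "gene2")
    ]
    path = tmp_path / "promoters.fa"
    write_promoters_fasta(regions, path)
    back = read_promoters_fasta(path)
    assert [(r.gene_id, r.mode.value, r.analyzed_length, r.fiveprime_utr_length,
             r.sequence) for r in regions] == back
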