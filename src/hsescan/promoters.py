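"""Strand-aware promoter extraction from genome FASTA + GFF3.

Two promoter modes are supported:

* ``UPSTREAM_2KB`` — up to 2,000 nt immediately 5' of the transcription
  initiation site (TSS), the conventional window for cis-element scans.
* ``EXTENDED_5KB_PLUS_5UTR`` — up to 5,000 nt upstream of the TSS
  concatenated with the TSS-to-start-codon segment (the 5' UTR), used
  when a wider net is cast for distal elements.

Sequences are always returned 5'->3' on the gene's sense strand, so
minus-strand genes are reverse-complemented.  Runs of N from assembly
gaps are preserved verbatim.  Windows truncated at a contig edge are
returned shorter, with the truncation logged.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import gffutils
from pyfaidx import Fasta

from .core import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterMode",
    "GeneModel",
    "PromoterRegion",
    "AnnotationError",
    "load_genome",
    "load_annotation",
    "choose_tss",
    "gene_models",
    "extract_promoter",
    "write_promoters_fasta",
    "read_promoters_fasta",
]

UPSTREAM_2KB_LENGTH = 2000
UPSTREAM_EXTENDED_LENGTH = 5000

_TRANSCRIPT_TYPES = ("mRNA", "transcript")


class AnnotationError(ValueError):
    """The annotation lacks the features needed to anchor a promoter."""


class PromoterMode(enum.Enum):
    UPSTREAM_2KB = "2kb"
    EXTENDED_5KB_PLUS_5UTR = "extended"


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene anchor: TSS and start codon on a named contig.

    Coordinates are 1-based genomic.  On the plus strand ``tss <=
    cds_start``; on the minus strand ``tss >= cds_start``.
    """

    gene_id: str
    chromosome: str
    strand: str  # "+" or "-"
    tss: int
    cds_start: int
    source_transcript: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.strand == "+" and self.tss > self.cds_start:
            raise ValueError("plus-strand gene requires tss <= cds_start")
        if self.strand == "-" and self.tss < self.cds_start:
            raise ValueError("minus-strand gene requires tss >= cds_start")

    @property
    def fiveprime_utr_length(self) -> int:
        return abs(self.cds_start - self.tss)


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    mode: PromoterMode
    sequence: str
    analyzed_length: int
    fiveprime_utr_length: int
    genomic_interval: tuple[str, int, int, str]  # chrom, start, end (1-based incl.), strand

    def __post_init__(self) -> None:
        if self.analyzed_length != len(self.sequence):
            raise ValueError("analyzed_length must equal len(sequence)")


def load_genome(fasta_path: Union[str, Path]) -> Fasta:
    """Open an indexed FASTA (the .fai index is built on first use)."""
    return Fasta(str(fasta_path), sequence_always_upper=False)


def load_annotation(gff3_path: Union[str, Path]) -> gffutils.FeatureDB:
    """Load a GFF3 file into an in-memory feature database."""
    return gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )


def choose_tss(db: gffutils.FeatureDB, gene_id: str) -> GeneModel:
    """Anchor a gene at the 5'-most TSS among its transcripts.

    When a gene has several splice variants their 5' ends can differ;
    the transcript whose 5' end is furthest upstream is chosen so the
    promoter window never overlaps transcribed sequence of any variant.
    The winning transcript id is recorded for audit.
    """
    gene = db[gene_id]
    transcripts = [
        t
        for t in db.children(gene, level=1)
        if t.featuretype in _TRANSCRIPT_TYPES
    ]
    if not transcripts:
        raise AnnotationError(f"gene {gene_id!r} has no transcript features")
    if gene.strand == "+":
        chosen = min(transcripts, key=lambda t: (t.start, t.id))
        tss = chosen.start
    elif gene.strand == "-":
        chosen = max(transcripts, key=lambda t: (t.end, t.id))
        tss = chosen.end
    else:
        raise AnnotationError(f"gene {gene_id!r} has no strand")

    cds = list(db.children(chosen, featuretype="CDS"))
    if cds:
        cds_start = (
            min(c.start for c in cds)
            if gene.strand == "+"
            else max(c.end for c in cds)
        )
    else:
        logger.warning(
            "gene %s transcript %s has no CDS; treating TSS as start codon",
            gene_id,
            chosen.id,
        )
        cds_start = tss
    return GeneModel(
        gene_id=gene_id,
        chromosome=gene.seqid,
        strand=gene.strand,
        tss=tss,
        cds_start=cds_start,
        source_transcript=chosen.id,
    )


def gene_models(
    db: gffutils.FeatureDB, gene_ids: Optional[Iterable[str]] = None
) -> Iterator[GeneModel]:
    ids = (
        list(gene_ids)
        if gene_ids is not None
        else [g.id for g in db.features_of_type("gene")]
    )
    for gene_id in ids:
        yield choose_tss(db, gene_id)


def _fetch(genome: Fasta, chrom: str, start: int, end: int) -> str:
    """1-based inclusive fetch; empty when the interval is empty."""
    if end < start:
        return ""
    return str(genome[chrom][start - 1 : end])


def extract_promoter(
    gene: GeneModel,
    genome: Fasta,
    mode: PromoterMode,
    upstream_2kb: int = UPSTREAM_2KB_LENGTH,
    upstream_extended: int = UPSTREAM_EXTENDED_LENGTH,
) -> PromoterRegion:
    """Extract a promoter window for one gene.

    The window is truncated (never padded) at contig edges, matching the
    shorter analyzed lengths seen for genes near assembly gaps.
    """
    if gene.chromosome not in genome:
        raise KeyError(f"chromosome {gene.chromosome!r} not in genome")
    contig_len = len(genome[gene.chromosome])
    want = (
        upstream_2kb if mode is PromoterMode.UPSTREAM_2KB else upstream_extended
    )

    if gene.strand == "+":
        up_start = max(1, gene.tss - want)
        up_end = gene.tss - 1
        upstream = _fetch(genome, gene.chromosome, up_start, up_end)
        utr = (
            _fetch(genome, gene.chromosome, gene.tss, gene.cds_start - 1)
            if mode is PromoterMode.EXTENDED_5KB_PLUS_5UTR
            else ""
        )
        sequence = upstream + utr
        interval_start = up_start
        interval_end = gene.cds_start - 1 if utr else up_end
    else:
        up_start = gene.tss + 1
        up_end = min(contig_len, gene.tss + want)
        upstream = reverse_complement(
            _fetch(genome, gene.chromosome, up_start, up_end)
        )
        utr = (
            reverse_complement(
                _fetch(genome, gene.chromosome, gene.cds_start + 1, gene.tss)
            )
            if mode is PromoterMode.EXTENDED_5KB_PLUS_5UTR
            else ""
        )
        sequence = upstream + utr
        interval_start = gene.cds_start + 1 if utr else up_start
        interval_end = up_end

    got_upstream = len(upstream)
    if got_upstream < want:
        logger.info(
            "gene %s: upstream window truncated to %d nt at contig edge",
            gene.gene_id,
            got_upstream,
        )
    if not sequence:
        logger.warning("gene %s: empty promoter region", gene.gene_id)
        # degenerate, but representable: an empty interval at the TSS
        interval_start, interval_end = gene.tss, gene.tss - 1

    return PromoterRegion(
        gene_id=gene.gene_id,
        mode=mode,
        sequence=sequence,
        analyzed_length=len(sequence),
        fiveprime_utr_length=(
            len(utr) if mode is PromoterMode.EXTENDED_5KB_PLUS_5UTR else 0
        ),
        genomic_interval=(
            gene.chromosome,
            interval_start,
            interval_end,
            gene.strand,
        ),
    )


def write_promoters_fasta(
    regions: Iterable[PromoterRegion], path: Union[str, Path]
) -> None:
    """Write promoters as FASTA with ``gene_id|mode|analyzed_length|utr_len`` headers."""
    with open(path, "w") as handle:
        for region in regions:
            header = (
                f"{region.gene_id}|{region.mode.value}"
                f"|{region.analyzed_length}|{region.fiveprime_utr_length}"
            )
            handle.write(f">{header}\n")
            seq = region.sequence
            for off in range(0, len(seq), 60):
                handle.write(seq[off : off + 60] + "\n")


def read_promoters_fasta(
    path: Union[str, Path],
) -> list[tuple[str, str, int, int, str]]:
    """Read back promoters written by :func:`write_promoters_fasta`.

    Returns ``(gene_id, mode, analyzed_length, utr_len, sequence)`` tuples.
    Plain FASTA headers (no pipes) are accepted with default metadata.
    """
    from Bio import SeqIO

    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        fields = record.description.split("|")
        seq = str(record.seq)
        if len(fields) >= 4:
            out.append(
                (fields[0], fields[1], int(fields[2]), int(fields[3]), seq)
            )
        else:
            out.append((record.id, "", len(seq), 0, seq))
    return out
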