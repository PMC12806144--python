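"""TSS selection, proximal promoter windows, and CREF matrix assembly.

The proximal regulatory window of a gene is the 1501-bp region from 1000 bp
upstream of the transcription start site (TSS) to 500 bp downstream of it,
taken in transcription orientation and including the TSS base itself.  For a
gene with multiple annotated transcripts, the TSS is the start of the most
upstream transcript toward the 5' end.

All internal coordinates are 0-based half-open; GFF3 input is converted from
its 1-based inclusive convention on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
from pyfaidx import Fasta

from .matrix import CrefMatrix
from .pwm import PwmLibrary, reverse_complement, scan_sequence

logger = logging.getLogger(__name__)

UPSTREAM = 1000
DOWNSTREAM = 500
WINDOW = UPSTREAM + 1 + DOWNSTREAM  # 1501, TSS base included


class AnnotationError(ValueError):
    """Raised for inconsistent gene annotations."""


class CoordinateError(ValueError):
    """Raised when a coordinate falls outside its contig."""


@dataclass(frozen=True)
class PromoterRegion:
    """A proximal promoter window (0-based half-open genomic interval)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if self.end - self.start > WINDOW:
            raise AnnotationError(f"{self.gene_id}: window longer than {WINDOW} bp")

    def __len__(self) -> int:
        return self.end - self.start


def select_tss(transcripts: list[tuple[str, str, int, int, str]]) -> tuple[int, str]:
    """Select the TSS from a gene's transcripts.

    Each transcript is ``(transcript_id, chrom, start, end, strand)`` with a
    0-based half-open interval.  Returns ``(tss, strand)`` where the TSS is
    the 0-based coordinate of the 5'-most transcript start: the minimum start
    on the plus strand, the maximum end-1 on the minus strand.  Ties between
    transcripts are broken by lexicographic transcript id (the rule is
    coordinate-driven, so ties do not change the result).
    """
    if not transcripts:
        raise AnnotationError("gene has no transcripts")
    transcripts = sorted(transcripts, key=lambda t: t[0])
    chroms = {t[1] for t in transcripts}
    strands = {t[4] for t in transcripts}
    if len(chroms) > 1:
        raise AnnotationError(f"transcripts on multiple contigs: {sorted(chroms)}")
    if len(strands) > 1:
        raise AnnotationError(f"transcripts on mixed strands: {sorted(strands)}")
    strand = strands.pop()
    if strand == "+":
        tss = min(t[2] for t in transcripts)
    elif strand == "-":
        tss = max(t[3] for t in transcripts) - 1
    else:
        raise AnnotationError(f"invalid strand {strand!r}")
    return tss, strand


def promoter_interval(
    tss: int, strand: str, chrom_length: int
) -> tuple[int, int, bool]:
    """0-based half-open promoter interval for a TSS, clipped at contig ends."""
    if not (0 <= tss < chrom_length):
        raise CoordinateError(f"TSS {tss} outside contig of length {chrom_length}")
    if strand == "+":
        start, end = tss - UPSTREAM, tss + DOWNSTREAM + 1
    else:
        start, end = tss - DOWNSTREAM, tss + UPSTREAM + 1
    cstart, cend = max(start, 0), min(end, chrom_length)
    return cstart, cend, (cstart != start or cend != end)


def extract_promoter(
    sequence: str, gene_id: str, chrom: str, tss: int, strand: str
) -> tuple[PromoterRegion, str]:
    """Extract the promoter window from a contig sequence.

    Returns the region and its 5'->3' nucleotide sequence (reverse complement
    of the genomic slice for minus-strand genes).
    """
    start, end, clipped = promoter_interval(tss, strand, len(sequence))
    region = PromoterRegion(gene_id, chrom, start, end, strand, tss, clipped)
    seq = sequence[start:end]
    if strand == "-":
        seq = reverse_complement(seq)
    return region, seq.upper()


def _open_annotation(annotation: str | Path | gffutils.FeatureDB) -> gffutils.FeatureDB:
    if isinstance(annotation, gffutils.FeatureDB):
        return annotation
    return gffutils.create_db(
        str(annotation),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )


_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def gene_promoters(
    genome: Fasta, db: gffutils.FeatureDB
) -> list[tuple[str, PromoterRegion, str]]:
    """All resolvable promoter windows, one per gene, in annotation order.

    Genes with missing contigs, no transcripts, or inconsistent annotations
    are dropped and logged.
    """
    out = []
    for gene in db.features_of_type("gene", order_by="start"):
        gid = gene.attributes.get("gene_id", [gene.id])[0]
        try:
            transcripts = [
                (t.id, t.seqid, t.start - 1, t.end, t.strand)
                for t in db.children(gene, featuretype=_TRANSCRIPT_TYPES)
            ]
            if not transcripts:
                # single-feature annotations: treat the gene as one transcript
                transcripts = [
                    (gene.id, gene.seqid, gene.start - 1, gene.end, gene.strand)
                ]
            tss, strand = select_tss(transcripts)
            chrom = transcripts[0][1]
            if chrom not in genome:
                raise CoordinateError(f"contig {chrom!r} not in genome")
            seq = str(genome[chrom][:])
            region, pseq = extract_promoter(seq, gid, chrom, tss, strand)
        except (AnnotationError, CoordinateError) as exc:
            logger.warning("dropping gene %s: %s", gid, exc)
            continue
        out.append((gid, region, pseq))
    return out


def build_cref(
    genome: str | Path | Fasta,
    annotation: str | Path | gffutils.FeatureDB,
    pwm_lib: PwmLibrary,
    profile: str = "minFN",
    species: str = "unknown",
) -> CrefMatrix:
    """Assemble the CREF matrix: promoter-window motif counts per gene.

    Rows follow the annotation's gene order (genes with unresolvable TSS are
    dropped and logged); columns follow the PWM library order.
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    db = _open_annotation(annotation)
    promoters = gene_promoters(fa, db)
    if not promoters:
        raise AnnotationError("no annotated gene could be resolved on the genome")
    gene_ids = [gid for gid, _, _ in promoters]
    counts = np.zeros((len(promoters), len(pwm_lib)), dtype=np.int64)
    for i, (_, _, pseq) in enumerate(promoters):
        for j, pwm in enumerate(pwm_lib):
            counts[i, j] = scan_sequence(pwm, pseq, profile)
    return CrefMatrix(counts, gene_ids, pwm_lib.motif_ids, species=species)
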