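"""Consensus outliers and transcriptome annotation of outlier SNPs.

Loci flagged by both scans ("best outliers") have their 80-bp flanking
window — two adjacent 36-bp RAD tags around the SNP — aligned locally
against a transcriptome.  A hit is an unambiguous positive only if some
aligned block reaches >=90% identity over >=25 aligned columns and covers
the SNP position; this guards against non-specific similarity among
homologous sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .align import LocalAlignment, smith_waterman
from .core import LocusInfo

__all__ = [
    "AnnotationHit",
    "consensus_outliers",
    "read_fasta",
    "extract_flank_window",
    "annotate_outlier",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AnnotationHit:
    locus_id: str
    transcript_id: str
    alignment: LocalAlignment
    strand: str  # "+" or "-"
    spans_snp: bool
    positive: bool

    @property
    def identity(self) -> float:
        return self.alignment.identity

    @property
    def block_length(self) -> int:
        return self.alignment.n_columns


def consensus_outliers(flags_a, flags_b):
    """Loci flagged by both scans.

    Accepts either two sets of flagged locus ids, or two mappings
    ``locus_id -> bool`` over the same locus universe (mismatched universes
    are an error).  Returns the set of shared outliers.
    """
    if isinstance(flags_a, Mapping) and isinstance(flags_b, Mapping):
        if set(flags_a) != set(flags_b):
            raise ValueError("scans cover different locus universes")
        return {k for k in flags_a if flags_a[k] and flags_b[k]}
    return set(flags_a) & set(flags_b)


def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file into an id -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def extract_flank_window(
    reference: "Mapping[str, str] | str",
    locus: LocusInfo,
    width: int = 80,
) -> tuple[str, int]:
    """Window of ``width`` bases centered on the SNP, clipped at contig ends.

    With the default width of 80 this covers the two adjacent 36-bp RAD
    tags around the SNP.  Internally 0-based half-open: the window is
    ``[pos - width//2, pos - width//2 + width)`` around the 0-based SNP
    index.  Returns ``(sequence, snp_offset_within_window)``.
    """
    contigs = read_fasta(reference) if isinstance(reference, str) else reference
    if locus.contig not in contigs:
        raise KeyError(f"contig {locus.contig!r} absent from reference")
    seq = contigs[locus.contig]
    snp = locus.position - 1
    if not 0 <= snp < len(seq):
        raise ValueError(
            f"{locus.locus_id}: position {locus.position} outside contig "
            f"{locus.contig} (length {len(seq)})"
        )
    start = max(0, snp - width // 2)
    end = min(len(seq), snp - width // 2 + width)
    return seq[start:end], snp - start


def annotate_outlier(
    window: str,
    snp_offset: int,
    transcriptome: "Mapping[str, str] | str",
    locus_id: str = "",
    min_identity: float = 0.90,
    min_length: int = 25,
    require_flank: int = 0,
) -> list[AnnotationHit]:
    """Align the flanking window to every transcript, both orientations.

    A hit is positive iff its aligned block reaches ``min_identity`` over
    at least ``min_length`` aligned columns and covers the SNP column
    (optionally with ``require_flank`` aligned bases on each side).
    Positive hits are ranked first, by identity x block length descending.
    """
    transcripts = (
        read_fasta(transcriptome) if isinstance(transcriptome, str) else transcriptome
    )
    hits: list[AnnotationHit] = []
    for tx_id, tx_seq in transcripts.items():
        best: tuple[LocalAlignment, str] | None = None
        for strand, qseq, offset in (
            ("+", window, snp_offset),
            ("-", revcomp(window), len(window) - 1 - snp_offset),
        ):
            aln = smith_waterman(qseq, tx_seq)
            if aln is None:
                continue
            if best is None or aln.score > best[0].score:
                best = (aln, strand)
        if best is None:
            continue
        aln, strand = best
        offset = snp_offset if strand == "+" else len(window) - 1 - snp_offset
        spans = (
            aln.query_start + require_flank
            <= offset
            < aln.query_end - require_flank
        )
        positive = (
            aln.identity >= min_identity
            and aln.n_columns >= min_length
            and spans
        )
        hits.append(
            AnnotationHit(
                locus_id=locus_id,
                transcript_id=tx_id,
                alignment=aln,
                strand=strand,
                spans_snp=spans,
                positive=positive,
            )
        )
    hits.sort(
        key=lambda h: (
            not h.positive,
            -(h.identity * h.block_length),
            h.transcript_id,
        )
    )
    return hits
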