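"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ (plain or gzip) come in through Biopython, SAM through pysam
and GTF through gffutils.  Everything is normalized into a small internal
data model that uses 0-based half-open coordinates throughout; GTF's
1-based inclusive intervals are converted on parse and BED6 is emitted
natively.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Columns of the final tab-separated interaction table, in order.
INTERACTION_COLUMNS = [
    "read_id",
    "arm1_read_start", "arm1_read_end",
    "arm1_ref_id", "arm1_ref_start", "arm1_ref_end", "arm1_strand",
    "arm1_cigar", "arm1_locus_id", "arm1_crl_id",
    "arm1_gene_id", "arm1_gene_symbol", "arm1_biotype", "arm1_region",
    "arm1_posterior", "arm1_tpm",
    "arm2_read_start", "arm2_read_end",
    "arm2_ref_id", "arm2_ref_start", "arm2_ref_end", "arm2_strand",
    "arm2_cigar", "arm2_locus_id", "arm2_crl_id",
    "arm2_gene_id", "arm2_gene_symbol", "arm2_biotype", "arm2_region",
    "arm2_posterior", "arm2_tpm",
    "score",
    "hybrid_structure", "hybrid_energy",
]


class ParseError(ValueError):
    """Raised for malformed records in any of the supported formats."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ReadRecord:
    """A sequencing read, possibly collapsed from PCR duplicates.

    ``umi`` is the unique molecular identifier split off the 5' end of the
    raw sequence; ``copy_count`` is the number of identical raw reads this
    record represents after deduplication.
    """

    read_id: str
    sequence: str
    quality: Optional[str] = None
    umi: Optional[str] = None
    copy_count: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"read {self.read_id!r}: empty sequence")
        if self.copy_count < 1:
            raise ValueError(f"read {self.read_id!r}: copy_count must be >= 1")


@dataclass
class AlignmentSegment:
    """One aligned portion of a read on a reference.

    Coordinates are 0-based half-open on both the read and the reference.
    ``pass_id`` records which alignment pass produced the hit and ``ref_db``
    which of the (up to two) split references it is on.  ``group_id`` ties
    a primary record and its expanded XA alternatives together.
    """

    read_id: str
    read_start: int
    read_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str
    cigar: str = "*"
    score: int = 0
    pass_id: int = 1
    ref_db: int = 1
    group_id: Optional[int] = None
    locus_id: Optional[str] = None  # set once expressed loci are built

    def __post_init__(self) -> None:
        if not self.read_start < self.read_end:
            raise ValueError(
                f"{self.read_id}: read interval [{self.read_start},{self.read_end}) is empty")
        if not self.ref_start < self.ref_end:
            raise ValueError(
                f"{self.read_id}: ref interval [{self.ref_start},{self.ref_end}) is empty")
        if self.strand not in "+-":
            raise ValueError(f"{self.read_id}: bad strand {self.strand!r}")

    @property
    def read_span(self) -> int:
        """Aligned read length (the 'read coverage' of this hit)."""
        return self.read_end - self.read_start

    def key(self) -> tuple:
        """Identity key used for cross-pass duplicate removal."""
        return (self.read_id, self.read_start, self.read_end,
                self.ref_id, self.ref_start, self.ref_end, self.strand)


@dataclass
class TranscriptModel:
    """Exon structure and annotation of one transcript.

    ``exons`` are genomic 0-based half-open intervals sorted in
    transcription order (ascending genomic for '+', descending for '-').
    ``cds`` is the genomic (start, end) pair delimiting the coding region,
    when annotated.
    """

    transcript_id: str
    gene_id: str = ""
    gene_symbol: str = ""
    biotype: str = ""
    chrom: str = ""
    strand: str = "+"
    exons: list = field(default_factory=list)
    cds: Optional[tuple] = None

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _open_text(path: PathLike):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_fastx(handle) -> str:
    first = handle.read(1)
    handle.seek(0)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError("file is neither FASTA nor FASTQ (first line must start with '>' or '@')")


def read_fastx(path: PathLike, umi_length: Optional[int] = None) -> Iterator[ReadRecord]:
    """Parse a FASTA or FASTQ file (plain or gzip) into ReadRecords.

    If ``umi_length`` is set, the first ``umi_length`` bases of every read
    are split off into the ``umi`` field and removed from the sequence.
    Reads not longer than the UMI are skipped with a warning.
    """
    with _open_text(path) as handle:
        fmt = _sniff_fastx(handle)
        for rec in SeqIO.parse(handle, fmt):
            seq = str(rec.seq).upper()
            if not seq:
                raise ParseError(f"{path}: record {rec.id!r} has empty sequence")
            qual = None
            if fmt == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            umi = None
            if umi_length:
                if umi_length >= len(seq):
                    logger.warning(
                        "read %s shorter than UMI length %d; skipped", rec.id, umi_length)
                    continue
                umi, seq = seq[:umi_length], seq[umi_length:]
                if qual is not None:
                    qual = qual[umi_length:]
            yield ReadRecord(read_id=rec.id, sequence=seq, quality=qual, umi=umi)


def read_fasta_dict(path: PathLike) -> dict:
    """Load a FASTA file as an ordered ``{id: sequence}`` dict."""
    return {r.read_id: r.sequence for r in read_fastx(path)}


def write_fasta(records: Iterable[ReadRecord], path: PathLike) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.read_id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_XA_ENTRY_RE = re.compile(r"([^,;]+),([+-]?\d+),([0-9MIDNSHP=XS]+),(\d+)")


def _cigar_ops(cigar: str) -> list:
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise ParseError(f"unparsable CIGAR {cigar!r}")
    return [(int(n), o) for n, o in ops]


def _cigar_read_interval(cigar: str, reverse: bool, read_length: Optional[int] = None) -> tuple:
    """Read interval [start, end) implied by the CIGAR's clips.

    Clip arithmetic is done on the stored (aligned) orientation; for a
    reverse-strand hit the interval is flipped back onto the original read
    when the read length is known.
    """
    ops = _cigar_ops(cigar)
    lead = ops[0][0] if ops[0][1] in "SH" else 0
    tail = ops[-1][0] if ops[-1][1] in "SH" else 0
    aligned = sum(n for n, o in ops if o in "MI=X")
    total = lead + tail + aligned
    start, end = lead, lead + aligned
    if reverse and read_length is None:
        read_length = total
    if reverse:
        start, end = read_length - end, read_length - start
    return start, end


def _cigar_ref_span(cigar: str) -> int:
    return sum(n for n, o in _cigar_ops(cigar) if o in "MDN=X")


def parse_sam(path: PathLike, expand_xa: bool = True, max_alternatives: int = 100,
              pass_id: int = 1, ref_db: int = 1) -> list:
    """Parse SAM alignments into AlignmentSegments.

    Every mapped primary/secondary/supplementary record yields one segment;
    with ``expand_xa`` each entry of a BWA-style XA tag
    (``chr,±pos,CIGAR,NM;``) yields an additional segment in the same
    group.  Unmapped records are skipped.  Read intervals are recovered
    from CIGAR soft/hard clips.
    """
    segments: list = []
    group = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            cigar = aln.cigarstring
            if cigar is None:
                logger.warning("record %s has no CIGAR; skipped", aln.query_name)
                continue
            read_len = aln.infer_read_length()
            if aln.query_sequence is None and not aln.is_supplementary and not aln.is_secondary:
                logger.warning("primary record %s lacks sequence; using CIGAR lengths",
                               aln.query_name)
            try:
                rstart, rend = _cigar_read_interval(cigar, aln.is_reverse, read_len)
            except ParseError as exc:
                raise ParseError(f"record {aln.query_name}: {exc}") from exc
            group += 1
            score = aln.get_tag("AS") if aln.has_tag("AS") else 0
            segments.append(AlignmentSegment(
                read_id=aln.query_name,
                read_start=rstart, read_end=rend,
                ref_id=aln.reference_name,
                ref_start=aln.reference_start, ref_end=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
                cigar=cigar, score=int(score),
                pass_id=pass_id, ref_db=ref_db, group_id=group))
            if expand_xa and aln.has_tag("XA"):
                entries = [e for e in str(aln.get_tag("XA")).split(";") if e]
                for entry in entries[:max_alternatives]:
                    m = _XA_ENTRY_RE.fullmatch(entry)
                    if m is None:
                        raise ParseError(f"record {aln.query_name}: bad XA entry {entry!r}")
                    ref, pos, xcigar, _nm = m.groups()
                    strand = "-" if pos.startswith("-") else "+"
                    start = abs(int(pos)) - 1  # XA positions are 1-based
                    xs, xe = _cigar_read_interval(xcigar, strand == "-", read_len)
                    segments.append(AlignmentSegment(
                        read_id=aln.query_name,
                        read_start=xs, read_end=xe,
                        ref_id=ref, ref_start=start,
                        ref_end=start + _cigar_ref_span(xcigar),
                        strand=strand, cigar=xcigar, score=0,
                        pass_id=pass_id, ref_db=ref_db, group_id=group))
    return segments


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def parse_gtf(path: PathLike) -> dict:
    """Parse a GTF annotation into ``{transcript_id: TranscriptModel}``.

    GTF 1-based inclusive coordinates become 0-based half-open; exons are
    ordered 5'->3' in transcript orientation.  Transcripts without exon
    features are excluded with a warning.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, disable_infer_genes=True,
                            disable_infer_transcripts=True)

    def attr(feat, *names) -> str:
        for name in names:
            if name in feat.attributes:
                return feat.attributes[name][0]
        return ""

    models: dict = {}
    exons_by_tx: dict = {}
    cds_by_tx: dict = {}
    for feat in db.all_features():
        tid = attr(feat, "transcript_id")
        if not tid:
            continue
        if feat.featuretype == "exon":
            exons_by_tx.setdefault(tid, []).append((feat.start - 1, feat.end))
        elif feat.featuretype == "CDS":
            lo, hi = cds_by_tx.get(tid, (feat.start - 1, feat.end))
            cds_by_tx[tid] = (min(lo, feat.start - 1), max(hi, feat.end))
        if tid not in models:
            models[tid] = TranscriptModel(
                transcript_id=tid,
                gene_id=attr(feat, "gene_id"),
                gene_symbol=attr(feat, "gene_name", "gene_symbol"),
                biotype=attr(feat, "transcript_biotype", "gene_biotype", "biotype"),
                chrom=feat.seqid, strand=feat.strand if feat.strand in "+-" else "+")
    out: dict = {}
    for tid, model in models.items():
        exons = sorted(exons_by_tx.get(tid, []))
        if not exons:
            logger.warning("transcript %s has no exon features; excluded", tid)
            continue
        if model.strand == "-":
            exons = exons[::-1]
        model.exons = exons
        model.cds = cds_by_tx.get(tid)
        out[tid] = model
    if not out:
        logger.warning("%s: no transcripts with exons found", path)
    return out


# ---------------------------------------------------------------------------
# BED and the interaction table
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable, path: PathLike) -> None:
    """Write BED6 lines for (chrom, start, end, name, score, strand) tuples
    or objects exposing those attributes."""
    with open(path, "w") as out:
        for item in intervals:
            if isinstance(item, tuple):
                chrom, start, end, name, score, strand = item
            else:
                chrom, start, end = item.ref_id, item.ref_start, item.ref_end
                name, score, strand = getattr(item, "read_id", "."), 0, item.strand
            out.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: PathLike) -> list:
    """Read BED6 back into (chrom, start, end, name, score, strand) tuples."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}: BED6 line with {len(f)} fields: {line!r}")
            rows.append((f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]))
    return rows


def write_interactions(records: Iterable, path: PathLike) -> None:
    """Write InteractionRecords to the tab-separated interaction table."""
    with open(path, "w") as out:
        out.write("\t".join(INTERACTION_COLUMNS) + "\n")
        for rec in records:
            out.write("\t".join(str(v) for v in rec.to_row()) + "\n")
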