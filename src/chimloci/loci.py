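"""From alignments to expressed loci and chimeric read segments.

Alignments are optionally lifted from transcript to genomic coordinates
through the exon structure of a GTF annotation, merged along the
reference into *expressed loci* (interaction sites) by reciprocal
overlap, and merged along the read into *read segments* (chimeric arms).
A read with two or more non-overlapping segments is chimeric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .io_formats import AlignmentSegment, TranscriptModel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genomic blocks and coordinate lifting
# ---------------------------------------------------------------------------

@dataclass
class GenomicBlocks:
    """A (possibly spliced) genomic region: sorted, non-overlapping
    0-based half-open intervals on one chromosome strand."""

    chrom: str
    strand: str
    blocks: List[Tuple[int, int]]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def span(self) -> Tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


def to_genomic(segment: AlignmentSegment, model: Optional[TranscriptModel]) -> GenomicBlocks:
    """Lift a transcript-space alignment interval to genomic blocks.

    Spliced intervals become multiple blocks; minus-strand transcripts map
    with reversed orientation.  With no transcript model the operation is
    the identity on transcript coordinates.
    """
    if model is None:
        return GenomicBlocks(chrom=segment.ref_id, strand=segment.strand,
                             blocks=[(segment.ref_start, segment.ref_end)])
    if segment.ref_end > model.length:
        raise ValueError(
            f"alignment interval [{segment.ref_start},{segment.ref_end}) exceeds "
            f"transcript {model.transcript_id} length {model.length}")
    blocks = _lift_interval(model, segment.ref_start, segment.ref_end)
    return GenomicBlocks(chrom=model.chrom, strand=model.strand, blocks=blocks)


def _lift_interval(model: TranscriptModel, t_start: int, t_end: int) -> List[Tuple[int, int]]:
    """Map a transcript 0-based half-open interval through the exon chain."""
    blocks: List[Tuple[int, int]] = []
    offset = 0  # transcript coordinate at the 5' edge of the current exon
    for g_start, g_end in model.exons:
        exon_len = g_end - g_start
        lo = max(t_start, offset)
        hi = min(t_end, offset + exon_len)
        if lo < hi:
            if model.strand == "+":
                blocks.append((g_start + (lo - offset), g_start + (hi - offset)))
            else:
                blocks.append((g_end - (hi - offset), g_end - (lo - offset)))
        offset += exon_len
    return sorted(blocks)


def to_transcript(blocks: GenomicBlocks, model: TranscriptModel) -> Tuple[int, int]:
    """Inverse of :func:`to_genomic` for blocks fully inside the exons.

    Returns the transcript 0-based half-open interval covering exactly the
    given genomic blocks.
    """
    positions = []
    offset = 0
    index: Dict[int, int] = {}
    for g_start, g_end in model.exons:
        for i in range(g_end - g_start):
            g = g_start + i if model.strand == "+" else g_end - 1 - i
            index[g] = offset
            offset += 1
    for b_start, b_end in blocks.blocks:
        for g in range(b_start, b_end):
            if g not in index:
                raise ValueError(f"genomic position {g} is not exonic in "
                                 f"{model.transcript_id}")
            positions.append(index[g])
    return min(positions), max(positions) + 1


# ---------------------------------------------------------------------------
# expressed loci
# ---------------------------------------------------------------------------

@dataclass
class ExpressedLocus:
    """A merged reference region supporting a set of read segments."""

    locus_id: str
    ref_id: str
    strand: str
    blocks: List[Tuple[int, int]]
    read_segments: set = field(default_factory=set)
    alignments: List[AlignmentSegment] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


def _blocks_overlap(a: Sequence[Tuple[int, int]], b: Sequence[Tuple[int, int]]) -> int:
    """Total overlap length between two sorted block lists."""
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def _blocks_union(a: Sequence[Tuple[int, int]], b: Sequence[Tuple[int, int]]
                  ) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(list(a) + list(b)):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def merge_into_loci(segments: Sequence[AlignmentSegment],
                    models: Optional[Dict[str, TranscriptModel]] = None,
                    reciprocal_overlap: float = 0.7) -> List[ExpressedLocus]:
    """Merge alignments into expressed loci by strict reciprocal overlap.

    Alignments are grouped by (reference, strand) — genomic
    (chromosome, strand) when an annotation is given — sorted by start,
    and swept: an alignment joins the growing locus iff the overlap
    exceeds ``reciprocal_overlap`` of *both* the alignment length and the
    current locus length (total block length for spliced regions);
    otherwise it founds a new locus.  One reference may carry several
    loci.  Each locus records its supporting read-segment ids
    (``read_id|read_start-read_end``, resolved to merged segments later)
    and the contributing alignments.
    """
    lifted: List[Tuple[GenomicBlocks, AlignmentSegment]] = []
    for seg in segments:
        model = models.get(seg.ref_id) if models else None
        if models is not None and model is None:
            logger.warning("transcript %s absent from annotation; kept on "
                           "transcript coordinates", seg.ref_id)
        lifted.append((to_genomic(seg, model), seg))

    by_ref: Dict[Tuple[str, str], List[Tuple[GenomicBlocks, AlignmentSegment]]] = {}
    for blocks, seg in lifted:
        by_ref.setdefault((blocks.chrom, blocks.strand), []).append((blocks, seg))

    loci: List[ExpressedLocus] = []
    for (ref, strand) in sorted(by_ref):
        items = sorted(by_ref[(ref, strand)],
                       key=lambda t: (t[0].span[0], t[0].span[1], t[1].read_id))
        group: List[ExpressedLocus] = []
        current: Optional[ExpressedLocus] = None
        for blocks, seg in items:
            if current is not None:
                ov = _blocks_overlap(current.blocks, blocks.blocks)
                if (ov / blocks.length > reciprocal_overlap
                        and ov / current.length > reciprocal_overlap):
                    current.blocks = _blocks_union(current.blocks, blocks.blocks)
                    current.alignments.append(seg)
                    continue
            current = ExpressedLocus(locus_id="", ref_id=ref, strand=strand,
                                     blocks=list(blocks.blocks), alignments=[seg])
            group.append(current)
        # a locus that grew during the sweep can become mergeable with its
        # neighbour; iterate to the pairwise-non-mergeable fixed point
        _merge_to_fixed_point(group, reciprocal_overlap)
        loci.extend(group)
    for locus in loci:
        locus.locus_id = (f"{locus.ref_id}:{locus.start}-{locus.end}({locus.strand})")
    return loci


# ---------------------------------------------------------------------------
# read segments
# ---------------------------------------------------------------------------

@dataclass
class ReadSegment:
    """One aligned, non-overlapping portion of a read (a chimeric arm
    candidate), with all candidate alignments that were merged into it."""

    read_id: str
    segment_index: int
    read_start: int
    read_end: int
    alignments: List[AlignmentSegment] = field(default_factory=list)
    candidates: set = field(default_factory=set)  # locus ids after assignment

    @property
    def segment_id(self) -> str:
        return f"{self.read_id}|{self.segment_index}"


def _merge_to_fixed_point(group: List[ExpressedLocus], threshold: float) -> None:
    changed = True
    while changed:
        changed = False
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                ov = _blocks_overlap(a.blocks, b.blocks)
                if ov / a.length > threshold and ov / b.length > threshold:
                    a.blocks = _blocks_union(a.blocks, b.blocks)
                    a.alignments.extend(b.alignments)
                    del group[j]
                    changed = True
                    break
            if changed:
                break


def merge_read_segments(alignments: Sequence[AlignmentSegment],
                        segment_overlap: float = 0.7,
                        ) -> Tuple[List[ReadSegment], bool]:
    """Merge one read's alignments into read segments.

    Two read intervals are merged when their overlap is at least
    ``segment_overlap`` of *each* interval's length (repetitive references
    shift multi-mapped hits by a few bases; counting those as separate
    segments would dilute their weight in quantification).  Merging is
    transitive (single linkage) and the merged interval is the union.
    Segments are ordered by read start; a read is chimeric when it has
    two or more segments.
    """
    if not alignments:
        return [], False
    read_id = alignments[0].read_id
    items = sorted(alignments, key=lambda a: (a.read_start, a.read_end,
                                              a.ref_db, a.ref_id, a.ref_start))
    clusters: List[List[AlignmentSegment]] = []
    spans: List[Tuple[int, int]] = []
    for aln in items:
        placed = False
        for i, (lo, hi) in enumerate(spans):
            ov = min(hi, aln.read_end) - max(lo, aln.read_start)
            if ov <= 0:
                continue
            if (ov >= segment_overlap * (aln.read_end - aln.read_start)
                    and ov >= segment_overlap * (hi - lo)):
                clusters[i].append(aln)
                spans[i] = (min(lo, aln.read_start), max(hi, aln.read_end))
                placed = True
                break
        if not placed:
            clusters.append([aln])
            spans.append((aln.read_start, aln.read_end))

    # transitive closure: growing a span may make it mergeable with a later one
    changed = True
    while changed:
        changed = False
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                (lo1, hi1), (lo2, hi2) = spans[i], spans[j]
                ov = min(hi1, hi2) - max(lo1, lo2)
                if ov > 0 and ov >= segment_overlap * (hi1 - lo1) \
                        and ov >= segment_overlap * (hi2 - lo2):
                    spans[i] = (min(lo1, lo2), max(hi1, hi2))
                    clusters[i].extend(clusters[j])
                    del spans[j], clusters[j]
                    changed = True
                    break
            if changed:
                break

    order = sorted(range(len(spans)), key=lambda i: spans[i])
    segments = [ReadSegment(read_id=read_id, segment_index=k,
                            read_start=spans[i][0], read_end=spans[i][1],
                            alignments=clusters[i])
                for k, i in enumerate(order)]
    return segments, len(segments) >= 2


def assign_candidates(segments_by_read: Dict[str, List[ReadSegment]],
                      loci: Sequence[ExpressedLocus]) -> None:
    """Attach candidate locus ids to read segments and the merged
    read-segment ids to loci (replacing per-alignment placeholders)."""
    owner: Dict[int, ExpressedLocus] = {}
    for locus in loci:
        locus.read_segments = set()
        for aln in locus.alignments:
            owner[id(aln)] = locus
    for read_id, segments in segments_by_read.items():
        for seg in segments:
            for aln in seg.alignments:
                locus = owner.get(id(aln))
                if locus is None:
                    continue
                aln.locus_id = locus.locus_id
                seg.candidates.add(locus.locus_id)
                locus.read_segments.add(seg.segment_id)


def build_loci_and_segments(segments: Sequence[AlignmentSegment],
                            models: Optional[Dict[str, TranscriptModel]] = None,
                            reciprocal_overlap: float = 0.7,
                            segment_overlap: float = 0.7,
                            ) -> Tuple[List[ExpressedLocus],
                                       Dict[str, List[ReadSegment]]]:
    """Full locus/segment construction for a set of postprocessed
    alignments: merge per reference into loci, per read into segments,
    then cross-link candidates."""
    by_read: Dict[str, List[AlignmentSegment]] = {}
    for seg in segments:
        by_read.setdefault(seg.read_id, []).append(seg)
    segments_by_read = {rid: merge_read_segments(alns, segment_overlap)[0]
                        for rid, alns in sorted(by_read.items())}
    loci = merge_into_loci(segments, models, reciprocal_overlap)
    assign_candidates(segments_by_read, loci)
    loci = [l for l in loci if l.read_segments]
    return loci, segments_by_read
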