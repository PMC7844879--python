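"""Interaction extraction: pick the two most probable chimeric arms per
read, annotate them, optionally hybridize the locus sequences with an
external tool, and emit the final interaction table."""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .io_formats import TranscriptModel, write_interactions
from .loci import ReadSegment, to_transcript, GenomicBlocks

logger = logging.getLogger(__name__)


@dataclass
class Arm:
    """One selected chimeric arm: the read segment plus its chosen CRL,
    the representative alignment within that CRL, and annotation."""

    read_start: int
    read_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str
    cigar: str
    locus_id: str
    crl_id: str
    posterior: float
    tpm: float = 0.0
    gene_id: str = ""
    gene_symbol: str = ""
    biotype: str = ""
    region: str = "unannotated"
    #: all candidate alignments inside the chosen CRL, for benchmarking
    crl_alignments: list = field(default_factory=list)
    unique: bool = True


@dataclass
class InteractionRecord:
    """One chimeric read's two selected arms; arm1 has the smaller read
    start.  ``score`` is Pr[(s,s') in c<->c'], the product of the two arm
    posteriors."""

    read_id: str
    arm1: Arm
    arm2: Arm
    score: float
    hybrid_structure: str = "NA"
    hybrid_energy: str = "NA"

    def to_row(self) -> list:
        row = [self.read_id]
        for arm in (self.arm1, self.arm2):
            row += [arm.read_start, arm.read_end, arm.ref_id, arm.ref_start,
                    arm.ref_end, arm.strand, arm.cigar, arm.locus_id,
                    arm.crl_id, arm.gene_id or "NA", arm.gene_symbol or "NA",
                    arm.biotype or "NA", arm.region,
                    f"{arm.posterior:.6g}", f"{arm.tpm:.6g}"]
        row += [f"{self.score:.6g}", self.hybrid_structure, self.hybrid_energy]
        return row


def _best_crl(segment: ReadSegment, matrices, locus_to_crl: Dict[str, str]
              ) -> Optional[Tuple[str, float, bool]]:
    """(crl_id, posterior, unique argmax) for a quantified segment."""
    try:
        post = matrices.posterior_of(segment.segment_id)
    except ValueError:
        return None
    if not post:
        return None
    best_crl = max(post, key=lambda c: (post[c], c))
    best_p = post[best_crl]
    unique = sum(1 for p in post.values() if p == best_p) == 1
    return best_crl, best_p, unique


def select_arms(segments: Sequence[ReadSegment], matrices,
                locus_to_crl: Dict[str, str],
                crl_tpm: Optional[Dict[str, float]] = None,
                ) -> Optional[Tuple[Arm, Arm]]:
    """Choose the two most probable, read-non-overlapping arms.

    Each segment's best CRL is the argmax of its posterior row; among all
    pairs of segments with non-overlapping read intervals the pair with
    the highest posterior product wins.  Singleton reads (one segment)
    return None and are counted separately.
    """
    if len(segments) < 2:
        return None
    scored = []
    for seg in segments:
        best = _best_crl(seg, matrices, locus_to_crl)
        if best is not None:
            scored.append((seg, *best))
    best_pair = None
    best_product = -1.0
    for i in range(len(scored)):
        for j in range(i + 1, len(scored)):
            s1, s2 = scored[i], scored[j]
            a, b = (s1, s2) if s1[0].read_start <= s2[0].read_start else (s2, s1)
            if a[0].read_end > b[0].read_start:  # read-overlapping
                continue
            product = s1[2] * s2[2]
            if product > best_product:
                best_product = product
                best_pair = (a, b)
    if best_pair is None:
        return None
    return tuple(_make_arm(seg, crl_id, post, unique, locus_to_crl, crl_tpm)
                 for seg, crl_id, post, unique in best_pair)


def _make_arm(seg: ReadSegment, crl_id: str, posterior: float, unique: bool,
              locus_to_crl: Dict[str, str],
              crl_tpm: Optional[Dict[str, float]]) -> Arm:
    in_crl = [a for a in seg.alignments
              if a.locus_id is not None and locus_to_crl.get(a.locus_id) == crl_id]
    if not in_crl:  # defensive: posterior support implies membership
        in_crl = list(seg.alignments)
    # representative alignment: the highest-scoring hit whose locus is in
    # the chosen CRL; ties break deterministically on coordinates
    chosen = sorted(in_crl, key=lambda a: (-a.score, a.ref_id, a.ref_start))[0]
    return Arm(read_start=seg.read_start, read_end=seg.read_end,
               ref_id=chosen.ref_id, ref_start=chosen.ref_start,
               ref_end=chosen.ref_end, strand=chosen.strand, cigar=chosen.cigar,
               locus_id=chosen.locus_id or "",
               crl_id=crl_id, posterior=posterior,
               tpm=(crl_tpm or {}).get(crl_id, 0.0),
               crl_alignments=in_crl, unique=unique)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate(arm: Arm, models: Optional[Dict[str, TranscriptModel]]) -> Arm:
    """Attach gene annotation and classify the arm region.

    Protein-coding arms are classified by the position of the arm midpoint
    (in transcript coordinates) relative to the CDS bounds into
    5'UTR/CDS/3'UTR, strand-aware; other biotypes are 'noncoding';
    transcripts absent from the annotation stay 'unannotated'.
    """
    if not models or arm.ref_id not in models:
        arm.region = "unannotated"
        return arm
    model = models[arm.ref_id]
    arm.gene_id = model.gene_id
    arm.gene_symbol = model.gene_symbol
    arm.biotype = model.biotype
    if model.biotype not in ("protein_coding", "mRNA") or model.cds is None:
        arm.region = "noncoding"
        return arm
    cds_t = _cds_transcript_bounds(model)
    midpoint = (arm.ref_start + arm.ref_end) // 2
    if midpoint < cds_t[0]:
        arm.region = "5'UTR"
    elif midpoint >= cds_t[1]:
        arm.region = "3'UTR"
    else:
        arm.region = "CDS"
    return arm


def _cds_transcript_bounds(model: TranscriptModel) -> Tuple[int, int]:
    lo, hi = model.cds
    exonic = [(max(s, lo), min(e, hi)) for s, e in model.exons
              if max(s, lo) < min(e, hi)]
    blocks = GenomicBlocks(chrom=model.chrom, strand=model.strand,
                           blocks=sorted(exonic))
    return to_transcript(blocks, model)


# ---------------------------------------------------------------------------
# hybridization hook
# ---------------------------------------------------------------------------

def hybridize(seq1: str, seq2: str, tool: Optional[str] = "RNAduplex",
              ) -> Tuple[str, str]:
    """Predict the duplex of the two merged locus sequences.

    The prediction is delegated to an external tool (ViennaRNA RNAduplex
    or IntaRNA); the locus sequences carry the mapped-arm context, which
    is why they — and not the raw read arms — are hybridized.  A missing
    or failing tool degrades to ('NA', 'NA') and the record is kept.
    """
    if not seq1 or not seq2:
        raise ValueError("cannot hybridize an empty sequence")
    if tool is None or shutil.which(tool) is None:
        return "NA", "NA"
    try:
        if "intarna" in tool.lower():
            return _run_intarna(tool, seq1, seq2)
        return _run_rnaduplex(tool, seq1, seq2)
    except (subprocess.SubprocessError, ValueError, OSError) as exc:
        logger.warning("hybridizer %s failed (%s); hybrid set to NA", tool, exc)
        return "NA", "NA"


def _run_rnaduplex(tool: str, seq1: str, seq2: str) -> Tuple[str, str]:
    proc = subprocess.run([tool, "--noLP"], input=f"{seq1}\n{seq2}\n",
                          capture_output=True, text=True, check=True)
    # output like: ".((((&)))). 1,4 : 1,4 (-5.40)"
    line = proc.stdout.strip().splitlines()[-1]
    structure = line.split()[0]
    energy = line.rsplit("(", 1)[1].rstrip(")").strip()
    if "&" not in structure:
        raise ValueError(f"unexpected RNAduplex output: {line!r}")
    return structure, energy


def _run_intarna(tool: str, seq1: str, seq2: str) -> Tuple[str, str]:
    proc = subprocess.run(
        [tool, "-t", seq1, "-q", seq2, "--outMode", "C",
         "--outCsvCols", "hybridDB,E"],
        capture_output=True, text=True, check=True)
    lines = [l for l in proc.stdout.strip().splitlines() if l]
    if len(lines) < 2:
        return "NA", "NA"  # no favourable interaction found
    structure, energy = lines[1].split(";")[:2]
    return structure, energy


# ---------------------------------------------------------------------------
# final table
# ---------------------------------------------------------------------------

def filter_and_write(records: Sequence[InteractionRecord], path,
                     score_threshold: float = 0.0,
                     require_hybrid: bool = False,
                     n_singletons: int = 0, n_unmapped: int = 0,
                     ) -> Dict[str, int]:
    """Apply the score (and optional hybrid) filter and write the table.

    Returns the summary read accounting.
    """
    kept = [r for r in records if r.score >= score_threshold]
    if require_hybrid:
        kept = [r for r in kept if r.hybrid_structure != "NA"]
        if not kept and records:
            logger.warning("require_hybrid dropped every record; was a "
                           "hybridization tool available?")
    write_interactions(kept, path)
    return {
        "chimeric_reads": len({r.read_id for r in records}),
        "reported_interactions": len(kept),
        "singleton_reads": n_singletons,
        "unmapped_reads": n_unmapped,
    }
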