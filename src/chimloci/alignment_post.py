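"""Two-pass alignment orchestration and alignment post-processing.

The aligner itself is external (BWA-MEM through a subprocess contract and
fully bypassable with pre-made SAM files); what belongs to the method is
the post-processing: keep only sense-strand hits, keep only the
alternatives with the highest read coverage within each primary+XA group,
and drop pass-2 hits that duplicate a pass-1 hit.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .io_formats import AlignmentSegment, PathLike

logger = logging.getLogger(__name__)


class AlignerUnavailableError(RuntimeError):
    """The external aligner executable could not be found."""


@dataclass
class AlignerContract:
    """Parameters handed to the external 2-pass aligner.

    Pass 1 targets long, gapped chimeric segments (high score threshold);
    pass 2 rescues short, perfectly matching segments: it must forbid
    insertions/deletions (here via prohibitive gap penalties) and request
    up to ``max_alternatives`` suboptimal hits so no equally good hit is
    lost.
    """

    executable: Optional[str] = "bwa"
    pass1_params: str = "-k 12 -T 18"
    pass2_params: str = "-k 10 -T 10 -O 1000 -E 1000"
    max_alternatives: int = 100


def run_two_pass(reads: PathLike, references: Sequence[PathLike],
                 contract: AlignerContract, out_dir: PathLike) -> Dict[int, List[Path]]:
    """Run the external aligner twice per reference FASTA.

    Returns ``{ref_db: [pass1_sam, pass2_sam]}``.  Raises
    AlignerUnavailableError (with a pointer to the ``--sam`` bypass) when
    the executable is missing.
    """
    exe = contract.executable or "bwa"
    if shutil.which(exe) is None:
        raise AlignerUnavailableError(
            f"external aligner {exe!r} not found; supply pre-made alignments "
            "with --sam instead")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: Dict[int, List[Path]] = {}
    for db, ref in enumerate(references, start=1):
        ref = Path(ref)
        if not (ref.with_suffix(ref.suffix + ".bwt")).exists():
            subprocess.run([exe, "index", str(ref)], check=True,
                           capture_output=True)
        sams = []
        for pass_id, params in ((1, contract.pass1_params), (2, contract.pass2_params)):
            args = [exe, "mem"] + params.split()
            if pass_id == 2:
                args += ["-h", str(contract.max_alternatives)]
            args += [str(ref), str(reads)]
            sam_path = out_dir / f"ref{db}_pass{pass_id}.sam"
            with open(sam_path, "w") as out:
                subprocess.run(args, check=True, stdout=out,
                               stderr=subprocess.DEVNULL)
            sams.append(sam_path)
        outputs[db] = sams
    return outputs


def postprocess(segments: Sequence[AlignmentSegment]) -> List[AlignmentSegment]:
    """Apply the alignment filtering rules, in order:

    1. drop all antisense (``-`` strand) hits — the references are
       transcript sequences, so only sense hits are meaningful;
    2. within each primary+XA group, keep only the hits whose aligned
       read length equals the group's maximum read coverage;
    3. drop pass-2 hits identical (read id, read interval, reference,
       reference interval, strand) to a pass-1 hit.

    The result is a subset of the input, order-independent and idempotent.
    """
    sense = [s for s in segments if s.strand == "+"]

    groups: dict = {}
    for seg in sense:
        gid = seg.group_id if seg.group_id is not None else id(seg)
        groups.setdefault((seg.read_id, seg.pass_id, seg.ref_db, gid), []).append(seg)
    kept: List[AlignmentSegment] = []
    for members in groups.values():
        best = max(m.read_span for m in members)
        kept.extend(m for m in members if m.read_span == best)

    pass1_keys = {s.key() for s in kept if s.pass_id == 1}
    seen: set = set()
    out: List[AlignmentSegment] = []
    for seg in sorted(kept, key=lambda s: (s.pass_id, s.read_id, s.read_start,
                                           s.read_end, s.ref_db, s.ref_id, s.ref_start)):
        if seg.pass_id == 2 and seg.key() in pass1_keys:
            continue
        if seg.key() in seen:  # exact duplicates within a pass collapse too
            continue
        seen.add(seg.key())
        out.append(seg)
    return out
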