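"""Read deduplication.

Interactome libraries are heavily PCR amplified; identical reads with the
same UMI (or identical sequences when no UMI is used) are collapsed into a
single representative carrying a copy count.  Identical sequences with
*different* UMIs are genuinely distinct fragments and stay separate.
Reads shorter than ``min_length`` are discarded first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

from .io_formats import ReadRecord


@dataclass
class DedupReport:
    """Copy accounting for one deduplication run.

    ``input_reads`` counts input copies (records weighted by their
    ``copy_count``), so re-deduplicating already collapsed reads still
    balances: output copies + discarded_short == input_reads.
    """

    input_reads: int = 0
    output_reads: int = 0
    discarded_short: int = 0


def deduplicate(reads: Iterable[ReadRecord], min_length: int = 10,
                ) -> Tuple[List[ReadRecord], DedupReport]:
    """Collapse exact (sequence, UMI) duplicates and drop short reads.

    Output order is canonical (sorted by sequence, then UMI), so the
    result is independent of input order and the operation is idempotent.
    Each collapsed record keeps the lexicographically smallest member read
    id (stripped of any previous ``|N`` suffix), re-suffixed with ``|N``
    where N is the total multiplicity, keeping origins traceable without a
    lookup table.
    """
    report = DedupReport()
    groups: dict = {}  # (sequence, umi) -> [representative id, copies]
    for read in reads:
        report.input_reads += read.copy_count
        if len(read.sequence) < min_length:
            report.discarded_short += read.copy_count
            continue
        base_id = read.read_id.rsplit("|", 1)[0]
        key = (read.sequence, read.umi or "")
        bucket = groups.get(key)
        if bucket is None:
            groups[key] = [base_id, read.copy_count]
        else:
            bucket[0] = min(bucket[0], base_id)
            bucket[1] += read.copy_count

    out: List[ReadRecord] = []
    for (seq, umi), (rid, count) in sorted(groups.items()):
        out.append(ReadRecord(
            read_id=f"{rid}|{count}",
            sequence=seq,
            umi=umi or None,
            copy_count=count,
        ))
    report.output_reads = len(out)
    return out, report
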