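"""Benchmark simulation and evaluation.

Generates CLASH-style chimeric reads — direct fusions of a short
"miRNA-like" arm and a "target-like" arm, optionally with a random 5-nt
insert — over split references that contain families of near-identical
paralogous sequences, with per-read ground truth.  A built-in exhaustive
exact-match toy mapper makes benchmark round trips possible without any
external aligner, and the evaluator sorts every read into the seven
alignment categories used for chimeric-read benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import AlignmentSegment, ReadRecord

BASES = np.array(list("ACGT"))

CATEGORIES = ("perfect", "partial_multi", "both_multi", "partial_wrong",
              "both_wrong", "partial_miss", "both_miss")


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TrueArm:
    ref_id: str
    ref_start: int
    ref_end: int


@dataclass
class ReadTruth:
    read_id: str
    arm1: TrueArm  # miRNA-like arm (5' on the read)
    arm2: TrueArm  # target-like arm
    arm_length: int
    has_insert: bool


@dataclass
class BenchmarkTruth:
    reads: Dict[str, ReadTruth] = field(default_factory=dict)

    def write_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("read_id\tref1\tstart1\tend1\tref2\tstart2\tend2\t"
                      "arm_length\thas_insert\n")
            for t in self.reads.values():
                out.write(f"{t.read_id}\t{t.arm1.ref_id}\t{t.arm1.ref_start}\t"
                          f"{t.arm1.ref_end}\t{t.arm2.ref_id}\t{t.arm2.ref_start}\t"
                          f"{t.arm2.ref_end}\t{t.arm_length}\t{int(t.has_insert)}\n")

    @classmethod
    def read_tsv(cls, path) -> "BenchmarkTruth":
        truth = cls()
        with open(path) as fh:
            next(fh)
            for line in fh:
                f = line.rstrip("\n").split("\t")
                truth.reads[f[0]] = ReadTruth(
                    read_id=f[0],
                    arm1=TrueArm(f[1], int(f[2]), int(f[3])),
                    arm2=TrueArm(f[4], int(f[5]), int(f[6])),
                    arm_length=int(f[7]), has_insert=bool(int(f[8])))
        return truth


@dataclass
class Reference:
    """Split benchmark reference: short miRNA-like sequences and longer
    target-like sequences, with the paralog family of every entry."""

    mirnas: Dict[str, str]
    targets: Dict[str, str]
    families: Dict[str, str]  # ref_id -> family id


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))

def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def make_reference(n_families: int = 20, family_size: int = 1,
                   divergence: float = 0.0,
                   target_len_range: Tuple[int, int] = (50, 400),
                   mirna_len_range: Tuple[int, int] = (18, 25),
                   seed: int = 0) -> Reference:
    """Build split references with paralogous families.

    Each family is founded by a random sequence and filled with
    ``family_size`` copies mutated at per-base rate ``divergence``
    (divergence 0 gives identical family members, emulating recently
    duplicated paralogs).  Sequences duplicated *across* families are
    regenerated so that cross-family hits are never exact.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must be in [0,1], got {divergence}")
    rng = np.random.default_rng(seed)
    mirnas: Dict[str, str] = {}
    targets: Dict[str, str] = {}
    families: Dict[str, str] = {}
    for kind, pool, lo_hi in (("mir", mirnas, mirna_len_range),
                              ("tgt", targets, target_len_range)):
        seen_founders: set = set()
        for fam in range(n_families):
            length = int(rng.integers(lo_hi[0], lo_hi[1] + 1))
            founder = _random_seq(rng, length)
            while founder in seen_founders:
                founder = _random_seq(rng, length)
            seen_founders.add(founder)
            for copy in range(family_size):
                seq = founder if copy == 0 else _mutate(rng, founder, divergence)
                ref_id = f"{kind}_f{fam}_c{copy}"
                pool[ref_id] = seq
                families[ref_id] = f"{kind}_f{fam}"
    return Reference(mirnas=mirnas, targets=targets, families=families)


def write_reference_fasta(ref: Reference, mirna_path, target_path) -> None:
    for pool, path in ((ref.mirnas, mirna_path), (ref.targets, target_path)):
        with open(path, "w") as out:
            for rid in pool:
                out.write(f">{rid}\n{pool[rid]}\n")


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def make_chimeric_reads(ref: Reference, n_reads: int, arm_length: int = 20,
                        insert: bool = False, seed: int = 0,
                        mirna_ids: Optional[Sequence[str]] = None,
                        target_ids: Optional[Sequence[str]] = None,
                        ) -> Tuple[List[ReadRecord], BenchmarkTruth]:
    """Fuse a miRNA-like arm and a target-like arm into each read.

    Arms are ``arm_length``-nt substrings of randomly chosen references
    (the whole sequence when the reference is shorter).  With ``insert``,
    a random 5-nt sequence is placed uniformly between the arms or at
    either end.  Source references can be restricted (e.g. to one
    "expressed" family member) via ``mirna_ids``/``target_ids``.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    mirna_ids = sorted(mirna_ids if mirna_ids is not None else ref.mirnas)
    target_ids = sorted(target_ids if target_ids is not None else ref.targets)
    reads: List[ReadRecord] = []
    truth = BenchmarkTruth()
    for i in range(n_reads):
        rid = f"read{i}"
        m_id = mirna_ids[rng.integers(len(mirna_ids))]
        t_id = target_ids[rng.integers(len(target_ids))]
        arm1, t1 = _draw_arm(rng, m_id, ref.mirnas[m_id], arm_length)
        arm2, t2 = _draw_arm(rng, t_id, ref.targets[t_id], arm_length)
        seq = arm1 + arm2
        if insert:
            ins = _random_seq(rng, 5)
            where = rng.integers(3)  # 0: between, 1: 5' end, 2: 3' end
            if where == 0:
                seq = arm1 + ins + arm2
            elif where == 1:
                seq = ins + arm1 + arm2
            else:
                seq = arm1 + arm2 + ins
        reads.append(ReadRecord(read_id=rid, sequence=seq))
        truth.reads[rid] = ReadTruth(read_id=rid, arm1=t1, arm2=t2,
                                     arm_length=arm_length, has_insert=insert)
    return reads, truth


def _draw_arm(rng: np.random.Generator, ref_id: str, seq: str,
              arm_length: int) -> Tuple[str, TrueArm]:
    if len(seq) <= arm_length:
        return seq, TrueArm(ref_id, 0, len(seq))
    start = int(rng.integers(0, len(seq) - arm_length + 1))
    return seq[start:start + arm_length], TrueArm(ref_id, start, start + arm_length)


def make_singleton_reads(ref: Reference, ref_ids: Sequence[str], n_reads: int,
                         length: int = 30, seed: int = 0,
                         unique_only: bool = False) -> List[ReadRecord]:
    """Non-chimeric reads from chosen references, e.g. to give one family
    member extra expression evidence.  With ``unique_only`` only reads
    whose sequence occurs in a single reference are kept (retrying up to
    50x per read)."""
    rng = np.random.default_rng(seed)
    all_seqs = {**ref.mirnas, **ref.targets}
    reads: List[ReadRecord] = []
    ref_ids = sorted(ref_ids)
    for i in range(n_reads):
        for _ in range(50):
            rid = ref_ids[rng.integers(len(ref_ids))]
            seq = all_seqs[rid]
            arm, _ = _draw_arm(rng, rid, seq, length)
            if not unique_only or _count_hits(arm, all_seqs) == 1:
                reads.append(ReadRecord(read_id=f"sgl{i}", sequence=arm))
                break
    return reads


def _count_hits(pattern: str, pools: Dict[str, str]) -> int:
    return sum(_occurrences(pattern, seq) for seq in pools.values())


def _occurrences(pattern: str, text: str) -> int:
    count = start = 0
    while True:
        idx = text.find(pattern, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


# ---------------------------------------------------------------------------
# toy exact mapper
# ---------------------------------------------------------------------------

def exact_map(reads: Iterable[ReadRecord], ref_dbs: Sequence[Dict[str, str]],
              min_match: int = 10) -> List[AlignmentSegment]:
    """Exhaustive exact-match chimeric mapper.

    Scans each read left to right: at the current offset the longest
    substring with at least one exact occurrence in any reference is
    found by binary search; all of its occurrences become alignments
    (CIGAR ``<lead>S<len>M<tail>S``, score = match length), and the scan
    resumes behind the match.  Matches shorter than ``min_match`` are
    discarded, so a random 5-nt insert does not spawn arms.  Alignments
    feed the normal pipeline exactly like parsed SAM records.
    """
    segments: List[AlignmentSegment] = []
    group = 0
    for read in reads:
        seq = read.sequence
        n = len(seq)
        offset = 0
        while offset < n:
            length = _longest_match_at(seq, offset, ref_dbs)
            if length < min_match:
                offset += 1
                continue
            group += 1
            pattern = seq[offset:offset + length]
            for db, pool in enumerate(ref_dbs, start=1):
                for rid in pool:
                    text = pool[rid]
                    start = 0
                    while True:
                        idx = text.find(pattern, start)
                        if idx < 0:
                            break
                        lead = f"{offset}S" if offset else ""
                        tail_n = n - offset - length
                        tail = f"{tail_n}S" if tail_n else ""
                        segments.append(AlignmentSegment(
                            read_id=read.read_id,
                            read_start=offset, read_end=offset + length,
                            ref_id=rid, ref_start=idx, ref_end=idx + length,
                            strand="+", cigar=f"{lead}{length}M{tail}",
                            score=length, pass_id=1, ref_db=db,
                            group_id=group))
                        start = idx + 1
            offset += length
    return segments


def _longest_match_at(seq: str, offset: int,
                      ref_dbs: Sequence[Dict[str, str]]) -> int:
    """Length of the longest substring of seq starting at offset with an
    exact occurrence anywhere in the references (binary search; occurrence
    is monotone decreasing in length)."""
    lo, hi = 0, len(seq) - offset  # lo: known hit, hi: longest tried
    def hit(length: int) -> bool:
        pattern = seq[offset:offset + length]
        return any(pattern in text for pool in ref_dbs for text in pool.values())
    if not hit(1):
        return 0
    lo = 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if hit(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------

@dataclass
class ArmPrediction:
    """One predicted arm: its candidate alignments (ref_id, start, end)
    and whether the arm counts as uniquely mapped."""

    alignments: List[Tuple[str, int, int]]
    unique: bool


@dataclass
class CategoryCounts:
    counts: Dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})

    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, category: str) -> float:
        total = self.total()
        return self.counts[category] / total if total else 0.0


def _arm_agreed(pred: ArmPrediction, true_arm: TrueArm, agree_overlap: float) -> bool:
    need = agree_overlap * (true_arm.ref_end - true_arm.ref_start)
    for ref_id, start, end in pred.alignments:
        if ref_id != true_arm.ref_id:
            continue
        ov = min(end, true_arm.ref_end) - max(start, true_arm.ref_start)
        if ov >= need:
            return True
    return False


def categorize(predictions: Dict[str, Tuple[Optional[ArmPrediction],
                                            Optional[ArmPrediction]]],
               truth: BenchmarkTruth,
               agree_overlap: float = 0.8) -> CategoryCounts:
    """Assign every simulated read to one of the seven categories.

    An arm is *agreed* when one of its alignments overlaps at least
    ``agree_overlap`` of the true arm interval on the true reference.
    Categories: perfect (2 unique agreed), partial_multi (1 unique + 1
    multi agreed), both_multi, partial_wrong (1 agreed + 1 mapped wrong),
    both_wrong, partial_miss (1 unmapped), both_miss.  Reads absent from
    ``predictions`` count as both_miss; a predicted read missing from the
    truth is an error.
    """
    unknown = set(predictions) - set(truth.reads)
    if unknown:
        raise ValueError(f"reads not present in truth: {sorted(unknown)[:5]}")
    counts = CategoryCounts()
    for read_id, t in truth.reads.items():
        arms = predictions.get(read_id, (None, None))
        counts.counts[_classify(arms, t, agree_overlap)] += 1
    return counts


def _classify(arms, t: ReadTruth, agree_overlap: float) -> str:
    a1, a2 = arms
    mapped = [a for a in (a1, a2) if a is not None and a.alignments]
    if len(mapped) == 0:
        return "both_miss"
    if len(mapped) == 1:
        return "partial_miss"
    # both arms mapped: match predicted arms to true arms by best agreement
    direct = (_arm_agreed(a1, t.arm1, agree_overlap),
              _arm_agreed(a2, t.arm2, agree_overlap))
    crossed = (_arm_agreed(a1, t.arm2, agree_overlap),
               _arm_agreed(a2, t.arm1, agree_overlap))
    agreed = direct if sum(direct) >= sum(crossed) else crossed
    n_agreed = sum(agreed)
    if n_agreed == 2:
        n_unique = sum(1 for a in (a1, a2) if a.unique)
        if n_unique == 2:
            return "perfect"
        if n_unique == 1:
            return "partial_multi"
        return "both_multi"
    if n_agreed == 1:
        return "partial_wrong"
    return "both_wrong"


# ---------------------------------------------------------------------------
# prediction builders for the two benchmark modes
# ---------------------------------------------------------------------------

def naive_predictions(segments: Sequence[AlignmentSegment],
                      ) -> Dict[str, Tuple[Optional[ArmPrediction],
                                           Optional[ArmPrediction]]]:
    """The longest-hit baseline applied directly to raw alignments.

    Per read, alignments are split into a left and right arm at the read
    midpoint of their intervals; within each arm only the longest hits
    are kept (all of them when tied), and an arm is unique when exactly
    one longest hit remains.
    """
    by_read: Dict[str, List[AlignmentSegment]] = {}
    for seg in segments:
        by_read.setdefault(seg.read_id, []).append(seg)
    out: Dict[str, Tuple[Optional[ArmPrediction], Optional[ArmPrediction]]] = {}
    for read_id, alns in by_read.items():
        read_len = max(a.read_end for a in alns)
        left = [a for a in alns if a.read_start + a.read_end < read_len]
        right = [a for a in alns if a.read_start + a.read_end >= read_len]
        out[read_id] = (_naive_arm(left), _naive_arm(right))
    return out


def _naive_arm(alns: List[AlignmentSegment]) -> Optional[ArmPrediction]:
    if not alns:
        return None
    best = max(a.read_span for a in alns)
    hits = [a for a in alns if a.read_span == best]
    return ArmPrediction(
        alignments=[(a.ref_id, a.ref_start, a.ref_end) for a in hits],
        unique=len(hits) == 1)


def pipeline_predictions(records: Sequence,
                      ) -> Dict[str, Tuple[Optional[ArmPrediction],
                                           Optional[ArmPrediction]]]:
    """Predictions from the pipeline's selected arms (InteractionRecords).

    An arm's alignment set is its candidate alignments within the chosen
    CRL; the arm is unique when its posterior row has a unique argmax.
    """
    out: Dict[str, Tuple[Optional[ArmPrediction], Optional[ArmPrediction]]] = {}
    for rec in records:
        arms = []
        for arm in (rec.arm1, rec.arm2):
            arms.append(ArmPrediction(
                alignments=[(a.ref_id, a.ref_start, a.ref_end)
                            for a in arm.crl_alignments],
                unique=arm.unique))
        out[rec.read_id] = tuple(arms)
    return out
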