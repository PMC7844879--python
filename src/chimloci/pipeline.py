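"""End-to-end workflow orchestration.

Stages run in fixed order — dedup, map, merge (loci/segments), CRL, EM
quantification, extraction — with plain files between stages, so every
intermediate can be inspected and the run is reproducible bit for bit:
the analysis path is fully deterministic and the only randomness (the
simulator) is governed by one seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import extract as ex
from . import simulate as sim
from .alignment_post import AlignerContract, postprocess, run_two_pass
from .crl import CommonReadLocus, build_crls
from .io_formats import (AlignmentSegment, ReadRecord, parse_gtf, parse_sam,
                         read_fasta_dict, read_fastx, write_bed,
                         write_interactions)
from .loci import build_loci_and_segments
from .preprocess import deduplicate
from .quant import build_y, em_quantify, tpm

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and paths of one pipeline run.

    Fraction-valued thresholds must lie in (0, 1]; the config is
    serialized verbatim into the run log.
    """

    reads: Optional[str] = None
    ref1: Optional[str] = None
    ref2: Optional[str] = None
    gtf: Optional[str] = None
    sam: List[str] = field(default_factory=list)
    out_dir: str = "chimloci_out"

    umi_length: int = 0
    min_length: int = 10
    reciprocal_overlap: float = 0.7
    segment_overlap: float = 0.7
    crl_share: float = 0.7
    epsilon: float = 1e-5
    max_iter: int = 1000
    max_alternatives: int = 100
    score_min: float = 0.0
    agree_overlap: float = 0.8
    hybridize_tool: Optional[str] = None
    require_hybrid: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("reciprocal_overlap", "segment_overlap", "crl_share",
                     "agree_overlap"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.max_alternatives < 1 or self.max_iter < 1:
            raise ValueError("max_alternatives and max_iter must be >= 1")


@dataclass
class PipelineResult:
    records: List[ex.InteractionRecord]
    loci: list
    crls: List[CommonReadLocus]
    abundances: object
    matrices: object
    segments_by_read: Dict[str, list]
    summary: Dict[str, object]


def run(config: RunConfig,
        reads: Optional[Sequence[ReadRecord]] = None,
        alignments: Optional[Sequence[AlignmentSegment]] = None,
        ) -> PipelineResult:
    """Execute the full workflow and write all outputs to ``out_dir``.

    ``reads``/``alignments`` may be passed in memory (the test and
    benchmark path); otherwise they come from the configured files.
    Any stage failure aborts with the stage name in the exception.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("chimloci")
    root.addHandler(log_handler)
    timings: Dict[str, float] = {}
    try:
        logger.info("config: %s", json.dumps(asdict(config), default=str))
        return _run_stages(config, out_dir, reads, alignments, timings)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _stage(timings, name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 4)
            if exc is not None:
                logger.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.3fs", name, timings[name])
    return _Timer()


def _run_stages(config, out_dir, reads, alignments, timings) -> PipelineResult:
    with _stage(timings, "dedup"):
        if reads is None:
            if config.reads is None:
                if alignments is None:
                    raise ValueError("no reads or alignments supplied")
                reads = []
            else:
                reads = list(read_fastx(config.reads,
                                        config.umi_length or None))
        deduped, report = deduplicate(reads, min_length=config.min_length)

    with _stage(timings, "map"):
        if alignments is None:
            alignments = _map_reads(config, deduped, out_dir)
        segments = postprocess(alignments)

    with _stage(timings, "merge"):
        models = parse_gtf(config.gtf) if config.gtf else None
        loci, segments_by_read = build_loci_and_segments(
            segments, models,
            reciprocal_overlap=config.reciprocal_overlap,
            segment_overlap=config.segment_overlap)
        write_bed([(l.ref_id, l.start, l.end, l.locus_id,
                    len(l.read_segments), l.strand) for l in loci],
                  out_dir / "loci.bed")

    with _stage(timings, "crl"):
        crls = build_crls(loci, share_threshold=config.crl_share)
        with open(out_dir / "crls.tsv", "w") as out:
            out.write("crl_id\tmember_loci\tn_reads\n")
            for crl in crls:
                out.write(f"{crl.crl_id}\t{','.join(sorted(crl.member_loci))}\t"
                          f"{len(crl.read_set)}\n")

    with _stage(timings, "quantify"):
        all_segments = [seg for _, segs in sorted(segments_by_read.items())
                        for seg in segs]
        if all_segments and crls:
            matrices = build_y(all_segments, crls)
            abundances, matrices = em_quantify(
                matrices, epsilon=config.epsilon, max_iter=config.max_iter)
            tpms = tpm(abundances)
            for i, crl in enumerate(crls):
                crl.rho = float(abundances.rho[i])
                crl.tpm = float(tpms[i])
        else:
            matrices, abundances = None, None
        with open(out_dir / "quant.tsv", "w") as out:
            out.write("crl_id\trho\ttpm\tn_members\n")
            for crl in crls:
                out.write(f"{crl.crl_id}\t{crl.rho:.6g}\t{crl.tpm:.6g}\t"
                          f"{len(crl.member_loci)}\n")

    with _stage(timings, "extract"):
        locus_to_crl = {l: c.crl_id for c in crls for l in c.member_loci}
        crl_tpm = {c.crl_id: c.tpm for c in crls}
        records: List[ex.InteractionRecord] = []
        n_singleton = n_unmapped = n_chimeric = 0
        copies = {r.read_id: r.copy_count for r in deduped}
        copy_counts = {"singleton": 0, "unmapped": 0, "chimeric": 0}
        mapped_ids = set(segments_by_read)
        for read in deduped:
            if read.read_id not in mapped_ids or not segments_by_read[read.read_id]:
                n_unmapped += 1
                copy_counts["unmapped"] += read.copy_count
        ref_seqs = _load_ref_seqs(config)
        for read_id, segs in sorted(segments_by_read.items()):
            if not segs:
                continue
            pair = ex.select_arms(segs, matrices, locus_to_crl, crl_tpm) \
                if matrices is not None else None
            if pair is None:
                n_singleton += 1
                copy_counts["singleton"] += copies.get(read_id, 1)
                continue
            n_chimeric += 1
            copy_counts["chimeric"] += copies.get(read_id, 1)
            arm1, arm2 = (ex.annotate(a, _models_cache(config)) for a in pair)
            rec = ex.InteractionRecord(read_id=read_id, arm1=arm1, arm2=arm2,
                                       score=arm1.posterior * arm2.posterior)
            if config.hybridize_tool and ref_seqs:
                s1 = _locus_sequence(arm1, ref_seqs)
                s2 = _locus_sequence(arm2, ref_seqs)
                if s1 and s2:
                    rec.hybrid_structure, rec.hybrid_energy = ex.hybridize(
                        s1, s2, config.hybridize_tool)
            records.append(rec)
        summary_counts = ex.filter_and_write(
            records, out_dir / "interactions.tsv",
            score_threshold=config.score_min,
            require_hybrid=config.require_hybrid,
            n_singletons=n_singleton, n_unmapped=n_unmapped)

    summary = {
        "reads": {
            "raw_copies": report.input_reads,
            "too_short_copies": report.discarded_short,
            "deduplicated": report.output_reads,
            "unmapped": n_unmapped,
            "singleton": n_singleton,
            "chimeric": n_chimeric,
            "copies": copy_counts,
        },
        "loci": len(loci),
        "crls": len(crls),
        "interactions": summary_counts,
        "em": {"iterations": abundances.n_iterations,
               "converged": abundances.converged} if abundances else None,
        "timings_s": timings,
    }
    with open(out_dir / "summary.json", "w") as out:
        json.dump(summary, out, indent=2)
    return PipelineResult(records=records, loci=loci, crls=crls,
                          abundances=abundances, matrices=matrices,
                          segments_by_read=segments_by_read, summary=summary)


def _map_reads(config: RunConfig, deduped: Sequence[ReadRecord],
               out_dir: Path) -> List[AlignmentSegment]:
    if config.sam:
        segments = []
        for i, sam_path in enumerate(config.sam):
            pass_id = 1 if i % 2 == 0 else 2
            db = 1 if i < 2 or len(config.sam) <= 2 else 2
            segments.extend(parse_sam(sam_path, expand_xa=True,
                                      max_alternatives=config.max_alternatives,
                                      pass_id=pass_id, ref_db=db))
        return segments
    if config.ref1 is None:
        raise ValueError("either --sam files or reference FASTAs are required")
    dbs = [read_fasta_dict(config.ref1)]
    if config.ref2:
        dbs.append(read_fasta_dict(config.ref2))
    return sim.exact_map(deduped, dbs, min_match=config.min_length)


_MODEL_CACHE: dict = {}


def _models_cache(config: RunConfig):
    if not config.gtf:
        return None
    key = str(config.gtf)
    if key not in _MODEL_CACHE:
        _MODEL_CACHE[key] = parse_gtf(config.gtf)
    return _MODEL_CACHE[key]


def _load_ref_seqs(config: RunConfig) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    for path in (config.ref1, config.ref2):
        if path:
            seqs.update(read_fasta_dict(path))
    return seqs


def _locus_sequence(arm: ex.Arm, ref_seqs: Dict[str, str]) -> str:
    """Merged locus sequence (the mapped arm with its locus context)."""
    seq = ref_seqs.get(arm.ref_id, "")
    if not seq or not arm.locus_id:
        return seq[arm.ref_start:arm.ref_end] if seq else ""
    try:
        coords = arm.locus_id.rsplit("(", 1)[0].rsplit(":", 1)[1]
        start, end = (int(x) for x in coords.split("-"))
        return seq[start:end]
    except (IndexError, ValueError):
        return seq[arm.ref_start:arm.ref_end]


# ---------------------------------------------------------------------------
# benchmark round trip
# ---------------------------------------------------------------------------

def run_benchmark(seed: int = 0, n_reads: int = 1000, arm_length: int = 20,
                  n_families: int = 20, family_size: int = 3,
                  divergence: float = 0.0, insert: bool = False,
                  n_extra_singletons: int = 0,
                  expressed_copy: int = 0,
                  out_dir: Optional[str] = None,
                  ) -> Dict[str, object]:
    """Simulate, map, run the full pipeline, and categorize both modes.

    Chimeric arms are drawn from one "expressed" copy per paralog family;
    the naive longest-hit baseline and the CRL+EM pipeline are evaluated
    on identical alignments.  Returns the truth, per-mode category
    counts, and the pipeline result.
    """
    ref = sim.make_reference(n_families=n_families, family_size=family_size,
                             divergence=divergence, seed=seed)
    expressed_mirnas = [r for r, f in ref.families.items()
                        if r.startswith("mir") and r.endswith(f"_c{expressed_copy}")]
    expressed_targets = [r for r, f in ref.families.items()
                         if r.startswith("tgt") and r.endswith(f"_c{expressed_copy}")]
    reads, truth = sim.make_chimeric_reads(
        ref, n_reads=n_reads, arm_length=arm_length, insert=insert,
        seed=seed + 1, mirna_ids=expressed_mirnas, target_ids=expressed_targets)
    all_reads = list(reads)
    if n_extra_singletons:
        all_reads += sim.make_singleton_reads(
            ref, expressed_mirnas + expressed_targets, n_extra_singletons,
            seed=seed + 2, unique_only=True)

    config = RunConfig(out_dir=out_dir or "scratch/benchmark", seed=seed)
    deduped, _ = deduplicate(all_reads, min_length=config.min_length)
    alignments = sim.exact_map(deduped, [ref.mirnas, ref.targets],
                               min_match=config.min_length)
    result = run(config, reads=all_reads, alignments=alignments)

    seq_to_reads: Dict[str, List[str]] = {}
    for read in reads:
        seq_to_reads.setdefault(read.sequence, []).append(read.read_id)
    collapsed_seq = {r.read_id: r.sequence for r in deduped}

    naive = _expand(sim.naive_predictions(postprocess(alignments)),
                    collapsed_seq, seq_to_reads)
    rescued = _expand(sim.pipeline_predictions(result.records),
                    collapsed_seq, seq_to_reads)
    naive = {r: p for r, p in naive.items() if r in truth.reads}
    rescued = {r: p for r, p in rescued.items() if r in truth.reads}
    counts_naive = sim.categorize(naive, truth, agree_overlap=config.agree_overlap)
    counts_rescued = sim.categorize(rescued, truth, agree_overlap=config.agree_overlap)
    return {"truth": truth, "reference": ref, "result": result,
            "naive": counts_naive, "crl_em": counts_rescued,
            "alignments": alignments}


def _expand(predictions: Dict[str, tuple], collapsed_seq: Dict[str, str],
            seq_to_reads: Dict[str, List[str]]) -> Dict[str, tuple]:
    """Deduplication collapses identical simulated reads; spread each
    collapsed prediction back over every original read with that
    sequence."""
    out: Dict[str, tuple] = {}
    for rid, arms in predictions.items():
        seq = collapsed_seq.get(rid)
        originals = seq_to_reads.get(seq, []) if seq is not None else []
        if not originals:
            originals = [rid.rsplit("|", 1)[0]]
        for orig in originals:
            out[orig] = arms
    return out
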