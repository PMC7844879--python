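"""Arm selection, annotation, the hybridizer hook, and the final table."""

import shutil

import numpy as np
import pytest

from chimloci.crl import CommonReadLocus
from chimloci.extract import (Arm, InteractionRecord, annotate,
                              filter_and_write, hybridize, select_arms)
from chimloci.io_formats import AlignmentSegment
from chimloci.loci import ReadSegment
from chimloci.quant import MappingMatrices, build_y, em_quantify


def make_segment(read_id, index, rs, re, locus):
    seg = ReadSegment(read_id=read_id, segment_index=index,
                      read_start=rs, read_end=re)
    seg.candidates = {locus}
    aln = AlignmentSegment(read_id=read_id, read_start=rs, read_end=re,
                           ref_id=locus.split(":")[0], ref_start=0,
                           ref_end=re - rs, strand="+", cigar=f"{re - rs}M",
                           score=re - rs)
    aln.locus_id = locus
    seg.alignments = [aln]
    return seg


def quantify(segments, crls):
    m = build_y(segments, crls)
    _, m = em_quantify(m)
    return m


class TestSelectArms:
    def test_two_segments_are_the_only_pair(self):
        crls = [CommonReadLocus("c1", ["tx1:0-20(+)"], set()),
                CommonReadLocus("c2", ["tx2:0-20(+)"], set())]
        segs = [make_segment("r", 0, 0, 20, "tx1:0-20(+)"),
                make_segment("r", 1, 20, 40, "tx2:0-20(+)")]
        m = quantify(segs, crls)
        locus_to_crl = {"tx1:0-20(+)": "c1", "tx2:0-20(+)": "c2"}
        arm1, arm2 = select_arms(segs, m, locus_to_crl)
        assert arm1.read_start == 0 and arm2.read_start == 20
        assert arm1.crl_id == "c1" and arm2.crl_id == "c2"

    def test_three_segments_best_posterior_pair_wins(self):
        # r has three non-overlapping segments; segment 2 is ambiguous
        # between c1 and c3 (posterior 2/3 at best), so the pair of the
        # two posterior-1 segments must be selected
        crls = [CommonReadLocus("c1", ["tx1:0-20(+)"], set()),
                CommonReadLocus("c2", ["tx2:0-20(+)"], set()),
                CommonReadLocus("c3", ["tx3:0-20(+)"], set())]
        segs = [make_segment("r", 0, 0, 15, "tx1:0-20(+)"),
                make_segment("r", 1, 15, 30, "tx2:0-20(+)"),
                make_segment("r", 2, 30, 45, "tx3:0-20(+)")]
        segs[2].candidates = {"tx1:0-20(+)", "tx3:0-20(+)"}
        extra = AlignmentSegment(read_id="r", read_start=30, read_end=45,
                                 ref_id="tx1", ref_start=0, ref_end=15,
                                 strand="+", cigar="15M", score=15)
        extra.locus_id = "tx1:0-20(+)"
        segs[2].alignments.append(extra)
        # extra reads unique to c3 keep its abundance (hence s2's split) honest
        others = [make_segment("q1", 0, 0, 15, "tx3:0-20(+)"),
                  make_segment("q2", 0, 0, 15, "tx3:0-20(+)")]
        m = quantify(segs + others, crls)
        locus_to_crl = {"tx1:0-20(+)": "c1", "tx2:0-20(+)": "c2",
                        "tx3:0-20(+)": "c3"}
        post2 = m.posterior_of("r|2")
        assert max(post2.values()) < 1.0
        arm1, arm2 = select_arms(segs, m, locus_to_crl)
        chosen = {(arm1.read_start, arm1.read_end), (arm2.read_start, arm2.read_end)}
        assert chosen == {(0, 15), (15, 30)}  # the two posterior-1 segments

    def test_singleton_returns_none(self):
        crls = [CommonReadLocus("c1", ["tx1:0-20(+)"], set())]
        segs = [make_segment("r", 0, 0, 20, "tx1:0-20(+)")]
        m = quantify(segs, crls)
        assert select_arms(segs, m, {"tx1:0-20(+)": "c1"}) is None


class TestAnnotate:
    def arm_at(self, start, end, ref="t1"):
        return Arm(read_start=0, read_end=end - start, ref_id=ref,
                   ref_start=start, ref_end=end, strand="+",
                   cigar=f"{end - start}M", locus_id="", crl_id="c",
                   posterior=1.0)

    def test_midpoint_left_of_cds_is_5utr(self, plus_model):
        # transcript CDS spans t-coords [50, 150) on the fixture model
        arm = annotate(self.arm_at(0, 40), {"t1": plus_model})
        assert arm.region == "5'UTR"
        assert arm.gene_symbol == "GENE1"

    def test_midpoint_in_cds(self, plus_model):
        assert annotate(self.arm_at(60, 100), {"t1": plus_model}).region == "CDS"

    def test_midpoint_right_of_cds_is_3utr(self, plus_model):
        assert annotate(self.arm_at(160, 200), {"t1": plus_model}).region == "3'UTR"

    def test_mirna_is_noncoding(self, minus_model):
        arm = annotate(self.arm_at(0, 20, ref="t2"), {"t2": minus_model})
        assert arm.region == "noncoding"
        assert arm.biotype == "miRNA"

    def test_unknown_transcript_is_unannotated(self, plus_model):
        assert annotate(self.arm_at(0, 20, ref="nope"),
                        {"t1": plus_model}).region == "unannotated"

    def test_no_annotation_at_all(self):
        assert annotate(self.arm_at(0, 20), None).region == "unannotated"


class TestHybridize:
    def test_reverse_complementary_sequences_form_duplex(self):
        assert shutil.which("RNAduplex"), "ViennaRNA ships with the environment"
        seq = "GGGGAAAACCCCUUUUGGGG"
        rc = seq[::-1].translate(str.maketrans("ACGU", "UGCA"))
        structure, energy = hybridize(seq, rc, tool="RNAduplex")
        assert structure != "NA" and "&" in structure
        assert float(energy) < 0

    def test_missing_tool_degrades_to_na(self):
        assert hybridize("ACGU", "ACGU", tool="no-such-hybridizer") == ("NA", "NA")

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            hybridize("", "ACGU")


class TestFilterAndWrite:
    def record(self, read_id, score):
        arm = Arm(read_start=0, read_end=20, ref_id="tx1", ref_start=0,
                  ref_end=20, strand="+", cigar="20M", locus_id="l",
                  crl_id="c", posterior=score ** 0.5)
        return InteractionRecord(read_id=read_id, arm1=arm, arm2=arm, score=score)

    def test_threshold_filters(self, tmp_path):
        records = [self.record("a", 0.72), self.record("b", 0.4)]
        summary = filter_and_write(records, tmp_path / "i.tsv",
                                   score_threshold=0.5)
        assert summary["reported_interactions"] == 1
        lines = (tmp_path / "i.tsv").read_text().splitlines()
        assert len(lines) == 2 and lines[1].startswith("a\t")

    def test_zero_threshold_keeps_all(self, tmp_path):
        records = [self.record("a", 0.72), self.record("b", 0.4)]
        summary = filter_and_write(records, tmp_path / "i.tsv")
        assert summary["reported_interactions"] == 2

    def test_monotone_in_threshold(self, tmp_path):
        rng = np.random.default_rng(0)
        records = [self.record(f"r{i}", float(s))
                   for i, s in enumerate(rng.uniform(0.01, 1, 30))]
        counts = [filter_and_write(records, tmp_path / "i.tsv",
                                   score_threshold=t)["reported_interactions"]
                  for t in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_require_hybrid_without_tool_drops_all(self, tmp_path):
        records = [self.record("a", 0.9)]
        summary = filter_and_write(records, tmp_path / "i.tsv",
                                   require_hybrid=True)
        assert summary["reported_interactions"] == 0
        header = (tmp_path / "i.tsv").read_text().splitlines()
        assert len(header) == 1  # header-only file

    def test_score_recomputable_from_table(self, tmp_path):
        records = [self.record("a", 0.49)]
        filter_and_write(records, tmp_path / "i.tsv")
        row = (tmp_path / "i.tsv").read_text().splitlines()[1].split("\t")
        p1, p2, score = float(row[14]), float(row[29]), float(row[31])
        assert score == pytest.approx(p1 * p2, rel=1e-4)
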