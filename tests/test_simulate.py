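"""Benchmark simulator, toy mapper, and the 7-category evaluator."""

import numpy as np
import pytest

from chimloci.io_formats import ReadRecord
from chimloci.pipeline import run_benchmark
from chimloci.simulate import (ArmPrediction, BenchmarkTruth, CATEGORIES,
                               ReadTruth, TrueArm, categorize, exact_map,
                               make_chimeric_reads, make_reference,
                               make_singleton_reads, naive_predictions)


class TestMakeReference:
    def test_zero_divergence_gives_identical_family_members(self):
        ref = make_reference(n_families=3, family_size=3, divergence=0.0, seed=1)
        for fam in {f for f in ref.families.values() if f.startswith("tgt")}:
            seqs = {ref.targets[r] for r, f in ref.families.items() if f == fam}
            assert len(seqs) == 1

    def test_family_size_one_has_no_paralogy(self):
        ref = make_reference(n_families=5, family_size=1, seed=2)
        assert len(set(ref.mirnas.values())) == len(ref.mirnas)
        assert len(set(ref.targets.values())) == len(ref.targets)

    def test_fixed_seed_is_deterministic(self, tmp_path):
        from chimloci.simulate import write_reference_fasta
        for i in (1, 2):
            ref = make_reference(n_families=4, family_size=2, divergence=0.05,
                                 seed=99)
            write_reference_fasta(ref, tmp_path / f"m{i}.fa", tmp_path / f"t{i}.fa")
        assert (tmp_path / "m1.fa").read_bytes() == (tmp_path / "m2.fa").read_bytes()
        assert (tmp_path / "t1.fa").read_bytes() == (tmp_path / "t2.fa").read_bytes()

    def test_divergence_out_of_range(self):
        with pytest.raises(ValueError):
            make_reference(divergence=1.5)

    def test_length_ranges_respected(self):
        ref = make_reference(n_families=10, seed=3)
        assert all(18 <= len(s) <= 25 for s in ref.mirnas.values())
        assert all(50 <= len(s) <= 400 for s in ref.targets.values())


class TestMakeChimericReads:
    def test_read_is_fusion_of_two_arms(self):
        ref = make_reference(n_families=5, seed=4)
        reads, truth = make_chimeric_reads(ref, n_reads=50, arm_length=20, seed=5)
        for read in reads:
            t = truth.reads[read.read_id]
            arm1 = ref.mirnas[t.arm1.ref_id][t.arm1.ref_start:t.arm1.ref_end]
            arm2 = ref.targets[t.arm2.ref_id][t.arm2.ref_start:t.arm2.ref_end]
            assert read.sequence == arm1 + arm2

    def test_no_insert_read_length(self):
        ref = make_reference(n_families=5, mirna_len_range=(25, 30), seed=6)
        reads, _ = make_chimeric_reads(ref, n_reads=20, arm_length=20, seed=7)
        assert all(len(r.sequence) == 40 for r in reads)

    def test_insert_adds_five_nucleotides(self):
        ref = make_reference(n_families=5, mirna_len_range=(25, 30), seed=8)
        reads, truth = make_chimeric_reads(ref, n_reads=20, arm_length=20,
                                           insert=True, seed=9)
        assert all(len(r.sequence) == 45 for r in reads)
        assert all(t.has_insert for t in truth.reads.values())

    def test_short_reference_uses_whole_sequence(self):
        ref = make_reference(n_families=5, mirna_len_range=(18, 18), seed=10)
        _, truth = make_chimeric_reads(ref, n_reads=20, arm_length=20, seed=11)
        for t in truth.reads.values():
            assert t.arm1.ref_end - t.arm1.ref_start == 18

    def test_zero_reads_is_error(self):
        ref = make_reference(n_families=2, seed=0)
        with pytest.raises(ValueError):
            make_chimeric_reads(ref, n_reads=0)

    def test_truth_round_trips_through_tsv(self, tmp_path):
        ref = make_reference(n_families=3, seed=12)
        _, truth = make_chimeric_reads(ref, n_reads=10, seed=13)
        truth.write_tsv(tmp_path / "truth.tsv")
        back = BenchmarkTruth.read_tsv(tmp_path / "truth.tsv")
        assert back == truth


class TestExactMap:
    def test_finds_both_arms_with_all_occurrences(self):
        dbs = [{"m1": "AAACCCGGGTTTACGTACGT"},
               {"t1": "TTTGGGCCCAAATGCATGCA", "t2": "TTTGGGCCCAAATGCATGCA"}]
        read = ReadRecord(read_id="r", sequence="AAACCCGGGTTT" + "TTTGGGCCCAAA")
        segments = exact_map([read], dbs, min_match=10)
        by_ref = {s.ref_id for s in segments}
        assert by_ref == {"m1", "t1", "t2"}
        arm2_hits = [s for s in segments if s.ref_id in ("t1", "t2")]
        assert all(s.read_start == 12 for s in arm2_hits)

    def test_short_spurious_matches_ignored(self):
        dbs = [{"m1": "ACGTACGTACGTACGTACGT"}]
        read = ReadRecord(read_id="r", sequence="TTTTTTTTTTTTTTTTTTTT")
        assert exact_map([read], dbs, min_match=10) == []


class TestCategorize:
    def truth_one(self):
        truth = BenchmarkTruth()
        truth.reads["r"] = ReadTruth(read_id="r",
                                     arm1=TrueArm("m1", 0, 20),
                                     arm2=TrueArm("t1", 10, 30),
                                     arm_length=20, has_insert=False)
        return truth

    def arm(self, ref="m1", start=0, end=20, unique=True, mapped=True):
        return ArmPrediction(alignments=[(ref, start, end)] if mapped else [],
                             unique=unique)

    @pytest.mark.parametrize("arm1_kw,arm2_kw,expected", [
        (dict(), dict(ref="t1", start=10, end=30), "perfect"),
        (dict(unique=False), dict(ref="t1", start=10, end=30), "partial_multi"),
        (dict(unique=False), dict(ref="t1", start=10, end=30, unique=False),
         "both_multi"),
        (dict(), dict(ref="t9", start=10, end=30), "partial_wrong"),
        (dict(ref="m9"), dict(ref="t9", start=10, end=30), "both_wrong"),
        (dict(), dict(mapped=False), "partial_miss"),
        (dict(mapped=False), dict(mapped=False), "both_miss"),
    ])
    def test_each_category_reachable(self, arm1_kw, arm2_kw, expected):
        counts = categorize({"r": (self.arm(**arm1_kw), self.arm(**arm2_kw))},
                            self.truth_one())
        assert counts.counts[expected] == 1
        assert counts.total() == 1

    def test_75_percent_overlap_is_not_agreed(self):
        # alignment covers 15/20 = 0.75 of the true arm: below 0.8
        pred = (self.arm(start=5, end=20), self.arm(ref="t1", start=10, end=30))
        counts = categorize({"r": pred}, self.truth_one())
        assert counts.counts["partial_wrong"] == 1

    def test_80_percent_overlap_is_agreed(self):
        pred = (self.arm(start=4, end=20), self.arm(ref="t1", start=10, end=30))
        counts = categorize({"r": pred}, self.truth_one())
        assert counts.counts["perfect"] == 1

    def test_absent_read_counts_as_both_miss(self):
        counts = categorize({}, self.truth_one())
        assert counts.counts["both_miss"] == 1

    def test_unknown_predicted_read_is_error(self):
        with pytest.raises(ValueError):
            categorize({"ghost": (self.arm(), self.arm())}, self.truth_one())

    def test_counts_partition_random_read_sets(self):
        rng = np.random.default_rng(0)
        truth = BenchmarkTruth()
        predictions = {}
        for i in range(100):
            rid = f"r{i}"
            truth.reads[rid] = ReadTruth(read_id=rid,
                                         arm1=TrueArm("m1", 0, 20),
                                         arm2=TrueArm("t1", 0, 20),
                                         arm_length=20, has_insert=False)
            if rng.random() < 0.8:
                predictions[rid] = (
                    self.arm(ref=rng.choice(["m1", "m2"]),
                             unique=bool(rng.random() < 0.5),
                             mapped=bool(rng.random() < 0.9)),
                    self.arm(ref=rng.choice(["t1", "t2"]),
                             unique=bool(rng.random() < 0.5),
                             mapped=bool(rng.random() < 0.9)))
        counts = categorize(predictions, truth)
        assert counts.total() == 100
        assert set(counts.counts) == set(CATEGORIES)


class TestBenchmarkProperties:
    def test_sanity_ceiling_without_paralogy(self, tmp_path):
        """Unique references and 15-nt arms: essentially every read should
        land in the perfect category."""
        res = run_benchmark(seed=21, n_reads=300, arm_length=15,
                            n_families=15, family_size=1,
                            out_dir=str(tmp_path / "ceiling"))
        assert res["crl_em"].fraction("perfect") >= 0.95

    def test_em_rescue_beats_naive_on_near_identical_families(self, tmp_path):
        """3-copy near-identical families with one expressed copy backed by
        unique reads: CRL+EM recovers strictly more perfect reads than the
        longest-hit baseline on the same alignments."""
        res = run_benchmark(seed=22, n_reads=400, arm_length=18,
                            n_families=12, family_size=3, divergence=0.03,
                            n_extra_singletons=200,
                            out_dir=str(tmp_path / "rescue"))
        assert res["crl_em"].counts["perfect"] > res["naive"].counts["perfect"]
        assert res["crl_em"].fraction("perfect") > 0.6
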