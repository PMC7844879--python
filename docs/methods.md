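# Methods

This note documents the model and procedure implemented in `chimloci`,
its assumptions, the parameters that matter, the design choices made
where the design was genuinely open, and what the synthetic benchmark
does and does not show.

## Problem setting

Interactome protocols (CLASH, CLEAR-CLIP, PARIS, SPLASH, LIGR-Seq)
produce chimeric reads: ligation products whose two arms come from two
interacting RNA fragments (or two parts of one folded molecule).  Arms
are 10–20 nt, far below the length at which alignment to a transcriptome
is unambiguous, and the worst ambiguity is systematic: mature miRNA
family members and paralogous target regions are near-identical, so the
true origin of an arm is often unidentifiable at the transcript level
even in principle.  The pipeline's central idea is to *change the
resolution of the question*: group near-identical reference regions into
clusters (common read loci) discovered from the multi-mapping structure
itself, and assign reads probabilistically at that resolution.

## Pipeline model and assumptions

**Deduplication.**  Identical (sequence, UMI) pairs are PCR duplicates
and collapse into one record with a copy count; identical sequences with
different UMIs are independent fragments.  Matching is exact — no UMI
error correction — and reads shorter than `min_length` (default 10 nt)
are discarded first.  Collapsed output is canonically ordered (sequence,
UMI), so deduplication is idempotent and independent of input order; the
representative keeps the lexicographically smallest member id suffixed
with `|N` (N = multiplicity).  Downstream quantification counts each
deduplicated record once: multiplicity is bookkeeping, not evidence,
since duplicates are presumed artifactual.

**Alignment post-processing.**  Alignment itself is delegated (2-pass
BWA-MEM contract: pass 1 long/gapped/high threshold, pass 2
short/ungapped via prohibitive gap penalties, with up to
`max_alternatives` (100) XA hits), or bypassed with pre-made SAM, or
performed by the built-in exact mapper.  Post-processing: (i) antisense
hits are dropped — references are transcript sequences, so only sense
hits are biologically meaningful; (ii) within a primary+XA group only
hits with the maximal aligned read length ("read coverage",
read_end − read_start) survive; (iii) pass-2 hits identical to a pass-1
hit are removed.  The coverage rule is applied per record group, not per
read, because a chimeric read legitimately carries two records of
different lengths.

**Expressed loci.**  Alignments on one reference (or, after GTF-based
lifting, one chromosome strand) merge into loci when alignment and locus
reciprocally overlap **strictly more than** 70 % of each one's length;
read-interval merging into segments uses **at least** 70 %.  The
asymmetry (strict vs inclusive) is kept deliberately as specified.
Merging sweeps start-sorted alignments against the growing locus extent
(deterministic, O(n log n)); because a growing extent can become
mergeable with a later locus, a fixed-point pass afterwards merges locus
pairs until no pair satisfies the rule — the published invariant
("loci are pairwise non-mergeable") holds of the output.  Spliced loci
use total block length in all overlap fractions.  Sorting ties break on
(start, end, read id).

**Read segments.**  Per read, alignment intervals overlapping ≥ 70 % of
each interval's length are unioned (single linkage, iterated to a fixed
point): repetitive references shift multi-mapped hits by a few bases,
and counting those as separate segments would dilute their weight in
quantification.  A read with ≥ 2 disjoint segments is chimeric; > 2
segments are allowed and resolved at extraction.  Locus merging runs per
reference first; candidate loci are attached to segments afterwards, so
a segment's candidate set spans references.

**Common read loci.**  Loci are processed in *decreasing* read-set size
(large, well-supported loci found clusters — the direction is a design
choice; the clustering itself is single linkage on the Jaccard index of
read-segment sets).  A locus joins the existing CRL with the highest
J against the CRL's running union read set when J > `crl_share`
(default 0.7); ties prefer the larger CRL, then the smaller id; otherwise
the locus founds its own CRL.  The result is a partition of the loci.

**Quantification.**  With y_{s,c} = 1 iff segment s maps to (any locus
of) CRL c, the observed-data likelihood is 𝓛(ρ) = ∏ₛ Σ_c y_{s,c} ρ_c.
A segment that multi-maps only within one CRL has a single-entry row —
the whole point of the CRL construction.  Chimeric reads contribute one
row per segment; singletons one row.  EM starts from the uniform
ρ = 1/K (unbiased; the log-likelihood is concave — a sum of logs of
affine functions — so the start point affects only the path, not the
optimum), and stops when Σ_c |ρ_c^{(t+1)} − ρ_c^{(t)}| ≤ ε (default
1e−5), with a `max_iter` safeguard of 1000 that reports
non-convergence rather than failing.  Convergence to the simplex
boundary is allowed; no pseudocounts are added.  TPM is ρ·10⁶: CRLs are
short captured interaction sites of comparable length, so length
normalization is omitted and relative abundance scales directly.

**Extraction.**  Each segment's CRL is the argmax of its posterior row;
among pairs of read-disjoint segments, the pair maximizing the posterior
product wins, and the interaction score is that product,
Pr[(s,s′) ∈ c↔c′] = Pr(z_{s,c}=1)·Pr(z_{s′,c′}=1) — posteriors, not
abundances, so scores for one read sum to 1 over all CRL pairs.  The
reported alignment for an arm is the highest-scoring hit among the
segment's candidates inside the chosen CRL (ties break on coordinates).
The score threshold applied when writing the table defaults to 0 (report
everything); 0.5 is a reasonable analysis choice when only confidently
assigned interactions are wanted.  Region annotation classifies a
protein-coding arm by its midpoint relative to the CDS in transcript
coordinates (5′UTR/CDS/3′UTR, strand-aware); the midpoint rule is a
design choice for arms straddling a boundary.  Protein-coding
transcripts without CDS records and transcripts absent from the
annotation are reported as `unannotated`.  Hybridization runs on the
merged *locus* sequences (they carry context around the mapped arms, and
the true pairing site is often adjacent to the sequenced fragment)
through an external tool; a missing or failing tool yields `NA` and the
record is kept.

## Synthetic benchmark

`make_reference` builds a split reference: short miRNA-like sequences
(18–25 nt) and longer target-like sequences (50–400 nt, emulating target
sites extended with flanking context), organized in families of
`family_size` copies mutated at per-base rate `divergence`.
Divergence 0 gives identical family members (recently duplicated
paralogs, the hardest case); founders duplicated across families are
regenerated.  `make_chimeric_reads` fuses an `arm_length`-nt substring
of a random miRNA-like reference to one of a target-like reference
(whole sequence when shorter), optionally inserting a random 5-mer
between the arms or at either end (uniform choice).  Arm lengths follow
the benchmark grid {10, 12, 15, 18, 20}.  The built-in mapper finds, per
read offset, the longest substring with an exact occurrence anywhere in
the references (binary search over length) and reports *all* its
occurrences; matches under 10 nt are ignored so inserts do not spawn
arms.

The evaluator scores each read's two arms against the ground truth: an
arm is *agreed* when an alignment covers ≥ 80 % of the true arm interval
on the true reference; arms are unique/multi by alignment multiplicity
(naive mode) or by whether the selected posterior row has a unique
argmax (pipeline mode, where an arm's alignment set is its candidates
within the chosen CRL).  The seven categories partition the read set.
The printed category definitions do not cover a multi-mapped agreed arm
paired with a wrongly mapped arm; precedence here is: any unmapped arm →
miss categories; both agreed → perfect/partial_multi/both_multi by
uniqueness; exactly one agreed → partial_wrong; none → both_wrong.

**What the benchmark does not emulate**: sequencing errors, quality
scores, adapter remnants, coverage biases, expression dispersion,
intramolecular (structure) chimeras, and genuine biological duplicates —
so passing it demonstrates correctness of the locus/CRL/EM machinery
under idealized mapping, not end-to-end accuracy on real libraries with
a real aligner.

## Numerical and scale choices

* Coordinates are 0-based half-open everywhere internally; GTF is
  converted on parse, BED written natively.  The transcript↔genome lift
  is exact and length-preserving (verified by round-trip on random
  intervals).
* All iteration orders are canonical (sorted), dict/set iteration never
  leaks into output, and the analysis path contains no randomness, so
  re-running a configuration is byte-identical (`summary.json` and
  `run.log` carry wall-clock timings and are the only exceptions).
* Test and acceptance runs use 10³-read simulations over ~20 families —
  large enough that category fractions are stable to a few percent,
  small enough to keep the whole suite in seconds; the EM grid-search
  cross-check enumerates *all* mapping matrices with ≤ 4 segments and
  ≤ 3 CRLs rather than sampling.
* Inside the EM oracle comparison the stop tolerance is tightened to
  1e−12 so the comparison measures the estimator, not the stop rule; the
  default ε = 1e−5 is verified separately.

## Known limitations

* The interaction-table column set is a documented, fixed superset of
  the fields the analysis produces; downstream consumers of other tools'
  column layouts need a mapping step.
* The exact mapper is exhaustive and exact-match only — adequate for
  benchmark round trips, not a replacement for a local aligner on real
  data (the BWA-MEM contract or `--sam` input covers that path).
* CRL grouping can over-merge genuinely distinct loci whose read sets
  coincide by chance at very high coverage; the reciprocal-overlap locus
  definition shares this high-coverage caveat.
* TPM omits length normalization; for CRLs of very heterogeneous length
  the reported abundances are read-fraction, not molarity, estimates.
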