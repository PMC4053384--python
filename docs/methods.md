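# Methods

## Problem setting and scoring model

Given references 1…r…N of sizes G_r (cumulative R = ΣG_r) and short reads of
length L, the aligner searches for the trajectory A(s,r) maximizing the
additive score SA(s,r) = Σ Pₗ over matches, mismatches and affine gaps.
Additive scoring is what dynamic programming optimizes; it cannot express,
say, a triple deletion being cheaper than three isolated deletions, which is
why affine gap costs (open −12, extend −2) are the default — they approximate
that preference while staying additive. Match +5 / mismatch −4 are chosen so
that the reporting thresholds (minimum match length 36, ≤15% mismatches) are
meaningful: the weakest reportable alignment, 31 matches + 5 mismatches,
scores 135, which is the pruning target of the banded aligner. All scoring
values are configurable; setting gap open = extend gives linear gaps.

## Pipeline stages

**Read filtering.** Reads with more than 10% ambiguity codes are dropped and
reported unaligned. Isolated Ns survive: they block seed indexing at
overlapping k-mer positions and score as mismatches during extension and
alignment. An optional low-complexity read filter (2-mer Shannon entropy) is
off by default.

**Non-redundification and sorting.** Reads are partitioned into 4^k prefix
classes (k=2 by default; each class keyed by the 2-bit code of the first k
bases, short reads padded with A for routing only) and each class is digested
into a compressed radix tree. Duplicate detection is exact string equality;
duplicates increment a counter. Left-first traversal of each tree, classes
concatenated in code order, yields the globally sorted unique reads without
any merge step — prefix classes cannot interleave. Cross-similarity
coefficients c_i (LCP with the previous sorted read) are computed on the
concatenated order. Worst cases: fully identical input degenerates to one
counter (cheap storage, per-read full comparison), fully diverse input
stores everything but compares little.

**K-mer index.** Each reference position (every p-th, p=1 by default)
contributes its k-mer, k ≤ 14, to a bucket keyed by the k-mer's 2-bit code
(first base most significant, so code order = lexicographic order and sorted
reads touch monotone index regions). A 4^k-bit presence vector is set for
every non-empty bucket *before* masking, so a zero bit proves emptiness (no
false negatives; this degenerate single-hash bloom is exact by construction,
deliberately not a multi-hash bloom). Buckets with occupancy above the
overexpression threshold T (default 50) are flagged and contribute no
candidates; on random references the expected occupancy is R/4^k ≪ T, so
masking fires essentially only on low-complexity repeats. Seeds longer than
14 use double lookups: two adjacent sub-seeds must occur at consecutive
reference positions on the same diagonal. Lookup deduplicates hits per
(reference, diagonal) keeping the leftmost read offset, and caps candidates
per read (default 200, best-first by supporting seed count); a read whose
every seed is masked is reported unaligned.

**Fuzzy extension.** Each verified seed hit is extended greedily left and
right with integer scores (match +1, mismatch −1, gap open −2, extend −1) in
a floating window of half-width 4 (max indel run per step). At a mismatch
the front ranks alternatives by look-ahead exact-run length minus cost and
requires at least a 2-base resync run before accepting a gap. Two distinct
rules govern termination and acceptance:

- *Stop rule*: extension halts when the trailing 32-step window reaches 50%
  errors, then trims back to the last match. Random flanks (75% expected
  mismatch) hit this within ~20 steps; a candidate that merely runs at the
  15% reporting allowance essentially never does. Tying the stop density to
  the 15% allowance itself would terminate legitimately noisy candidates
  early, because a read that is globally at 15% mismatches routinely exceeds
  15% inside some 32-base window — the stop rule is a junk detector, not the
  acceptance test.
- *Pass rule*: the extension passes when it covers ≥75% of the read and its
  edits (mismatches + gap bases) stay within 15% of the extended span, plus
  one edit of slack so the optimal stage, not the filter, makes borderline
  calls. If a gapped account fails, the plain ungapped diagonal is re-checked
  before rejection: the greedy front occasionally explains a substitution
  cluster with spurious compensating gaps, and a substitution-only candidate
  is exactly its diagonal. This re-check is strictly more permissive and
  closes the filter's false-negative channel; measured over 10^4 seeded
  substitution pairs meeting the final thresholds, zero pass-worthy
  candidates are filtered.

Failed extensions carry a margin (integer score shortfall) consumed by the
cross-similarity skip rule.

**Banded optimal alignment.** Survivors are aligned by a local
Smith-Waterman with affine gaps restricted, per read row, to a band of
half-width w (default 8) around a floating center; storage is one short
array per row (≤ (2w+1)×L cells, asserted), never L×G. The center has an
inertial track and a bounded steering term:

- the track linearly interpolates the diagonal between the two bracket ends
  — the fuzzy extension already traced any net indel drift, so the track
  passes near the true path even when cumulative drift exceeds w;
- the steering offset moves at most one column per row toward the
  best-scoring column within w/2 of the track, ignoring weaker cells than a
  4-match run. Both restrictions are deliberate: unrestricted row maxima are
  dominated for many rows by "ghost" cells (gap-continuations of a strong
  prefix) while the genuine path is stalled inside a gap, and an
  unconditioned global-best anchor lets early low-score noise drag the band.
  Differentially tested against full-matrix Smith-Waterman (an independent
  implementation) over thousands of substitution+indel pairs: zero score
  discrepancies whenever the optimum's indel excursion fits the band.

Cells are pruned ("holes") when an admissible upper bound — cell score plus
at most match×(remaining rows), discounted by the gap schedule for the
cell's distance from the center but never below the cell's own score, since
any cell can be a local end — cannot reach the reporting threshold 135.
Pruning is verified to never change a reported score or trajectory
(pruning-on vs pruning-off property tests); disabling it yields zero holes
and identical output. Traceback walks stored pointers over live cells only;
a pointer into a hole raises an internal-consistency error. A
Needleman-Wunsch-style mode that forces the whole read into the window is
available behind a flag (`mode="glocal"`).

A candidate whose extension covered the entire read with zero mismatches
and zero indels is reported directly as the exact-match alignment
(score L×match): under a positive match score no alignment can exceed it,
so the banded DP is provably redundant there. This fast path is what makes
error-free datasets cheap; it changes no result.

**Reporting.** First-best: among equal scores the earliest candidate in
(reference ordinal, diagonal) order wins, forward strand before reverse —
deterministic, byte-identical SAM across runs. Both strands are aligned by
default (the reverse complement is looked up and aligned independently;
reverse-strand records follow the SAM orientation convention) with a
forward-only switch. Unaligned reads are emitted with the unmapped flag;
duplicate reads are expanded back into individual records (or collapsed
with an `XC:i` count tag).

**Cross-similarity (optional, off by default).** Only extension-stage
failures of the immediately preceding sorted read are memoized (depth 1).
A hit at a memoized failed (reference, diagonal) is skipped iff the recorded
margin exceeds (L−c)·(match−mismatch)·margin_factor in extension-score
units — the maximum swing the non-shared suffix can produce, so with
margin_factor ≤ 1 a candidate that could have aligned is never skipped when
the prefix bound holds. margin_factor = ∞ restores byte-identical output to
the feature being off (tested). The option is conservative by design and
not recommended for references distant from the sample.

## Synthetic data

The simulator generates uniform i.i.d. references and reads cut at uniform
random offsets of a uniform random reference (optionally restricted to a
subset, for mixture experiments) and strand. Per-base errors are injected at
rate e with composition 90% substitutions, 5% insertions, 5% deletions
(configurable; the standard validation sets correspond to e = 0, 0.01 and
0.05). Reads are emitted at exactly L bases; when e > 0 a 16-base template
tail buffer absorbs deletions, so offsets span [0, G−L−16]. Every read
carries provenance (source, offset, strand, injected edit counts) in a truth
table; a template-oversampling mode emulates highly redundant datasets for
dedup testing. All randomness flows from one integer seed and identical
configurations give byte-identical FASTQ.

What the simulator does *not* model: platform quality profiles,
homopolymer-dependent errors, coverage bias, adapter contamination, and real
genomic repeat structure (uniform random references are nearly repeat-free
at these sizes). Passing tests therefore demonstrate algorithmic
correctness under the stated error model, not end-to-end performance on a
particular sequencing platform or on repeat-rich genomes.

## Problem sizes used in tests

The validation experiments run at desk scale, chosen so the full suite stays
fast while keeping each statistic meaningful: 10,000 reads × 12 kb reference
for the error-free mapping; 15 × 10 kb references for mixture separation;
a 1 Mb reference and 1,500 reads for the seed-length scaling ratio (the
R/4^k expectation; sampling error ≈1%, asserted within ±5%); 500 bracketed
pairs for floating-band/full-matrix equivalence; 10^5 reads for the dedup
oracle comparison; 1,500 1%-error reads for the cross-similarity
differential; 2,000 reads per error rate for the sensitivity trend.

## Known limitations

- The floating band guarantees the full-matrix optimum only when the true
  path stays within w of the bracket-interpolated diagonal; grossly
  misleading brackets (which the extension stage does not produce) can hide
  part of the path.
- The pruning bound's distance discount is heuristic for *through*-paths
  (it is exact for end cells); it is floored at the cell's own score, and
  equivalence with pruning disabled is property-tested rather than proven.
- Overexpression masking trades sensitivity in low-complexity regions for
  speed; entirely masked reads are reported unaligned with that reason.
- Tie-breaking is by candidate encounter order, which is deterministic but
  not biologically privileged; MAPQ is not estimated (255).
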