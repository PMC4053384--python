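# hexalign

A seed-and-extend short-read DNA aligner built around three ideas that
exploit the structure of high-coverage sequencing data:

1. **Read non-redundification.** High-coverage read sets are massively
   redundant. Reads are digested into a compressed prefix (radix) tree that
   collapses exact duplicates while counting them, and a left-first traversal
   emits the unique reads in lexicographic order together with
   *cross-similarity coefficients* (the longest-common-prefix length between
   consecutive sorted reads). Every unique read is aligned exactly once and
   the result is expanded by its redundancy count.
2. **Direct-indexed k-mer seeding behind a bloom bit-table.** References are
   compiled into a bucket table addressed by the 2-bit integer code of each
   k-mer (A=0, C=1, G=2, T=3; k ≤ 14, longer seeds via double lookups of two
   adjacent sub-seeds). A dense one-bit-per-k-mer presence vector is probed
   before any bucket fetch, so the frequent misses stay cheap. Overexpressed
   seeds (bucket occupancy above a threshold) are masked, not deleted.
3. **Floating variable-width diagonal Smith-Waterman.** Candidates surviving
   a cheap fuzzy bidirectional extension are aligned optimally inside a
   linearized band of half-width *w* whose center floats with the
   highest-scoring path, storing ~(2w+1)×L cells instead of L×G. Cells whose
   admissible score upper bound cannot reach the reporting threshold are
   pruned ("holes") and never computed into the traceback.

The scoring model is additive: an alignment trajectory
A(s,r) = (s₁r₁)…(sᵢrⱼ)… has score SA(s,r) = Σ Pₗ, where Pₗ is the match
benefit, mismatch cost, or affine gap cost of the l-th column (defaults
+5 / −4 / −12 open / −2 extend). An alignment is reported when it spans at
least 36 read bases with at most 15% mismatches, first-best on ties.

Cross-similarity can additionally be switched on: because consecutive sorted
reads share a prefix of length *c*, a candidate position where the previous
read's extension failed by more than the score swing the differing suffix
could recover, `(L−c)·(match−mismatch)·margin_factor`, is skipped outright.

## Worked example

Simulate an error-free read set from a 12 kb random reference and align it
back (the bundled simulator writes FASTA references, FASTQ reads, and a TSV
truth table, so no downloads are needed):

```
$ hexalign simulate --ref-len 12000 --reads 10000 --read-len 100 \
      --error 0 --seed 11 --out demo
wrote 1 references, 10000 reads -> demo.*

$ hexalign align --ref demo.refs.fa --reads demo.reads.fq --out demo.sam
total 10000  unique 8157  aligned 10000  unaligned 0  percent_unaligned 0.0000

$ hexalign dedup demo.reads.fq --out demo.unique.fa --counts demo.counts.tsv
10000 reads -> 8157 unique (counts sum 10000)
```

Only 8,157 of the 10,000 reads are unique (random 100-base windows of a
12 kb reference collide), so the aligner ran 8,157 alignments and expanded
the counts; every read aligns, hence `percent_unaligned 0.0000`. With 1% or
5% simulated error (`--error 0.01` / `--error 0.05`) the same command
exercises the fuzzy-extension filter and the banded optimal aligner instead
of the exact-match fast path, and the unaligned percentage grows
monotonically with the error rate.

`evaluate_against_truth(sam, truth_tsv)` scores any run against the
simulator's provenance: fraction unaligned, fraction on the correct source
reference, and fraction within ±5 bases of the true offset.

## Limitations

Single-end reads only; no BAM/CRAM output; no quality-aware scoring; the
4^k prefix partitioning provides the parallel decomposition but execution is
single-process. See `docs/methods.md` for the model, parameter meanings, and
numerical design choices.
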