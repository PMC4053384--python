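"""End-to-end alignment workflow.

Stages, in order: read filtering (ambiguity/low-complexity), prefix-tree
non-redundification with 4**k partitioning, reference k-mer index
compilation, per-unique-read candidate lookup (optionally pruned by the
previous read's cross-similarity memo), fuzzy extension filtering, banded
optimal alignment of the survivors, and finally redundancy-count expansion
into SAM plus a summary report.  Every unique read is aligned exactly once
no matter how many identical copies the input contains.
"""

from __future__ import annotations

import dataclasses
import math
import time
from dataclasses import dataclass
from typing import Optional, Sequence

import yaml

from .cross_similarity import CandidateMemo, filter_candidates
from .diagonal_aligner import Alignment, ScoringParams, Thresholds, band_align
from .fuzzy_extension import ExtensionParams, fuzzy_extend
from .kmer_index import build_index, lookup
from .nonredund_tree import build_unique_set
from .read_simulator import read_truth
from .sequence_io import ReadRecord, Reference, reverse_complement, write_sam

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "evaluate_against_truth"]


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; the defaults are the aligner's standard operating point.

    Seed length 14, minimum match length 36, 15% mismatches allowed, fuzzy
    extension requiring 75% of the read at a 15% mismatch allowance,
    first-best reporting.
    """

    k: int = 14
    min_match_len: int = 36
    mismatch_pct: float = 15.0
    ext_min_len_pct: float = 75.0
    ext_mismatch_pct: float = 15.0
    overexpression_threshold: int = 50
    seed_step: int = 1
    band_w: int = 8
    candidate_cap: int = 200
    cross_similarity: bool = False
    cs_margin: float = 1.0
    strand: str = "both"  # "both" or "forward"
    report: str = "first-best"
    partition_k: int = 2
    max_n_fraction: float = 0.10
    low_complexity_filter: bool = False
    lc_entropy_min: float = 1.0
    match: int = 5
    mismatch: int = -4
    gap_open: int = -12
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.strand not in ("both", "forward"):
            raise ValueError("strand mode must be 'both' or 'forward'")
        if self.report != "first-best":
            raise ValueError("only first-best reporting is implemented")

    def scoring(self) -> ScoringParams:
        return ScoringParams(self.match, self.mismatch, self.gap_open, self.gap_extend)

    def thresholds(self) -> Thresholds:
        return Thresholds(self.min_match_len, self.mismatch_pct)

    def extension(self) -> ExtensionParams:
        return ExtensionParams(self.ext_min_len_pct, self.ext_mismatch_pct)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    """Alignments in original read space plus the run summary."""

    alignments: list[Optional[Alignment]]
    summary: dict
    unique_alignments: list[Optional[Alignment]]


def _entropy2(seq: str) -> float:
    counts: dict[str, int] = {}
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        counts[pair] = counts.get(pair, 0) + 1
    n = len(seq) - 1
    return -sum((c / n) * math.log2(c / n) for c in counts.values()) if n > 0 else 0.0


def _align_unique(seq, index, references, config, params, thresholds, ext_params, memo_prev, c, counters):
    """Best alignment of one unique read; returns (alignment, extension memo)."""
    memo = CandidateMemo()
    best: Optional[Alignment] = None
    strands = ("+", "-") if config.strand == "both" else ("+",)
    double = config.k > 14
    all_masked = False
    for strand in strands:
        oriented = seq if strand == "+" else reverse_complement(seq)
        if len(oriented) < (2 * index.k if double else index.k):
            continue
        hits = lookup(index, oriented, double=double, max_candidates=config.candidate_cap)
        if strand == "+" and config.cross_similarity and memo_prev is not None:
            hits = filter_candidates(
                hits, memo_prev, min(c, len(oriented)), len(oriented),
                margin_factor=config.cs_margin,
            )
        for hit in hits:
            ref = references[hit.ref]
            ext = fuzzy_extend(oriented, ref.seq, hit, ext_params)
            counters["extensions"] += 1
            if strand == "+":
                memo.record(hit.ref, hit.diagonal, ext.passed, max(0, ext.margin))
            if not ext.passed:
                continue
            full_exact = (
                ext.read_start == 0
                and ext.read_end == len(oriented)
                and ext.mismatches == 0
                and ext.gap_bases == 0
            )
            if full_exact:
                # an exact full-length match is provably optimal under a
                # positive match score; skip the banded DP for this candidate
                aln = Alignment(
                    read_ordinal=0,
                    ref_ordinal=hit.ref,
                    strand=strand,
                    score=len(oriented) * params.match,
                    read_start=0,
                    read_end=len(oriented),
                    ref_start=ext.ref_start,
                    ref_end=ext.ref_end,
                    ops="=" * len(oriented),
                    read_len=len(oriented),
                )
                counters["exact_fast_path"] += 1
            else:
                counters["band_alignments"] += 1
                aln = band_align(
                    oriented,
                    ref.seq,
                    ext.bracket,
                    params,
                    w=config.band_w,
                    thresholds=thresholds,
                    ref_ordinal=hit.ref,
                    strand=strand,
                )
            if aln is not None and (best is None or aln.score > best.score):
                best = aln
    return best, memo


def run_pipeline(
    references: Sequence[Reference],
    reads: Sequence[ReadRecord],
    config: PipelineConfig = PipelineConfig(),
    sam_path=None,
) -> PipelineResult:
    """Align ``reads`` against ``references`` and report the summary.

    Alignment is computed once per unique read and expanded by redundancy
    count; the summary's ``percent_unaligned`` is over original (redundant)
    read counts.  Deterministic: fixed inputs and configuration yield
    byte-identical SAM output.
    """
    timings: dict[str, float] = {}
    counters = {"extensions": 0, "band_alignments": 0, "exact_fast_path": 0}
    t0 = time.perf_counter()

    # stage a: read filters
    kept_ordinals: list[int] = []
    dropped_n = dropped_lc = 0
    for i, read in enumerate(reads):
        seq = read.seq
        n_frac = seq.count("N") / len(seq)
        if n_frac > config.max_n_fraction:
            dropped_n += 1
            continue
        if config.low_complexity_filter and _entropy2(seq) < config.lc_entropy_min:
            dropped_lc += 1
            continue
        kept_ordinals.append(i)
    timings["filter"] = time.perf_counter() - t0

    # stage b: non-redundification + sorted order (4**k prefix partitions)
    t0 = time.perf_counter()
    kept_seqs = [reads[i].seq for i in kept_ordinals]
    unique = build_unique_set(kept_seqs, partition_k=config.partition_k)
    timings["dedup"] = time.perf_counter() - t0

    # stage c/d: reference k-mer hash + bloom compilation (rebuilt every run)
    t0 = time.perf_counter()
    index_k = (config.k + 1) // 2 if config.k > 14 else config.k
    index = build_index(
        references,
        k=index_k,
        threshold=config.overexpression_threshold,
        step=config.seed_step,
    )
    timings["index"] = time.perf_counter() - t0

    # stages e-g: lookup, fuzzy extension, optimal alignment per unique read
    t0 = time.perf_counter()
    params = config.scoring()
    thresholds = config.thresholds()
    ext_params = config.extension()
    unique_alignments: list[Optional[Alignment]] = []
    memo_prev: Optional[CandidateMemo] = None
    for u, seq in enumerate(unique.sequences):
        c = int(unique.cross_similarity[u])
        aln, memo = _align_unique(
            seq, index, references, config, params, thresholds, ext_params,
            memo_prev if u > 0 else None, c, counters,
        )
        if aln is not None:
            aln = dataclasses.replace(aln, read_ordinal=u)
        unique_alignments.append(aln)
        memo_prev = memo
    timings["align"] = time.perf_counter() - t0

    # redundancy-count expansion back to original read space
    alignments: list[Optional[Alignment]] = [None] * len(reads)
    for local_i, orig in enumerate(kept_ordinals):
        u = unique.unique_of_read.get(local_i)
        if u is None:
            continue
        aln = unique_alignments[u]
        if aln is not None:
            alignments[orig] = dataclasses.replace(aln, read_ordinal=orig)

    total = len(reads)
    aligned = sum(1 for a in alignments if a is not None)
    unaligned = total - aligned
    per_reference: dict[str, int] = {ref.id: 0 for ref in references}
    for a in alignments:
        if a is not None:
            per_reference[references[a.ref_ordinal].id] += 1

    summary = {
        "total_reads": total,
        "kept_reads": len(kept_ordinals),
        "dropped_high_n": dropped_n,
        "dropped_low_complexity": dropped_lc,
        "unique_reads": len(unique),
        "aligned_reads": aligned,
        "unaligned_reads": unaligned,
        "percent_unaligned": (100.0 * unaligned / total) if total else 0.0,
        "per_reference": per_reference,
        "counters": dict(counters),
        "timings_sec": {k: round(v, 4) for k, v in timings.items()},
        "config": dataclasses.asdict(config),
    }

    if sam_path is not None:
        write_sam(alignments, references, reads, sam_path)

    return PipelineResult(alignments, summary, unique_alignments)


def evaluate_against_truth(sam_path, truth_path, position_tolerance: int = 5) -> dict:
    """Score a SAM file against the simulator's truth table.

    Reports the fraction of reads left unaligned, the fraction of aligned
    reads placed on their source reference, and the fraction placed within
    ``position_tolerance`` bases of the true forward-strand offset.  Read ids
    present in the SAM but absent from the truth table are an error.
    """
    import pysam

    truth = read_truth(truth_path)
    total = aligned = correct_ref = correct_pos = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            total += 1
            t = truth.get(rec.query_name)
            if t is None:
                raise ValueError(f"read id {rec.query_name!r} not present in the truth table")
            if rec.is_unmapped:
                continue
            aligned += 1
            if rec.reference_name == t.ref_id:
                correct_ref += 1
                if abs(rec.reference_start - t.offset) <= position_tolerance:
                    correct_pos += 1
    return {
        "total_reads": total,
        "aligned_reads": aligned,
        "fraction_unaligned": (total - aligned) / total if total else 0.0,
        "fraction_correct_reference": correct_ref / aligned if aligned else 0.0,
        "fraction_correct_position": correct_pos / aligned if aligned else 0.0,
    }
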