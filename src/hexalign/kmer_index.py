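"""Direct-indexed k-mer seed dictionary with a bloom bit-table.

The reference set is compiled into a bucket table addressed by the 2-bit
integer code of each k-mer (k <= 14), each bucket holding the (reference
ordinal, position) pairs where that seed occurs.  A dense bit vector with one
presence bit per possible k-mer code — an exact, single-hash bloom table —
is consulted before any bucket fetch, so the frequent misses cost one bit
probe instead of a bucket access.  Buckets whose occupancy exceeds an
overexpression threshold are masked (flagged, not deleted) and contribute no
candidates; seed lengths above 14 are served by double lookups of two
adjacent sub-seeds that must agree on the alignment diagonal.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .sequence_io import Reference, kmer_codes

__all__ = ["SeedHit", "KmerIndex", "build_index", "lookup", "kmer_entropy"]

MAX_DIRECT_K = 14
_BIT = [1 << b for b in range(8)]


@dataclass(frozen=True)
class SeedHit:
    """One candidate placement: seed occurrence joined to a read offset.

    The implied alignment diagonal is ``ref_pos - read_offset``.
    """

    ref: int
    ref_pos: int
    read_offset: int
    length: int

    @property
    def diagonal(self) -> int:
        return self.ref_pos - self.read_offset


def kmer_entropy(kmer: str) -> float:
    """Shannon entropy (bits) of the 2-mer composition of a k-mer."""
    pairs = Counter(kmer[i : i + 2] for i in range(len(kmer) - 1))
    n = sum(pairs.values())
    return -sum((c / n) * math.log2(c / n) for c in pairs.values())


class KmerIndex:
    """Seed dictionary over a reference set.

    Attributes
    ----------
    k : seed length (<= 14)
    threshold : max bucket occupancy before the seed is masked as overexpressed
    step : index every ``step``-th reference position
    n_entries : total stored occurrences (masked buckets included)
    stats : lookup counters (bloom checks/hits, bucket fetches), resettable
    """

    def __init__(self, k: int, threshold: int, step: int):
        self.k = k
        self.threshold = threshold
        self.step = step
        self.buckets: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self.masked: set[int] = set()
        self.bloom = bytearray((4**k + 7) // 8)
        self.n_entries = 0
        self.n_references = 0
        self.stats = {"bloom_checks": 0, "bloom_hits": 0, "bucket_fetches": 0}

    def reset_stats(self) -> None:
        for key in self.stats:
            self.stats[key] = 0

    def bloom_bit(self, code: int) -> bool:
        return bool(self.bloom[code >> 3] & _BIT[code & 7])

    def bucket(self, code: int) -> list[tuple[int, int]]:
        """All stored occurrences of a k-mer code (masked or not)."""
        entry = self.buckets.get(code)
        if entry is None:
            return []
        refs, poss = entry
        return list(zip(refs.tolist(), poss.tolist()))

    def occupancy(self, code: int) -> int:
        entry = self.buckets.get(code)
        return 0 if entry is None else len(entry[0])

    def _fetch(self, code: int) -> Optional[tuple[np.ndarray, np.ndarray]]:
        """Bucket fetch as performed during lookup: masked buckets yield None."""
        self.stats["bucket_fetches"] += 1
        if code in self.masked:
            return None
        return self.buckets.get(code)


def build_index(
    references: Sequence[Reference],
    k: int = 14,
    threshold: int = 50,
    step: int = 1,
    mask_low_complexity: bool = False,
    lc_entropy_min: float = 1.0,
) -> KmerIndex:
    """Compile the reference set into a :class:`KmerIndex` in O(R).

    Positions 0, step, 2*step, ... of every reference are indexed (windows
    containing an ambiguous base are skipped).  Bloom bits are set for every
    non-empty bucket *before* masking, so a bloom miss always proves the
    bucket empty.  ``mask_low_complexity`` additionally masks seeds whose
    2-mer entropy falls below ``lc_entropy_min`` bits (an interpretation of
    reference low-complexity masking; off by default).
    """
    if k < 1:
        raise ValueError("seed length must be >= 1")
    if k > MAX_DIRECT_K:
        raise ValueError(
            f"seed length {k} exceeds the direct-index limit of {MAX_DIRECT_K}; "
            "use double-lookup mode (two adjacent sub-seeds of length <= 14)"
        )
    if threshold < 1:
        raise ValueError("overexpression threshold must be >= 1")
    if step < 1:
        raise ValueError("position step must be >= 1")

    index = KmerIndex(k, threshold, step)
    index.n_references = len(references)
    code_parts, ref_parts, pos_parts = [], [], []
    for r, ref in enumerate(references):
        codes = kmer_codes(ref.seq, k)
        if codes.size == 0:
            continue
        positions = np.arange(0, codes.size, step, dtype=np.int64)
        window_codes = codes[positions]
        keep = window_codes >= 0
        code_parts.append(window_codes[keep])
        pos_parts.append(positions[keep])
        ref_parts.append(np.full(int(keep.sum()), r, dtype=np.int64))
    if not code_parts:
        return index

    all_codes = np.concatenate(code_parts)
    all_refs = np.concatenate(ref_parts)
    all_pos = np.concatenate(pos_parts)
    order = np.argsort(all_codes, kind="stable")
    all_codes, all_refs, all_pos = all_codes[order], all_refs[order], all_pos[order]
    distinct, starts = np.unique(all_codes, return_index=True)
    bounds = np.append(starts, all_codes.size)

    bloom = np.frombuffer(bytes(index.bloom), dtype=np.uint8).copy()
    np.bitwise_or.at(bloom, distinct >> 3, np.left_shift(1, (distinct & 7)).astype(np.uint8))
    index.bloom = bytearray(bloom.tobytes())

    starts_list = starts.tolist()
    for i, code in enumerate(distinct.tolist()):
        lo, hi = starts_list[i], int(bounds[i + 1])
        index.buckets[code] = (all_refs[lo:hi], all_pos[lo:hi])
        if hi - lo > threshold:
            index.masked.add(code)
    index.n_entries = int(all_codes.size)

    if mask_low_complexity:
        bases = "ACGT"
        for code in index.buckets:
            kmer = "".join(bases[(code >> (2 * (k - 1 - t))) & 3] for t in range(k))
            if kmer_entropy(kmer) < lc_entropy_min:
                index.masked.add(code)
    return index


def lookup(
    index: KmerIndex,
    read: str,
    double: bool = False,
    max_candidates: int = 200,
) -> list[SeedHit]:
    """Candidate placements of ``read`` against the indexed references.

    Every read offset contributes its k-mer: the bloom bit is probed first
    and the bucket fetched only on a hit; masked buckets yield nothing.  Hits
    are deduplicated on (reference, diagonal) keeping the leftmost read
    offset.  With ``double=True`` the effective seed is ``2*index.k`` long: a
    hit requires the two adjacent sub-k-mers to occur at consecutive
    reference positions (consistent diagonal).  At most ``max_candidates``
    diagonals are returned, best-first by supporting seed count, emitted in
    (reference, diagonal) order.
    """
    k = index.k
    eff = 2 * k if double else k
    if len(read) < eff:
        return []
    codes = kmer_codes(read, k).tolist()
    bloom = index.bloom
    stats = index.stats
    cand: dict[tuple[int, int], list[int]] = {}  # (ref, diag) -> [count, pos, offset]
    n_off = len(read) - eff + 1
    for off in range(n_off):
        c1 = codes[off]
        if c1 < 0:
            continue
        stats["bloom_checks"] += 1
        if not bloom[c1 >> 3] & _BIT[c1 & 7]:
            continue
        stats["bloom_hits"] += 1
        if double:
            c2 = codes[off + k]
            if c2 < 0:
                continue
            stats["bloom_checks"] += 1
            if not bloom[c2 >> 3] & _BIT[c2 & 7]:
                continue
            stats["bloom_hits"] += 1
        entry = index._fetch(c1)
        if entry is None:
            continue
        refs, poss = entry
        if double:
            entry2 = index._fetch(c2)
            if entry2 is None:
                continue
            second = set(zip(entry2[0].tolist(), entry2[1].tolist()))
            pairs = [
                (ref, pos)
                for ref, pos in zip(refs.tolist(), poss.tolist())
                if (ref, pos + k) in second
            ]
        else:
            pairs = zip(refs.tolist(), poss.tolist())
        for ref, pos in pairs:
            key = (ref, pos - off)
            hit = cand.get(key)
            if hit is None:
                cand[key] = [1, pos, off]
            else:
                hit[0] += 1
    if len(cand) > max_candidates:
        ranked = sorted(cand.items(), key=lambda kv: (-kv[1][0], kv[0]))[:max_candidates]
        cand = dict(ranked)
    return [
        SeedHit(ref, info[1], info[2], eff)
        for (ref, _diag), info in sorted(cand.items())
    ]
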