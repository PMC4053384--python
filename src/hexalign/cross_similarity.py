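"""Explicit cross-similarity candidate skipping.

Consecutive reads in sorted unique order share a prefix of length c (the
cross-similarity coefficient).  If the previous read's extension attempt at
some (reference, diagonal) failed by more than the score swing the differing
suffix could possibly recover — ``(L - c) * (match - mismatch)`` in
extension-score units, scaled by a safety factor — the same candidate is
hopeless for the current read too and is skipped before any work is done.

Margins are extension-stage quantities, so the per-base swing defaults to
the extension scoring (match +1, mismatch -1); only extension failures are
memoized, and only for the immediately preceding sorted read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .kmer_index import SeedHit

__all__ = ["CandidateMemo", "filter_candidates"]


@dataclass
class CandidateMemo:
    """Candidate outcomes of the immediately preceding sorted unique read.

    ``records`` maps (reference ordinal, diagonal) to (aligned, fail margin);
    margins are >= 0 for failed entries and meaningless for aligned ones.
    """

    records: dict[tuple[int, int], tuple[bool, int]] = field(default_factory=dict)

    def record(self, ref: int, diagonal: int, aligned: bool, margin: int) -> None:
        if not aligned and margin < 0:
            raise ValueError("failed candidates must carry a non-negative margin")
        self.records[(ref, diagonal)] = (aligned, margin)

    def __len__(self) -> int:
        return len(self.records)


def filter_candidates(
    hits: Sequence[SeedHit],
    memo: CandidateMemo,
    c: int,
    read_len: int,
    match: int = 1,
    mismatch: int = -1,
    margin_factor: float = 1.0,
) -> list[SeedHit]:
    """Drop hits the previous similar read already failed with a wide margin.

    A hit at a memoized failed (reference, diagonal) is skipped iff the
    recorded margin exceeds ``(read_len - c) * (match - mismatch) *
    margin_factor`` — the maximum score swing the non-shared suffix can
    produce.  ``margin_factor=inf`` disables skipping entirely; all other
    hits (new positions, aligned positions, narrow failures) are retained.
    """
    if c < 0 or c > read_len:
        raise ValueError("shared prefix length must lie in [0, read_len]")
    if margin_factor == math.inf:
        return list(hits)
    bound = (read_len - c) * (match - mismatch) * margin_factor
    kept = []
    for hit in hits:
        rec = memo.records.get((hit.ref, hit.diagonal))
        if rec is not None and not rec[0] and rec[1] > bound:
            continue
        kept.append(hit)
    return kept
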