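"""Fuzzy bidirectional seed extension: candidate filter and frame bracketing.

Each exact seed hit is extended greedily to the left and right in a small
floating window using integer scores.  The extension serves two purposes:
it rejects accidental seed hits cheaply (random flanks stop extending within
a couple dozen bases), and for surviving candidates it brackets the frame in
which the expensive banded optimal alignment will run.

The stop rule and the pass rule are deliberately different.  Extension stops
only when the trailing 32-base window becomes half errors — a density no
biologically plausible candidate reaches, but one a random flank reaches
within ~20 bases.  The pass decision then applies the configured minimum
extension length (percent of the read) and mismatch allowance (percent of
the extended span, with one mismatch of slack so the optimal aligner, not
the filter, makes borderline calls).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

from .kmer_index import SeedHit

__all__ = ["ExtensionParams", "ExtensionResult", "fuzzy_extend"]


@dataclass(frozen=True)
class ExtensionParams:
    """Tunables for the extension filter.

    min_len_pct : minimal extended length as a percent of the read length
    mismatch_pct : allowed error density (mismatches + gap bases) over the
        extended span, in percent
    window : half-width of the floating front (maximum indel run considered)
    trailing_window : span (bases) over which the stop density is evaluated
    stop_fraction : trailing-window error fraction that terminates extension
    slack : extra mismatches tolerated by the pass rule (permissive filter)
    lookahead : exact-run length cap when ranking step alternatives
    """

    min_len_pct: float = 75.0
    mismatch_pct: float = 15.0
    window: int = 4
    trailing_window: int = 32
    stop_fraction: float = 0.5
    slack: int = 1
    lookahead: int = 16

    def __post_init__(self) -> None:
        if not (0 <= self.min_len_pct <= 100 and 0 <= self.mismatch_pct <= 100):
            raise ValueError("percent parameters must lie in [0, 100]")
        if self.window < 1:
            raise ValueError("extension window must be >= 1")


@dataclass
class ExtensionResult:
    """Outcome of one fuzzy extension.

    The bracket (half-open read/reference frame) always contains the seed.
    ``margin`` quantifies how far a failed extension fell below the pass
    threshold (integer score units); it is -1 for passing extensions.
    """

    passed: bool
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    score: int
    matches: int
    mismatches: int
    gap_opens: int
    gap_bases: int
    margin: int

    @property
    def bracket(self) -> tuple[int, int, int, int]:
        return (self.read_start, self.read_end, self.ref_start, self.ref_end)


def _run_len(a: str, b: str, i: int, j: int, cap: int) -> int:
    n = 0
    la, lb = len(a), len(b)
    while n < cap and i < la and j < lb and a[i] == b[j]:
        i += 1
        j += 1
        n += 1
    return n


def _extend_one_side(rs: str, qs: str, p: ExtensionParams):
    """Greedy front advance; returns state at the last matching position.

    Returns (read consumed, ref consumed, matches, mismatches, gap opens,
    gap bases) trimmed back to the last match, so brackets never end on an
    error run.
    """
    i = j = m = x = go = gb = 0
    best = (0, 0, 0, 0, 0, 0)
    win: deque[int] = deque(maxlen=p.trailing_window)
    wsum = 0
    stop_count = max(1, int(p.trailing_window * p.stop_fraction))
    cap = p.lookahead

    def push(flag: int) -> None:
        nonlocal wsum
        if len(win) == win.maxlen:
            wsum -= win[0]
        win.append(flag)
        wsum += flag

    lr, lq = len(rs), len(qs)
    while i < lr and j < lq:
        if rs[i] == qs[j]:
            i += 1
            j += 1
            m += 1
            push(0)
            best = (i, j, m, x, go, gb)
            continue
        # rank alternatives by (exact run gained) - (steps spent)
        kind, size = "x", 0
        vbest = _run_len(rs, qs, i + 1, j + 1, cap) - 1
        for g in range(1, p.window + 1):
            if i + g <= lr:
                r = _run_len(rs, qs, i + g, j, cap)
                if r >= 2 and r - (1 + g) > vbest:
                    vbest, kind, size = r - (1 + g), "i", g
            if j + g <= lq:
                r = _run_len(rs, qs, i, j + g, cap)
                if r >= 2 and r - (1 + g) > vbest:
                    vbest, kind, size = r - (1 + g), "d", g
        if kind == "x":
            i += 1
            j += 1
            x += 1
            push(1)
        elif kind == "i":  # extra read bases (insertion relative to reference)
            i += size
            go += 1
            gb += size
            for _ in range(size):
                push(1)
        else:  # missing read bases (deletion relative to reference)
            j += size
            go += 1
            gb += size
            for _ in range(size):
                push(1)
        if wsum >= stop_count:
            break
    return best


def fuzzy_extend(
    read: str,
    reference: str,
    hit: SeedHit,
    params: ExtensionParams = ExtensionParams(),
) -> ExtensionResult:
    """Extend a verified exact seed hit bidirectionally and judge it.

    The seed must match exactly at its stated coordinates (anything else is
    an upstream index bug and raises ``ValueError``).  Deterministic for
    fixed inputs.
    """
    off, pos, slen = hit.read_offset, hit.ref_pos, hit.length
    if off < 0 or pos < 0 or off + slen > len(read) or pos + slen > len(reference):
        raise ValueError("seed coordinates outside the sequences")
    if read[off : off + slen] != reference[pos : pos + slen]:
        raise ValueError("seed does not match exactly at its stated coordinates")

    ri, rj, rm, rx, rgo, rgb = _extend_one_side(read[off + slen :], reference[pos + slen :], params)
    li, lj, lm, lx, lgo, lgb = _extend_one_side(read[:off][::-1], reference[:pos][::-1], params)

    read_start, read_end = off - li, off + slen + ri
    ref_start, ref_end = pos - lj, pos + slen + rj
    matches = slen + rm + lm
    mismatches = rx + lx
    gap_opens = rgo + lgo
    gap_bases = rgb + lgb
    # extension-stage integer scoring: match +1, mismatch -1, gap open -2,
    # gap extend -1 (a gap of g bases costs g+1)
    score = matches - mismatches - (gap_opens + gap_bases)

    length = len(read)
    ext_len = read_end - read_start
    min_len = math.ceil(params.min_len_pct / 100.0 * length)
    edits = mismatches + gap_bases
    allowed = math.floor(params.mismatch_pct / 100.0 * ext_len) + params.slack
    passed = ext_len >= min_len and edits <= allowed

    if not passed and gap_opens > 0:
        # The greedy front occasionally explains a substitution cluster with
        # spurious compensating gaps and then mis-scores the candidate.  A
        # substitution-only candidate is exactly the ungapped diagonal, so
        # re-check it directly before rejecting (strictly more permissive).
        d = pos - off
        start = max(0, -d)
        end = min(length, len(reference) - d)
        span = end - start
        if span >= min_len:
            hamming = sum(1 for t in range(start, end) if read[t] != reference[t + d])
            if hamming <= math.floor(params.mismatch_pct / 100.0 * span) + params.slack:
                read_start, read_end = start, end
                ref_start, ref_end = start + d, end + d
                ext_len = span
                matches, mismatches = span - hamming, hamming
                gap_opens = gap_bases = 0
                score = matches - mismatches
                edits = hamming
                passed = True

    margin = -1 if passed else max(0, min_len - ext_len) + 2 * max(0, edits - allowed)

    return ExtensionResult(
        passed=passed,
        read_start=read_start,
        read_end=read_end,
        ref_start=ref_start,
        ref_end=ref_end,
        score=score,
        matches=matches,
        mismatches=mismatches,
        gap_opens=gap_opens,
        gap_bases=gap_bases,
        margin=margin,
    )
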