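"""Optimal alignment on a floating, variable-width, linearized diagonal band.

The Smith-Waterman recurrence (affine gaps) is evaluated row by row over
read positions, but each row only spans a band of half-width ``w`` centered
on the column where the previous row's best-scoring path sits — the band
*floats* with the alignment instead of being pinned to the seed diagonal, so
cumulative indel drift larger than the band width is still recovered as long
as no single excursion exceeds ``w``.  Cells whose admissible score upper
bound cannot reach the reporting threshold are pruned ("holes"): they are
marked dead, excluded from traceback, and never act as a path source.
Storage is one short array per row (~(2w+1) x L), never L x G.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "ScoringParams",
    "Thresholds",
    "Alignment",
    "BandMatrix",
    "band_align",
    "traceback",
    "score_upper_bound",
    "score_of_ops",
    "AlignerInternalError",
]

NEG = -(10**9)


class AlignerInternalError(RuntimeError):
    """Internal consistency violation (e.g. a traceback pointer into a dead cell)."""


@dataclass(frozen=True)
class ScoringParams:
    """Additive scoring factors: positive match benefit, non-positive costs.

    A gap of length g costs ``gap_open + (g-1) * gap_extend`` (the open cost
    covers the first gap base).  Setting ``gap_open == gap_extend`` recovers
    linear gap costs.
    """

    match: int = 5
    mismatch: int = -4
    gap_open: int = -12
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match benefit must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch and gap costs must be <= 0")

    def gap_score(self, length: int) -> int:
        return self.gap_open + (length - 1) * self.gap_extend if length else 0


@dataclass(frozen=True)
class Thresholds:
    """Reporting thresholds: minimum match length and mismatch percentage."""

    min_match_len: int = 36
    max_mismatch_pct: float = 15.0

    def min_score(self, params: ScoringParams) -> int:
        """Score of the weakest reportable alignment (the pruning target)."""
        allowed = int(self.min_match_len * self.max_mismatch_pct / 100.0)
        return (self.min_match_len - allowed) * params.match + allowed * params.mismatch


@dataclass(frozen=True)
class Alignment:
    """An alignment trajectory with its additive score.

    ``ops`` is a string over '=' (match), 'X' (mismatch), 'I' (read base not
    in reference) and 'D' (reference base not in read).  Read/reference
    coordinates are 0-based half-open; for reverse-strand alignments the read
    coordinates refer to the reverse-complemented read (SAM orientation).
    """

    read_ordinal: int
    ref_ordinal: int
    strand: str
    score: int
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    ops: str
    read_len: int

    def cigar(self) -> str:
        if not self.ops:
            return "*"
        parts: list[str] = []
        if self.read_start:
            parts.append(f"{self.read_start}S")
        run_op, run_len = "", 0
        for op in self.ops:
            sam_op = "M" if op in "=X" else op
            if sam_op == run_op:
                run_len += 1
            else:
                if run_len:
                    parts.append(f"{run_len}{run_op}")
                run_op, run_len = sam_op, 1
        parts.append(f"{run_len}{run_op}")
        tail = self.read_len - self.read_end
        if tail:
            parts.append(f"{tail}S")
        return "".join(parts)

    @property
    def n_mismatches(self) -> int:
        return self.ops.count("X")

    def recompute_score(self, params: ScoringParams) -> int:
        return score_of_ops(self.ops, params)


def score_of_ops(ops: str, params: ScoringParams) -> int:
    """Sum of per-operation scoring factors, with affine gap runs."""
    score = 0
    gap_run = ""
    run = 0
    for op in ops:
        if op in "ID":
            if op == gap_run:
                run += 1
            else:
                score += params.gap_score(run)
                gap_run, run = op, 1
        else:
            score += params.gap_score(run)
            gap_run, run = "", 0
            score += params.match if op == "=" else params.mismatch
    score += params.gap_score(run)
    return score


def score_upper_bound(
    distance: int,
    remaining: int,
    params: ScoringParams,
    current: int,
) -> int:
    """Admissible bound on any reportable score through a band cell.

    ``current`` is the path score accumulated at the cell, ``remaining`` the
    read rows still ahead, ``distance`` the cell's offset from the band
    center (the running best-scoring column).  The future gain is at most
    ``remaining * match``; a cell off the center additionally owes the gap
    schedule for rejoining the best path.  The future term is floored at
    zero so the bound never drops below the cell's own score — the cell may
    itself be the local end of the alignment.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    potential = remaining * params.match
    if distance > 0:
        potential += params.gap_open + (distance - 1) * params.gap_extend
    return current + max(0, potential)


class BandMatrix:
    """Linearized band storage: one (offset, arrays) record per read row.

    Row ``i`` (1-based read position) stores H values, pointer codes
    (0 stop, 1 diagonal, 2 gap-in-read via E, 3 gap-in-reference via F),
    E/F extension flags for affine traceback, and the live-cell bitmap
    (False = pruned hole).  Dead cells are never read back.
    """

    __slots__ = ("rows", "live_cells", "hole_cells", "w")

    def __init__(self, w: int):
        self.rows: list[tuple] = []  # (lo, H, ptr, eext, fext, live, center)
        self.live_cells = 0
        self.hole_cells = 0
        self.w = w

    def add_row(self, lo, H, ptr, eext, fext, live, center) -> None:
        self.rows.append((lo, H, ptr, eext, fext, live, center))
        alive = sum(live)
        self.live_cells += alive
        self.hole_cells += len(live) - alive

    def _cell(self, i: int, j: int) -> tuple[int, tuple]:
        row = self.rows[i - 1]
        idx = j - row[0]
        if idx < 0 or idx >= len(row[1]):
            raise AlignerInternalError(f"cell ({i},{j}) outside the stored band")
        if not row[5][idx]:
            raise AlignerInternalError(f"traceback pointer into pruned cell ({i},{j})")
        return idx, row

    def ptr(self, i: int, j: int) -> int:
        idx, row = self._cell(i, j)
        return row[2][idx]

    def eext(self, i: int, j: int) -> bool:
        idx, row = self._cell(i, j)
        return row[3][idx]

    def fext(self, i: int, j: int) -> bool:
        idx, row = self._cell(i, j)
        return row[4][idx]

    def value(self, i: int, j: int) -> int:
        idx, row = self._cell(i, j)
        return row[1][idx]


def traceback(band: BandMatrix, best_i: int, best_j: int, read: str, window: str):
    """Recover the trajectory ending at the given live cell.

    Returns (ops string, read start, window start), both 0-based.  The walk
    follows stored pointers through live cells only; hitting a dead cell is
    an internal error (bug trap), not a recoverable condition.
    """
    ops: list[str] = []
    i, j = best_i, best_j
    state = "H"
    while True:
        if state == "H":
            if i == 0:
                break
            p = band.ptr(i, j)
            if p == 0:
                break
            if p == 1:
                ops.append("=" if read[i - 1] == window[j - 1] else "X")
                i -= 1
                j -= 1
                if i == 0 or j == 0:
                    break
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in the read: consumes reference
            ext = band.eext(i, j)
            ops.append("D")
            j -= 1
            state = "E" if ext else "H"
            if j == 0:
                break
        else:  # gap in the reference: consumes read
            ext = band.fext(i, j)
            ops.append("I")
            i -= 1
            state = "F" if ext else "H"
            if i == 0:
                break
    ops.reverse()
    return "".join(ops), i, j


def band_align(
    read: str,
    reference: str,
    bracket: tuple[int, int, int, int],
    params: ScoringParams = ScoringParams(),
    w: int = 8,
    thresholds: Thresholds = Thresholds(),
    *,
    mode: str = "local",
    float_center: bool = True,
    prune: bool = True,
    read_ordinal: int = 0,
    ref_ordinal: int = 0,
    strand: str = "+",
    diagnostics: Optional[dict] = None,
) -> Optional[Alignment]:
    """Banded optimal alignment inside a bracketed frame.

    ``bracket`` is the (read_start, read_end, ref_start, ref_end) half-open
    frame from fuzzy extension; the reference window is the bracket padded by
    the band slack.  ``mode='local'`` is the Smith-Waterman recurrence (the
    default); ``mode='glocal'`` fits the whole read into the window
    (Needleman-Wunsch-style over the read, free reference shifts).

    Returns the maximum-score trajectory, or ``None`` when no alignment
    reaches the reporting thresholds.  Among equal scores the first maximum
    encountered (ascending read row, then ascending column) is kept.
    """
    if mode not in ("local", "glocal"):
        raise ValueError("mode must be 'local' or 'glocal'")
    if w < 1:
        raise ValueError("band half-width must be >= 1")
    L = len(read)
    rs, re_, qs, qe = bracket
    if not (0 <= rs <= re_ <= L):
        raise ValueError("bracket read frame outside the read")
    if not (0 <= qs <= qe <= len(reference)):
        raise ValueError("bracket outside the reference")

    pad = w + 2
    w0 = max(0, qs - rs - pad)
    w1 = min(len(reference), qe + (L - re_) + pad)
    window = reference[w0:w1]
    W = len(window)
    if W == 0 or L == 0:
        return None

    theta = thresholds.min_score(params)
    prune_floor = theta if prune else NEG // 2
    match, mismatch = params.match, params.mismatch
    gopen, gext = params.gap_open, params.gap_extend
    local = mode == "local"

    band = BandMatrix(w)
    diag_start = (qs - w0) - rs  # seed-side diagonal in window coordinates
    diag_end = (qe - w0) - re_  # bracket-end diagonal (captures net indels)
    span = max(1, re_ - rs)
    # steering zone: only cells this close to the inertial track may pull the
    # center.  Cells further out are either noise or gap-fed "ghosts" of a
    # strong prefix, which out-score a gap-stalled path for many rows and
    # would otherwise drag the band off it.
    steer_w = max(1, w // 2)
    steer_floor = 4 * match  # weaker maxima are indistinguishable from noise
    offset = 0
    prev_lo = 0
    prev_H: list[int] = []
    prev_F: list[int] = []
    prev_live: list[bool] = []
    prev_argmax: Optional[int] = None

    best_score, best_i, best_j = (0 if local else NEG), -1, -1

    for i in range(1, L + 1):
        # The band floats in two ways.  Its inertial track interpolates the
        # diagonal between the two bracket ends (the fuzzy extension already
        # traced any net indel drift), and an offset bounded by the steering
        # zone crawls one column per row toward the best scoring column near
        # the track.  With float_center off the band stays pinned to the
        # seed diagonal.
        if float_center:
            t = min(max(i, rs), re_)
            base = diag_start + (diag_end - diag_start) * (t - rs) // span
        else:
            base = diag_start
        track = i + base
        if float_center and prev_argmax is not None:
            target = prev_argmax + 1
            current = track + offset
            if target > current and offset < steer_w:
                offset += 1
            elif target < current and offset > -steer_w:
                offset -= 1
        center = track + offset
        center = min(max(center, 1), W)
        lo = max(1, center - w)
        hi = min(W, center + w)
        width = hi - lo + 1
        H = [0] * width
        F = [NEG] * width
        ptr = [0] * width
        eext = [False] * width
        fext = [False] * width
        live = [True] * width
        rb = read[i - 1]
        e_prev = NEG  # E value at the previous column of this row
        row_max, row_argmax = NEG, None
        remaining = L - i

        for j in range(lo, hi + 1):
            idx = j - lo
            sub = match if rb == window[j - 1] else mismatch

            # diagonal source H(i-1, j-1); the virtual row 0 is all zeros
            if i == 1:
                hd = sub
            else:
                pidx = (j - 1) - prev_lo
                if 0 <= pidx < len(prev_H) and prev_live[pidx]:
                    hd = prev_H[pidx] + sub
                else:
                    hd = NEG

            # F: gap in reference (vertical), from H/F(i-1, j)
            if i == 1:
                f_open = gopen  # H(0, j) == 0
                f_ext = NEG
            else:
                pidx = j - prev_lo
                if 0 <= pidx < len(prev_H) and prev_live[pidx]:
                    f_open = prev_H[pidx] + gopen
                    f_ext = prev_F[pidx] + gext
                else:
                    f_open = f_ext = NEG
            if f_ext > f_open:
                f_val, f_from_ext = f_ext, True
            else:
                f_val, f_from_ext = f_open, False

            # E: gap in read (horizontal), from H/E(i, j-1)
            if idx > 0 and live[idx - 1]:
                e_open = H[idx - 1] + gopen
            else:
                e_open = NEG
            e_ext = e_prev + gext
            if e_ext > e_open:
                e_val, e_from_ext = e_ext, True
            else:
                e_val, e_from_ext = e_open, False

            cand = hd
            p = 1
            if e_val > cand:
                cand, p = e_val, 2
            if f_val > cand:
                cand, p = f_val, 3
            if local and cand <= 0:
                h, p = 0, 0
            else:
                h = cand

            # pruning: admissible upper bound vs the reporting threshold
            if prune:
                dist = j - center if j >= center else center - j
                potential = remaining * match
                if dist > 0:
                    potential += gopen + (dist - 1) * gext
                if potential < 0:
                    potential = 0
                if h + potential < prune_floor:
                    live[idx] = False
                    H[idx] = NEG
                    e_prev = NEG
                    F[idx] = NEG
                    continue

            H[idx] = h
            ptr[idx] = p
            F[idx] = f_val
            fext[idx] = f_from_ext
            eext[idx] = e_from_ext
            e_prev = e_val
            # steering candidates: near-track cells above the noise floor
            if (
                (track - steer_w) <= j <= (track + steer_w)
                and (not local or h >= steer_floor)
                and (
                    h > row_max
                    or (
                        h == row_max
                        and row_argmax is not None
                        and abs(j - track) < abs(row_argmax - track)
                    )
                )
            ):
                row_max, row_argmax = h, j
            if local:
                if h > best_score:
                    best_score, best_i, best_j = h, i, j
            elif i == L and h > best_score:
                best_score, best_i, best_j = h, i, j

        band.add_row(lo, H, ptr, eext, fext, live, center)
        prev_lo, prev_H, prev_F, prev_live = lo, H, F, live
        prev_argmax = row_argmax

    assert band.live_cells <= (2 * w + 1) * L

    if diagnostics is not None:
        diagnostics.update(
            live_cells=band.live_cells,
            hole_cells=band.hole_cells,
            rows=len(band.rows),
            window_length=W,
            min_score=theta,
        )

    if best_i < 0 or best_score < theta:
        return None

    ops, i0, j0 = traceback(band, best_i, best_j, read, window)
    if not ops:
        return None
    rescored = score_of_ops(ops, params)
    if rescored != best_score:
        raise AlignerInternalError(
            f"trajectory score {rescored} != matrix score {best_score}"
        )
    aln = Alignment(
        read_ordinal=read_ordinal,
        ref_ordinal=ref_ordinal,
        strand=strand,
        score=best_score,
        read_start=i0,
        read_end=best_i,
        ref_start=w0 + j0,
        ref_end=w0 + best_j,
        ops=ops,
        read_len=L,
    )
    span = aln.read_end - aln.read_start
    if span < thresholds.min_match_len:
        return None
    if aln.n_mismatches > thresholds.max_mismatch_pct / 100.0 * len(ops) + 1e-9:
        return None
    return aln
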