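"""Shared fixtures: RNG-driven sequence builders and the full-matrix oracle."""

from __future__ import annotations

import numpy as np
import pytest

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def mutate_subs(rng: np.random.Generator, seq: str, n_sub: int, protect: range = range(0)) -> str:
    """Substitute n_sub positions (never inside ``protect``)."""
    out = list(seq)
    candidates = [p for p in range(len(seq)) if p not in protect]
    for p in rng.choice(candidates, size=n_sub, replace=False):
        out[p] = BASES[(BASES.index(out[p]) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(out)


def homologous_pair(rng, L=100, flank=30, n_sub=6, indel_sizes=(), protect=range(0)):
    """A (read, window, bracket) triple with planted substitutions and indels.

    The read derives from window[flank : flank+L] with ``n_sub`` substitutions
    and the requested indels (positive size = insertion into the read,
    negative = deletion from the read).  The bracket reflects the true frame,
    including the net reference consumption, as a fuzzy extension would.
    """
    window = random_seq(rng, L + 2 * flank)
    src = list(window[flank : flank + L + 16])
    positions = sorted(
        int(p) for p in rng.choice(range(10, L - 10), size=len(indel_sizes), replace=False)
    )
    read: list[str] = []
    i = 0
    pending = list(zip(positions, indel_sizes))
    while len(read) < L and i < len(src):
        if pending and i == pending[0][0]:
            _, size = pending.pop(0)
            if size > 0:
                read.extend(random_seq(rng, size))
            else:
                i += -size
            continue
        read.append(src[i])
        i += 1
    read = "".join(read[:L])
    read = mutate_subs(rng, read, n_sub, protect)
    bracket = (0, len(read), flank, min(flank + i, len(window)))
    return read, window, bracket


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sw_oracle():
    """Full-matrix local Smith-Waterman with the default scoring (independent oracle)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -2
    return aligner
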