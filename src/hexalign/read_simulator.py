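"""Synthetic references and artificial read sets with controlled error rates.

The generator emulates the classic aligner-validation protocol: uniform
i.i.d. random references, and reads cut from uniform random positions (and,
by default, either strand) of a uniform random reference, then mutated
per-base with a configured error rate.  Error-free sets correspond to a 0%
rate, and the standard 1% / 5% sets to rates 0.01 / 0.05.  Each read carries
provenance (source reference, offset, strand, injected edit counts) written
to a truth table so downstream accuracy can be scored exactly.

Everything is driven by a single integer seed: identical configurations
produce byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .sequence_io import ReadRecord, Reference, reverse_complement

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_reference",
    "simulate_references",
    "simulate_reads",
    "write_truth",
    "read_truth",
]

_BASES = "ACGT"
# tail buffer reserved when e > 0 so deletions cannot run off the template
_TAIL_BUFFER = 16


@dataclass(frozen=True)
class SimConfig:
    """Read-set generation parameters.

    error_rate is the per-base probability of injecting an error; of the
    errored positions a fraction ``sub_fraction`` become substitutions and
    the rest split between insertions and deletions.  ``source_subset``
    restricts sampling to the named reference ordinals (mixture experiments);
    ``n_templates`` draws reads from only that many distinct (reference,
    offset, strand) templates to emulate highly redundant datasets.
    """

    n_reads: int
    read_length: int = 100
    error_rate: float = 0.0
    sub_fraction: float = 0.90
    ins_fraction: float = 0.05
    del_fraction: float = 0.05
    seed: int = 0
    source_subset: Optional[tuple[int, ...]] = None
    n_templates: Optional[int] = None
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error rate must lie in [0, 1)")
        if self.n_reads < 0 or self.read_length < 1:
            raise ValueError("read count must be >= 0 and read length >= 1")
        total = self.sub_fraction + self.ins_fraction + self.del_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("error composition fractions must sum to 1")


@dataclass(frozen=True)
class TruthRecord:
    """Provenance of one simulated read (0-based forward-strand offset)."""

    read_id: str
    ref_id: str
    offset: int
    strand: str
    n_sub: int
    n_ins: int
    n_del: int

    @property
    def n_edits(self) -> int:
        return self.n_sub + self.n_ins + self.n_del


def simulate_reference(length: int, seed: int, ref_id: Optional[str] = None) -> Reference:
    """A uniform i.i.d. ACGT reference of the given length (seeded)."""
    if length < 1:
        raise ValueError("reference length must be >= 1")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length)
    seq = np.frombuffer(_BASES.encode(), dtype=np.uint8)[codes].tobytes().decode("ascii")
    return Reference(ref_id or f"simref_{length}_{seed}", seq)


def simulate_references(count: int, length: int, seed: int) -> list[Reference]:
    """``count`` independent random references with distinct sub-seeds."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=count)
    return [
        Reference(f"simref{i:02d}", simulate_reference(length, int(s)).seq, index_in_set=i)
        for i, s in enumerate(seeds)
    ]


def _mutate(window: str, length: int, rng: np.random.Generator, cfg: SimConfig):
    """Apply the per-base error model while emitting exactly ``length`` bases."""
    out: list[str] = []
    n_sub = n_ins = n_del = 0
    src = 0
    e = cfg.error_rate
    p_ins = cfg.ins_fraction
    p_del = cfg.ins_fraction + cfg.del_fraction
    while len(out) < length and src < len(window):
        if e > 0.0 and rng.random() < e:
            kind = rng.random()
            if kind < p_ins:
                out.append(_BASES[rng.integers(0, 4)])
                n_ins += 1
                continue  # insertion does not consume a template base
            if kind < p_del:
                src += 1
                n_del += 1
                continue
            original = window[src]
            choices = _BASES.replace(original, "")
            out.append(choices[rng.integers(0, 3)])
            src += 1
            n_sub += 1
        else:
            out.append(window[src])
            src += 1
    return "".join(out), n_sub, n_ins, n_del


def simulate_reads(
    references: Sequence[Reference],
    config: SimConfig,
) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Draw reads per the configuration; returns (reads, truth records).

    Each read is cut at a uniform random offset of a uniform random source
    reference (restricted to ``source_subset`` when given), optionally
    reverse-complemented, and mutated per base with probability
    ``error_rate``.  With a zero error rate every read is an exact substring
    of its source strand.
    """
    if not references:
        raise ValueError("need at least one reference")
    rng = np.random.default_rng(config.seed)
    pool = list(config.source_subset) if config.source_subset is not None else list(range(len(references)))
    for r in pool:
        if not (0 <= r < len(references)):
            raise ValueError(f"source subset ordinal {r} out of range")
    L = config.read_length
    buffer = _TAIL_BUFFER if config.error_rate > 0 else 0
    for r in pool:
        if len(references[r].seq) < L + buffer:
            raise ValueError(f"reference {references[r].id!r} shorter than a read window")

    templates = None
    if config.n_templates is not None:
        templates = []
        for _ in range(config.n_templates):
            r = pool[int(rng.integers(0, len(pool)))]
            max_off = len(references[r].seq) - L - buffer
            off = int(rng.integers(0, max_off + 1))
            strand = "-" if (config.both_strands and rng.random() < 0.5) else "+"
            templates.append((r, off, strand))

    reads: list[ReadRecord] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_reads):
        if templates is not None:
            r, off, strand = templates[int(rng.integers(0, len(templates)))]
        else:
            r = pool[int(rng.integers(0, len(pool)))]
            max_off = len(references[r].seq) - L - buffer
            off = int(rng.integers(0, max_off + 1))
            strand = "-" if (config.both_strands and rng.random() < 0.5) else "+"
        window = references[r].seq[off : off + L + buffer]
        seq, n_sub, n_ins, n_del = _mutate(window, L, rng, config)
        if strand == "-":
            seq = reverse_complement(seq)
        rid = f"r{i:06d}"
        reads.append(ReadRecord(rid, seq, "I" * len(seq)))
        truths.append(TruthRecord(rid, references[r].id, off, strand, n_sub, n_ins, n_del))
    return reads, truths


def write_truth(truths: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tref_id\toffset\tstrand\tn_sub\tn_ins\tn_del\n")
        for t in truths:
            fh.write(
                f"{t.read_id}\t{t.ref_id}\t{t.offset}\t{t.strand}\t{t.n_sub}\t{t.n_ins}\t{t.n_del}\n"
            )


def read_truth(path) -> dict[str, TruthRecord]:
    out: dict[str, TruthRecord] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise ValueError("not a truth table (missing header)")
        for line in fh:
            rid, ref_id, off, strand, ns, ni, nd = line.rstrip("\n").split("\t")
            out[rid] = TruthRecord(rid, ref_id, int(off), strand, int(ns), int(ni), int(nd))
    return out
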