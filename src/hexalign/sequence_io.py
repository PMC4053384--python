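"""FASTA/FASTQ/SAM input-output and the 2-bit ("2-na") nucleotide encoding.

Sequences live in memory as upper-case Python strings over {A,C,G,T,N}.
Wherever a k-mer has to act as an integer index, bases are encoded two bits
per base (A=0, C=1, G=2, T=3) with the *first* base in the most significant
bits, so that integer order of k-mer codes equals lexicographic order of the
k-mers themselves.  That convention is what lets sorted reads touch monotone
regions of the seed index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "AmbiguousBaseError",
    "ReadRecord",
    "Reference",
    "TwoBitSeq",
    "encode_2na",
    "kmer_code",
    "kmer_codes",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_sam",
]


class FormatError(ValueError):
    """Malformed FASTA/FASTQ input."""


class AmbiguousBaseError(ValueError):
    """A k-mer window contains a base outside {A,C,G,T} and is unindexable."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte -> 2-bit code, -1 for anything that is not an unambiguous base
_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE_LUT[_b] = _c
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReadRecord:
    """A single short read with an optional Sanger quality string."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Reference:
    """One reference genome record, with its ordinal within the reference set."""

    id: str
    seq: str
    index_in_set: int = 0

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"reference {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


class TwoBitSeq:
    """A nucleotide string packed at two bits per base.

    Only unambiguous bases can be packed; ``decode(encode(s)) == s`` for any
    string over ACGT.  The first base of the sequence occupies the most
    significant bits of the first byte.
    """

    __slots__ = ("packed", "length")

    def __init__(self, packed: np.ndarray, length: int):
        self.packed = packed
        self.length = length

    def __len__(self) -> int:
        return self.length

    def decode(self) -> str:
        bits = np.unpackbits(self.packed)[: 2 * self.length]
        codes = (bits[0::2] << 1) | bits[1::2]
        return _BASES[codes].tobytes().decode("ascii")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TwoBitSeq)
            and self.length == other.length
            and np.array_equal(self.packed, other.packed)
        )


def _codes_of(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def encode_2na(seq: str) -> TwoBitSeq:
    """Pack ``seq`` (ACGT only) into a :class:`TwoBitSeq`."""
    codes = _codes_of(seq)
    if (codes < 0).any():
        bad = int(np.argmax(codes < 0))
        raise AmbiguousBaseError(f"base {seq[bad]!r} at position {bad} is not 2-bit encodable")
    bits = ((codes[:, None].astype(np.uint8) >> np.array([1, 0], dtype=np.uint8)) & 1).ravel()
    return TwoBitSeq(np.packbits(bits), len(seq))


def kmer_code(seq: str, offset: int, k: int) -> int:
    """Integer code of ``seq[offset:offset+k]`` in [0, 4**k).

    Raises :class:`AmbiguousBaseError` when the window contains a base outside
    ACGT (the caller is expected to skip that seed position).
    """
    if k > 31:
        raise ValueError("k-mer length above 31 overflows the 2-bit integer code")
    if offset < 0 or offset + k > len(seq):
        raise ValueError("k-mer window outside the sequence")
    code = 0
    for base in seq[offset : offset + k]:
        c = _CODE_LUT[ord(base)]
        if c < 0:
            raise AmbiguousBaseError(f"ambiguous base {base!r} makes the k-mer unindexable")
        code = (code << 2) | int(c)
    return code


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Codes of every k-mer window of ``seq`` (vectorized).

    Returns an int64 array of length ``len(seq) - k + 1``; windows containing
    an ambiguous base are -1.
    """
    codes = _codes_of(seq).astype(np.int64)
    n = len(seq)
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    bad = (codes < 0).astype(np.int64)
    safe = np.where(codes < 0, 0, codes)
    out = np.zeros(m, dtype=np.int64)
    for t in range(k):
        out = (out << 2) | safe[t : t + m]
    cs = np.concatenate(([0], np.cumsum(bad)))
    out[(cs[k:] - cs[:-k]) > 0] = -1
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[Reference]:
    """Parse a FASTA file into :class:`Reference` records (file order).

    Multi-line sequences are concatenated and case-folded to upper case.
    Malformed input raises :class:`FormatError` naming the offending line.
    """
    refs: list[Reference] = []
    ids: set[str] = set()
    cur_id: Optional[str] = None
    cur: list[str] = []
    header_line = 0

    def _flush() -> None:
        nonlocal cur_id, cur
        if cur_id is None:
            return
        seq = "".join(cur)
        if not seq:
            raise FormatError(f"line {header_line}: FASTA record {cur_id!r} has no sequence")
        if cur_id in ids:
            raise FormatError(f"line {header_line}: duplicate FASTA id {cur_id!r}")
        ids.add(cur_id)
        refs.append(Reference(cur_id, seq.upper(), index_in_set=len(refs)))
        cur_id, cur = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                cur_id = line[1:].split()[0] if line[1:].strip() else ""
                if not cur_id:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                header_line = lineno
            else:
                if cur_id is None:
                    raise FormatError(f"line {lineno}: sequence data before any FASTA header")
                cur.append(line)
    _flush()
    return refs


def write_fasta(records: Iterable, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.seq
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> list[ReadRecord]:
    """Parse 4-line-record FASTQ; an empty file yields an empty list."""
    reads: list[ReadRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(f"line {len(lines)}: truncated FASTQ record (not a multiple of 4 lines)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise FormatError(f"line {lineno}: FASTQ header must start with '@'")
        if not plus.startswith("+"):
            raise FormatError(f"line {lineno + 2}: FASTQ separator must start with '+'")
        if len(qual) != len(seq):
            raise FormatError(
                f"line {lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        rid = head[1:].split()[0] if head[1:].strip() else ""
        if not rid:
            raise FormatError(f"line {lineno}: empty FASTQ read id")
        reads.append(ReadRecord(rid, seq.upper(), qual))
    return reads


def write_fastq(records: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM output
# ---------------------------------------------------------------------------

def write_sam(
    alignments: Sequence,
    references: Sequence[Reference],
    reads: Sequence[ReadRecord],
    path,
    counts: Optional[Sequence[int]] = None,
    command_line: Optional[str] = None,
) -> None:
    """Write single-end SAM v1.6.

    ``alignments`` is parallel to ``reads``: either an alignment object (see
    :class:`hexalign.diagonal_aligner.Alignment`) or ``None`` for an unmapped
    read.  When ``counts`` is given (collapsed/non-redundified mode) each row
    carries an ``XC:i`` redundancy-count tag instead of being expanded.

    Reverse-strand alignments follow the SAM convention: FLAG 0x10 is set and
    SEQ/QUAL are stored in reference-forward orientation, i.e. the alignment
    was computed on the reverse complement of the original read and that
    oriented sequence is what is written.
    """
    if len(alignments) != len(reads):
        raise ValueError("alignments and reads must be parallel sequences")
    if counts is not None and len(counts) != len(reads):
        raise ValueError("counts must be parallel to reads")
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for ref in references:
            fh.write(f"@SQ\tSN:{ref.id}\tLN:{len(ref.seq)}\n")
        pg = "@PG\tID:hexalign\tPN:hexalign\tVN:1.0.0"
        if command_line:
            pg += f"\tCL:{command_line}"
        fh.write(pg + "\n")
        for i, (read, aln) in enumerate(zip(reads, alignments)):
            qual = read.qual if read.qual is not None else "*"
            if aln is None:
                row = [read.id, "4", "*", "0", "0", "*", "*", "0", "0", read.seq, qual]
            else:
                if not (0 <= aln.ref_ordinal < len(references)):
                    raise ValueError(f"alignment for read {read.id!r}: bad reference ordinal")
                flag = 16 if aln.strand == "-" else 0
                if aln.strand == "-":
                    seq_out = reverse_complement(read.seq)
                    qual_out = qual if qual == "*" else qual[::-1]
                else:
                    seq_out, qual_out = read.seq, qual
                nm = aln.ops.count("X") + aln.ops.count("I") + aln.ops.count("D")
                row = [
                    read.id,
                    str(flag),
                    references[aln.ref_ordinal].id,
                    str(aln.ref_start + 1),
                    "255",
                    aln.cigar(),
                    "*",
                    "0",
                    "0",
                    seq_out,
                    qual_out,
                    f"AS:i:{aln.score}",
                    f"NM:i:{nm}",
                ]
            if counts is not None:
                row.append(f"XC:i:{counts[i]}")
            fh.write("\t".join(row) + "\n")
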