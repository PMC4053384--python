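"""Read non-redundification via a compressed prefix (radix) tree.

Exactly identical reads are collapsed to one stored copy with a redundancy
counter; a left-first traversal of the tree then yields the unique reads in
lexicographic order together with per-read cross-similarity coefficients (the
length of the longest common prefix with the previous sorted read).  The read
space can additionally be partitioned into 4**k classes keyed by the 2-bit
code of the first k bases, so per-class trees can be built independently and
their sorted outputs concatenated without any merge step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "PrefixTree",
    "UniqueReadSet",
    "sorted_traversal",
    "partition_by_prefix",
    "build_unique_set",
    "longest_common_prefix",
]

_PREFIX_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def longest_common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    if a[:n] == b[:n]:
        return n
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


class _Node:
    __slots__ = ("edge", "children", "count", "ordinals")

    def __init__(self, edge: str):
        self.edge = edge
        self.children: dict[str, _Node] = {}
        self.count = 0  # >0 marks a terminal (unique read) node
        self.ordinals: list[int] = []


class PrefixTree:
    """Radix tree over read sequences with duplicate counting.

    Sibling edges start with distinct first bases and unary paths are
    compressed, so inserting a read costs one comparison per tree level
    rather than one per stored read.
    """

    def __init__(self) -> None:
        self.root = _Node("")
        self.n_inserted = 0
        self.n_unique = 0

    def __len__(self) -> int:
        return self.n_unique

    def insert(self, seq: str, ordinal: int = -1) -> bool:
        """Insert ``seq``; return True if new, False if a duplicate.

        Duplicates increment the redundancy counter of the existing terminal.
        """
        if not seq:
            raise ValueError("cannot insert an empty sequence")
        self.n_inserted += 1
        node = self.root
        rest = seq
        while True:
            if not rest:
                # sequence ends exactly at this node
                is_new = node.count == 0
                node.count += 1
                node.ordinals.append(ordinal)
                if is_new:
                    self.n_unique += 1
                return is_new
            child = node.children.get(rest[0])
            if child is None:
                leaf = _Node(rest)
                leaf.count = 1
                leaf.ordinals.append(ordinal)
                node.children[rest[0]] = leaf
                self.n_unique += 1
                return True
            lcp = longest_common_prefix(child.edge, rest)
            if lcp == len(child.edge):
                node = child
                rest = rest[lcp:]
                continue
            # split the child edge at the divergence point (single node split)
            mid = _Node(child.edge[:lcp])
            child.edge = child.edge[lcp:]
            mid.children[child.edge[0]] = child
            node.children[mid.edge[0]] = mid
            rest = rest[lcp:]
            if rest:
                leaf = _Node(rest)
                leaf.count = 1
                leaf.ordinals.append(ordinal)
                mid.children[rest[0]] = leaf
            else:
                mid.count = 1
                mid.ordinals.append(ordinal)
            self.n_unique += 1
            return True

    def traverse(self) -> Iterator[tuple[str, int, list[int]]]:
        """Yield (sequence, count, original ordinals) in lexicographic order.

        Left-first depth traversal; a terminal that is a proper prefix of a
        longer read is yielded before its extensions (shorter-first rule).
        Each node is visited exactly once.
        """
        stack = [(self.root, "")]
        while stack:
            node, prefix = stack.pop()
            label = prefix + node.edge
            for base in sorted(node.children, reverse=True):
                stack.append((node.children[base], label))
            if node.count:
                yield label, node.count, node.ordinals


@dataclass
class UniqueReadSet:
    """Sorted unique reads with redundancy counts and cross-similarity.

    ``cross_similarity[i]`` is the longest-common-prefix length (in bases)
    between sorted unique read i and read i-1; ``cross_similarity[0] == 0``.
    ``unique_of_read`` maps every original read ordinal to its unique ordinal.
    """

    sequences: list[str]
    counts: np.ndarray
    cross_similarity: np.ndarray
    unique_of_read: dict[int, int]

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.sequences)


def _assemble(entries: Iterable[tuple[str, int, list[int]]]) -> UniqueReadSet:
    sequences: list[str] = []
    counts: list[int] = []
    cross: list[int] = []
    unique_of_read: dict[int, int] = {}
    prev = None
    for seq, count, ordinals in entries:
        u = len(sequences)
        sequences.append(seq)
        counts.append(count)
        cross.append(0 if prev is None else longest_common_prefix(prev, seq))
        for o in ordinals:
            if o >= 0:
                unique_of_read[o] = u
        prev = seq
    return UniqueReadSet(
        sequences,
        np.asarray(counts, dtype=np.int64),
        np.asarray(cross, dtype=np.int64),
        unique_of_read,
    )


def sorted_traversal(tree: PrefixTree) -> UniqueReadSet:
    """Materialize a tree into a :class:`UniqueReadSet` (empty tree -> empty set)."""
    return _assemble(tree.traverse())


def partition_by_prefix(seqs: Sequence[str], k: int) -> list[list[int]]:
    """Partition read ordinals into 4**k disjoint buckets.

    A read lands in the bucket whose index is the 2-bit code of its first k
    bases.  Reads shorter than k are padded with 'A' for bucket assignment
    only; ambiguous bases are likewise assigned code 0 for routing only.
    """
    if k < 0:
        raise ValueError("partition prefix length must be >= 0")
    buckets: list[list[int]] = [[] for _ in range(4**k)]
    for i, seq in enumerate(seqs):
        code = 0
        for t in range(k):
            base = seq[t] if t < len(seq) else "A"
            code = (code << 2) | _PREFIX_CODE.get(base, 0)
        buckets[code].append(i)
    return buckets


def build_unique_set(seqs: Sequence[str], partition_k: int = 0) -> UniqueReadSet:
    """Non-redundify ``seqs`` via 4**partition_k independent prefix trees.

    Concatenating the per-bucket sorted outputs in bucket order reproduces the
    global lexicographic order (buckets are prefix classes), so no merge step
    is needed.  Cross-similarity coefficients are computed on the concatenated
    order, including across bucket boundaries.
    """

    def entries() -> Iterator[tuple[str, int, list[int]]]:
        for bucket in partition_by_prefix(seqs, partition_k):
            tree = PrefixTree()
            for o in bucket:
                tree.insert(seqs[o], o)
            yield from tree.traverse()

    return _assemble(entries())
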