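"""Direct-address k-mer bucket table, bloom bit-vector, masking and lookup."""

import numpy as np
import pytest

from conftest import random_seq
from hexalign.kmer_index import build_index, lookup
from hexalign.sequence_io import Reference, kmer_code


class TestBuild:
    def test_enumerated_buckets(self):
        idx = build_index([Reference("r", "ACGTACGT")], k=4)
        assert idx.bucket(kmer_code("ACGT", 0, 4)) == [(0, 0), (0, 4)]
        assert idx.bucket(kmer_code("CGTA", 0, 4)) == [(0, 1)]
        assert idx.bucket(kmer_code("GTAC", 0, 4)) == [(0, 2)]

    def test_overexpressed_bucket_masked_not_deleted(self):
        idx = build_index([Reference("r", "A" * 100)], k=4, threshold=10)
        code = kmer_code("AAAA", 0, 4)
        assert idx.occupancy(code) == 97  # 100 - 4 + 1 positions, oracle: direct scan
        assert code in idx.masked
        assert idx.bloom_bit(code)  # bloom is set before masking

    def test_empty_bucket_has_zero_bloom_bit(self):
        idx = build_index([Reference("r", "ACGTACGT")], k=4)
        assert not idx.bloom_bit(kmer_code("TTTT", 0, 4))

    def test_k_above_direct_limit_directs_to_double_lookup(self):
        with pytest.raises(ValueError, match="double-lookup"):
            build_index([Reference("r", "ACGT" * 10)], k=15)

    def test_entry_count_formula(self, rng):
        refs = [Reference(f"r{i}", random_seq(rng, n), index_in_set=i) for i, n in enumerate((501, 77, 1200))]
        for p in (1, 2, 3):
            idx = build_index(refs, k=8, step=p)
            expected = sum(-(-(len(r.seq) - 8 + 1) // p) for r in refs)
            assert idx.n_entries == expected

    def test_stored_positions_spell_their_kmer(self, rng):
        ref = Reference("r", random_seq(rng, 400))
        idx = build_index([ref], k=6)
        bases = "ACGT"
        for code, (refs, poss) in idx.buckets.items():
            kmer = "".join(bases[(code >> (2 * (6 - 1 - t))) & 3] for t in range(6))
            for pos in poss.tolist():
                assert ref.seq[pos : pos + 6] == kmer


class TestLookup:
    def test_exact_containment_yields_true_diagonal(self, rng):
        ref = Reference("r", random_seq(rng, 5000))
        idx = build_index([ref], k=14)
        read = ref.seq[1200:1300]
        hits = lookup(idx, read)
        assert any(h.diagonal == 1200 and h.ref == 0 for h in hits)

    def test_absent_bases_never_fetch_buckets(self):
        idx = build_index([Reference("r", "A" * 200)], k=4)
        idx.reset_stats()
        hits = lookup(idx, "T" * 50)
        assert hits == []
        assert idx.stats["bloom_hits"] == 0
        assert idx.stats["bucket_fetches"] == 0

    def test_bloom_miss_implies_empty_bucket(self, rng):
        ref = Reference("r", random_seq(rng, 3000))
        idx = build_index([ref], k=8)
        for code in rng.integers(0, 4**8, size=2000).tolist():
            if not idx.bloom_bit(code):
                assert idx.occupancy(code) == 0

    def test_fetches_bounded_by_bloom_hits(self, rng):
        ref = Reference("r", random_seq(rng, 3000))
        idx = build_index([ref], k=8)
        idx.reset_stats()
        for _ in range(50):
            lookup(idx, random_seq(rng, 60))
        assert idx.stats["bucket_fetches"] <= idx.stats["bloom_hits"]

    def test_completeness_vs_bruteforce(self, rng):
        """Every exact common k-mer (unmasked, step 1) must produce its diagonal."""
        k = 5
        ref = Reference("r", random_seq(rng, 300))
        idx = build_index([ref], k=k, threshold=10**9)
        for _ in range(20):
            read = random_seq(rng, 40)
            expected = set()
            for off in range(len(read) - k + 1):
                kmer = read[off : off + k]
                start = ref.seq.find(kmer)
                while start != -1:
                    expected.add(start - off)
                    start = ref.seq.find(kmer, start + 1)
            got = {h.diagonal for h in lookup(idx, read, max_candidates=10**9)}
            assert got == expected

    def test_masking_monotonicity(self, rng):
        ref = Reference("r", random_seq(rng, 200) + "A" * 40 + random_seq(rng, 200))
        read = ref.seq[190:260]
        low = build_index([ref], k=6, threshold=2)
        high = build_index([ref], k=6, threshold=100)
        hits_low = {(h.ref, h.diagonal) for h in lookup(low, read)}
        hits_high = {(h.ref, h.diagonal) for h in lookup(high, read)}
        assert hits_low <= hits_high

    def test_leftmost_read_offset_kept(self, rng):
        ref = Reference("r", "ACGTACGTACGT")
        idx = build_index([ref], k=4)
        read = "ACGTACGT"
        hits = [h for h in lookup(idx, read) if h.diagonal == 0]
        assert len(hits) == 1 and hits[0].read_offset == 0

    def test_candidate_cap_best_first(self):
        ref = Reference("r", "ACGT" * 300)
        idx = build_index([ref], k=4, threshold=10**9)
        read = "ACGT" * 10
        capped = lookup(idx, read, max_candidates=5)
        assert len(capped) == 5
        full = lookup(idx, read, max_candidates=10**9)
        assert len(full) > 5

    def test_double_lookup_requires_adjacent_seeds(self, rng):
        ref = Reference("r", random_seq(rng, 5000))
        idx = build_index([ref], k=10)
        read = ref.seq[2000:2100]
        hits = lookup(idx, read, double=True)
        assert any(h.diagonal == 2000 for h in hits)
        assert all(h.length == 20 for h in hits)
        # a read whose two half-seeds only ever occur non-adjacently yields nothing
        scrambled = ref.seq[2000:2010] + ref.seq[3000:3010] + random_seq(rng, 20)
        hits2 = lookup(idx, scrambled, double=True)
        assert all(
            ref.seq[h.ref_pos : h.ref_pos + 20] == scrambled[h.read_offset : h.read_offset + 20]
            for h in hits2
        )

    def test_expected_occurrences_scale_as_r_over_4k(self, rng):
        """Mean bucket occupancy on a random reference is ~R/4^K (Poisson)."""
        n = 200_000
        ref = Reference("r", random_seq(rng, n))
        k = 7
        idx = build_index([ref], k=k, threshold=10**9)
        lam = (n - k + 1) / 4**k
        occ = np.array([idx.occupancy(c) for c in rng.integers(0, 4**k, size=4000).tolist()])
        sigma = np.sqrt(lam / len(occ))
        assert abs(occ.mean() - lam) < 3 * sigma * 2  # slack for k-mer overlap correlation
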