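"""Diagonal voting: scan correctness against brute force, candidate promotion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedvote import (ScanCounter, build_query_index, extract_candidates,
                      scan_batch_and_vote, split_database)
from seedvote.seqio import DatabaseBatch
from seedvote.vote import SeedCandidate, VoteTable

from conftest import brute_force_votes, make_record, random_records


def _batch(records, offset=0, index=0):
    return DatabaseBatch(batch_index=index, records=records,
                         total_residues=sum(r.length for r in records),
                         subject_offset=offset)


def _vote_table(buckets, bin_width=16):
    """Build a VoteTable literal from {(q, s, bin): count} (one diagonal per bin)."""
    rows = sorted(buckets)
    qi = np.array([r[0] for r in rows], dtype=np.int32)
    si = np.array([r[1] for r in rows], dtype=np.int32)
    bi = np.array([r[2] for r in rows], dtype=np.int32)
    di = (bi * bin_width).astype(np.int32)
    ct = np.array([buckets[r] for r in rows], dtype=np.int32)
    sp = np.zeros(len(rows), dtype=np.int32)
    return VoteTable(bin_width, int(ct.sum()), qi, si, bi, di, ct, sp, sp.copy())


class TestScanBatchAndVote:
    def test_self_scan_single_diagonal(self):
        """A sequence with no repeated words scanned against itself: every
        shared word sits on diagonal 0."""
        rng = np.random.default_rng(5)
        # rejection-sample a 100-mer with all-distinct 4-mers
        while True:
            rec = random_records(1, 100, 100, seed=int(rng.integers(1 << 30)))[0]
            codes = [tuple(rec.residues[i:i + 4]) for i in range(97)]
            if len(set(codes)) == 97:
                break
        idx = build_query_index([rec], k=4)
        votes = scan_batch_and_vote(idx, _batch([rec]), bin_width=16)
        assert votes.bucket_counts() == {(0, 0, 0): 97}

    def test_subject_shorter_than_k(self):
        idx = build_query_index([make_record("q", "MKVLAC")], k=4)
        votes = scan_batch_and_vote(idx, _batch([make_record("s", "MK")]), 16)
        assert votes.total_votes == 0

    def test_masked_subject_windows_do_not_vote(self):
        rec = make_record("q", "MKVLACDE")
        idx = build_query_index([rec], k=4)
        subj = make_record("s", "MKVLACDE")
        subj.mask[:] = True
        votes = scan_batch_and_vote(idx, _batch([subj]), 16)
        assert votes.total_votes == 0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10 ** 6),
           bin_width=st.sampled_from([1, 4, 16, 64]))
    def test_matches_brute_force_per_bin(self, seed, bin_width):
        queries = random_records(3, 20, 80, seed=seed, prefix="q")
        subjects = random_records(4, 20, 80, seed=seed + 1, prefix="s")
        idx = build_query_index(queries, k=3)
        votes = scan_batch_and_vote(idx, _batch(subjects), bin_width)
        assert votes.bucket_counts() == brute_force_votes(
            queries, subjects, 3, bin_width)

    def test_single_pass_counter(self):
        queries = random_records(2, 40, 60, seed=20, prefix="q")
        subjects = random_records(5, 40, 60, seed=21, prefix="s")
        idx = build_query_index(queries, k=4)
        counter = ScanCounter()
        for batch in split_database(subjects, budget=100):
            scan_batch_and_vote(idx, batch, 16, counter)
        assert counter.reads == {r.id: 1 for r in subjects}
        assert counter.residues == {r.id: r.length for r in subjects}

    def test_batch_additivity(self):
        """Scanning split batches and uniting candidates equals one batch."""
        queries = random_records(3, 30, 90, seed=30, prefix="q")
        subjects = random_records(8, 30, 90, seed=31, prefix="s")
        idx = build_query_index(queries, k=3)
        whole = scan_batch_and_vote(idx, _batch(subjects), 16)
        cands_whole = extract_candidates(whole, 1)
        batches = split_database(subjects, budget=120)
        assert len(batches) > 1
        cands_split = []
        for b in batches:
            cands_split.extend(extract_candidates(
                scan_batch_and_vote(idx, b, 16), 1))
        assert sorted(map(repr, cands_split)) == sorted(map(repr, cands_whole))


class TestExtractCandidates:
    def test_threshold_filters_buckets(self):
        votes = _vote_table({(0, 0, 0): 5, (0, 1, 0): 1, (0, 2, 0): 3})
        cands = extract_candidates(votes, vote_threshold=3)
        assert [c.votes for c in cands] == [5, 3]

    def test_threshold_one_promotes_everything(self):
        buckets = {(0, 0, 0): 5, (0, 1, 0): 1, (1, 2, -3): 2}
        cands = extract_candidates(_vote_table(buckets), vote_threshold=1)
        assert len(cands) == 3
        assert sum(c.votes for c in cands) == sum(buckets.values())

    def test_adjacent_bins_merge(self):
        votes = _vote_table({(0, 0, 0): 2, (0, 0, 1): 2})
        merged = extract_candidates(votes, vote_threshold=3, merge_adjacent=True)
        assert len(merged) == 1 and merged[0].votes == 4
        unmerged = extract_candidates(votes, vote_threshold=3, merge_adjacent=False)
        assert unmerged == []

    def test_non_adjacent_bins_stay_separate(self):
        votes = _vote_table({(0, 0, 0): 2, (0, 0, 5): 2})
        cands = extract_candidates(votes, vote_threshold=1, merge_adjacent=True)
        assert len(cands) == 2

    def test_monotone_in_threshold(self):
        queries = random_records(2, 50, 100, seed=40, prefix="q")
        subjects = random_records(6, 50, 100, seed=41, prefix="s")
        idx = build_query_index(queries, k=3)
        votes = scan_batch_and_vote(idx, _batch(subjects), 16)
        keyed = lambda cs: {(c.query_id, c.subject_id, c.diagonal_bin) for c in cs}
        prev = keyed(extract_candidates(votes, 1))
        for t in (2, 3, 4):
            cur = keyed(extract_candidates(votes, t))
            assert cur <= prev
            prev = cur

    def test_conservation_of_votes(self):
        queries = random_records(2, 50, 100, seed=50, prefix="q")
        subjects = random_records(6, 50, 100, seed=51, prefix="s")
        idx = build_query_index(queries, k=3)
        votes = scan_batch_and_vote(idx, _batch(subjects), 16)
        cands = extract_candidates(votes, 1, merge_adjacent=False)
        assert sum(c.votes for c in cands) == votes.total_votes

    def test_sort_order(self):
        votes = _vote_table({(1, 0, 0): 2, (0, 1, 0): 1, (0, 0, 0): 7, (0, 2, 0): 7})
        cands = extract_candidates(votes, 1)
        order = [(c.query_id, c.votes, c.subject_id) for c in cands]
        assert order == [(0, 7, 0), (0, 7, 2), (0, 1, 1), (1, 2, 0)]

    def test_representative_diagonal_is_modal(self):
        q = make_record("q", "MKVLMKVLWWCC")
        s = make_record("s", "MKVLAAAAWWCC")  # shared 4-mers on several diagonals
        idx = build_query_index([q], k=4)
        votes = scan_batch_and_vote(idx, _batch([s]), bin_width=64)
        (cand,) = extract_candidates(votes, 1)
        counts = {}
        for d, c in zip(votes.diagonals, votes.counts):
            counts[int(d)] = counts.get(int(d), 0) + int(c)
        best = max(sorted(counts), key=lambda d: counts[d])
        assert cand.representative_diagonal == best

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            extract_candidates(_vote_table({}), 0)
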