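"""Seed-and-vote scan of a database batch.

Every ambiguity-free, unmasked k-window of the database is looked up in the
query index exactly once (the batch is traversed in a single pass). Each
posting returned is one *vote* on the diagonal bin of the (query, subject)
pair: with diagonal d = subject_pos - query_pos, votes accumulate at
floor(d / bin_width). Bins collect the hits of one prospective HSP —
binning tolerates the diagonal drift caused by small indels — and a bin is
promoted to a :class:`SeedCandidate` once its votes reach the vote
threshold (the P0 of the search configuration; P0 = 1 keeps every hit and
is the most sensitive mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .kmer_index import KmerIndex, window_codes
from .seqio import DatabaseBatch


class ScanCounter:
    """Instrumentation hook: records how often each subject is consumed.

    The single-pass guarantee is testable: after a search, every database
    record id maps to exactly one consumption of exactly its length.
    """

    def __init__(self) -> None:
        self.reads: Dict[str, int] = {}
        self.residues: Dict[str, int] = {}

    def consume(self, record_id: str, n_residues: int) -> None:
        self.reads[record_id] = self.reads.get(record_id, 0) + 1
        self.residues[record_id] = self.residues.get(record_id, 0) + n_residues


@dataclass
class VoteTable:
    """Sparse accumulator of k-mer hits, one row per (query, subject, bin, diagonal).

    Rows are aggregated at exact-diagonal granularity so candidates can carry
    a modal diagonal and a seed span; bin-level vote counts are sums over the
    rows of one (query, subject, bin) bucket. Rows are sorted by
    (query_id, subject_id, bin, diagonal).
    """

    bin_width: int
    n_windows: int           # valid database windows looked up during the scan
    query_ids: np.ndarray    # int32
    subject_ids: np.ndarray  # int32 (global database index)
    bins: np.ndarray         # int32
    diagonals: np.ndarray    # int32, exact diagonal s_pos - q_pos
    counts: np.ndarray       # int32, hits on that exact diagonal
    s_min: np.ndarray        # int32, smallest contributing subject window start
    s_max: np.ndarray        # int32, largest contributing subject window start

    @property
    def total_votes(self) -> int:
        return int(self.counts.sum())

    def bucket_counts(self) -> Dict[Tuple[int, int, int], int]:
        """Vote count per (query_id, subject_id, diagonal_bin) bucket."""
        out: Dict[Tuple[int, int, int], int] = {}
        for q, s, b, c in zip(self.query_ids, self.subject_ids, self.bins, self.counts):
            key = (int(q), int(s), int(b))
            out[key] = out.get(key, 0) + int(c)
        return out


@dataclass(slots=True)
class SeedCandidate:
    """A thresholded vote bucket, ready for banded alignment."""

    query_id: int
    subject_id: int
    diagonal_bin: int
    votes: int
    representative_diagonal: int  # modal exact diagonal among the hits
    seed_span: Tuple[int, int]    # min/max subject window starts of the hits


def scan_batch_and_vote(index: KmerIndex, batch: DatabaseBatch, bin_width: int,
                        counter: Optional[ScanCounter] = None) -> VoteTable:
    """Single-pass scan of one batch against the query index.

    Each subject's residues are read once, windows are looked up in the
    index, and one vote per (window, posting) hit lands in the diagonal-bin
    accumulator. Subject ids are global database indices
    (``batch.subject_offset`` + position in batch), so tables from distinct
    batches never share keys.
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    k = index.k

    parts: List[Tuple[np.ndarray, ...]] = []
    n_windows = 0
    for local, rec in enumerate(batch.records):
        if counter is not None:
            counter.consume(rec.id, rec.length)
        codes, valid = window_codes(rec.residues, rec.mask, k)
        pos = np.nonzero(valid)[0].astype(np.int32)
        n_windows += len(pos)
        if len(pos) == 0:
            continue
        c = codes[pos]
        starts = index.offsets[c]
        cnt = (index.offsets[c + 1] - starts).astype(np.int64)
        total = int(cnt.sum())
        if total == 0:
            continue
        # expand each window to its postings run
        rep = np.repeat(np.arange(len(c)), cnt)
        base = np.repeat(starts, cnt)
        within = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        posting_idx = base + within
        qids = index.query_ids[posting_idx]
        qpos = index.query_pos[posting_idx]
        spos = pos[rep]
        diag = spos.astype(np.int32) - qpos.astype(np.int32)
        bins = np.floor_divide(diag, bin_width).astype(np.int32)

        # aggregate per (query, diagonal) — subject is fixed in this loop
        order = np.lexsort((diag, qids))
        qids, diag, bins, spos = qids[order], diag[order], bins[order], spos[order]
        newgrp = np.empty(total, dtype=bool)
        newgrp[0] = True
        newgrp[1:] = (qids[1:] != qids[:-1]) | (diag[1:] != diag[:-1])
        bounds = np.nonzero(newgrp)[0]
        counts = np.diff(np.append(bounds, total)).astype(np.int32)
        smin = np.minimum.reduceat(spos, bounds).astype(np.int32)
        smax = np.maximum.reduceat(spos, bounds).astype(np.int32)
        sid = np.full(len(bounds), batch.subject_offset + local, dtype=np.int32)
        parts.append((qids[bounds].astype(np.int32), sid, bins[bounds],
                      diag[bounds], counts, smin, smax))

    if not parts:
        empty = np.empty(0, dtype=np.int32)
        return VoteTable(bin_width, n_windows, empty, empty.copy(), empty.copy(),
                         empty.copy(), empty.copy(), empty.copy(), empty.copy())

    cols = [np.concatenate([p[i] for p in parts]) for i in range(7)]
    qi, si, bi, di, ct, mn, mx = cols
    order = np.lexsort((di, bi, si, qi))
    return VoteTable(bin_width, n_windows, qi[order], si[order], bi[order], di[order],
                     ct[order], mn[order], mx[order])


def extract_candidates(votes: VoteTable, vote_threshold: int,
                       merge_adjacent: bool = True) -> List[SeedCandidate]:
    """Promote vote buckets with at least ``vote_threshold`` votes.

    With ``merge_adjacent``, buckets occupying consecutive bins of the same
    (query, subject) pair are merged first (votes summed, modal diagonal
    recomputed over the union), so one HSP straddling a bin boundary is not
    split or double-counted. Output order: query_id asc, votes desc,
    subject_id asc, diagonal_bin asc.
    """
    if vote_threshold < 1:
        raise ValueError(f"vote_threshold must be >= 1, got {vote_threshold}")
    n = len(votes.query_ids)
    if n == 0:
        return []
    qi, si, bi = votes.query_ids, votes.subject_ids, votes.bins
    di, ct = votes.diagonals, votes.counts
    mn, mx = votes.s_min, votes.s_max

    # group boundaries: new candidate group when (q, s) changes or the bin
    # jumps by more than the merge distance (1 if merging, 0 otherwise).
    gap = 1 if merge_adjacent else 0
    new = np.empty(n, dtype=bool)
    new[0] = True
    new[1:] = ((qi[1:] != qi[:-1]) | (si[1:] != si[:-1])
               | (bi[1:] - bi[:-1] > gap))
    bounds = np.nonzero(new)[0]
    ends = np.append(bounds[1:], n)

    out: List[SeedCandidate] = []
    for lo, hi in zip(bounds, ends):
        total = int(ct[lo:hi].sum())
        if total < vote_threshold:
            continue
        seg_ct = ct[lo:hi]
        seg_di = di[lo:hi]
        # modal diagonal: highest count, ties to the smallest diagonal;
        # rows are diagonal-sorted within the group, argmax takes the first.
        best = int(np.argmax(seg_ct))
        modal = int(seg_di[best])
        out.append(SeedCandidate(
            query_id=int(qi[lo]),
            subject_id=int(si[lo]),
            diagonal_bin=int(np.floor_divide(modal, votes.bin_width)),
            votes=total,
            representative_diagonal=modal,
            seed_span=(int(mn[lo:hi].min()), int(mx[lo:hi].max())),
        ))
    out.sort(key=lambda c: (c.query_id, -c.votes, c.subject_id, c.diagonal_bin))
    return out
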