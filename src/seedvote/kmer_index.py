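"""Query-side k-mer index.

The database is never indexed: only the queries are, so the table size is a
function of the query set alone and stays constant however large the
database grows. Keys are base-20 codes of the k canonical-residue ordinals;
windows touching a masked or ambiguous residue produce no posting.

Layout is the classic offsets-plus-postings CSR: ``offsets`` has 20**k + 1
entries and ``postings`` rows are (query_id, query_pos) pairs sorted by code
then (query_id, query_pos), so lookup is two array reads and a slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .alphabet import EXCLUDED
from .seqio import SequenceRecord

MIN_K = 2
MAX_K = 7


def window_codes(residues: np.ndarray, mask: np.ndarray, k: int
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Base-20 codes and validity flags for every length-k window.

    Returns ``(codes, valid)`` of length ``len(residues) - k + 1`` (empty if
    the sequence is shorter than k). A window is valid iff every residue in
    it is canonical and unmasked; invalid windows carry code 0 and must be
    ignored by callers.
    """
    n = len(residues)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    ok = (residues < EXCLUDED) & ~mask
    vals = np.where(ok, residues, 0).astype(np.int64)
    win_vals = np.lib.stride_tricks.sliding_window_view(vals, k)
    win_ok = np.lib.stride_tricks.sliding_window_view(ok, k)
    powers = 20 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win_vals @ powers
    valid = win_ok.all(axis=1)
    codes[~valid] = 0
    return codes, valid


def encode_kmer(word: str) -> int:
    """Base-20 code of a canonical k-mer string (helper for tests/CLI)."""
    from .alphabet import encode

    ords = encode(word)
    if (ords >= EXCLUDED).any():
        raise ValueError(f"k-mer {word!r} contains a non-canonical residue")
    code = 0
    for o in ords:
        code = code * 20 + int(o)
    return code


@dataclass
class KmerIndex:
    """CSR table from k-mer code to (query_id, query_pos) postings."""

    k: int
    offsets: np.ndarray       # int64, length 20**k + 1, non-decreasing
    query_ids: np.ndarray     # int32, postings: index into the query list
    query_pos: np.ndarray     # int32, postings: 0-based window start

    @property
    def key_space(self) -> int:
        return 20 ** self.k

    @property
    def n_postings(self) -> int:
        return len(self.query_ids)

    def lookup(self, code: int) -> Tuple[np.ndarray, np.ndarray]:
        """Postings run for ``code``: (query_ids slice, query_pos slice).

        Constant-time addressing through the offsets table; an absent code
        yields two empty slices.
        """
        if not 0 <= code < self.key_space:
            raise ValueError(f"k-mer code {code} out of range [0, {self.key_space})")
        lo, hi = self.offsets[code], self.offsets[code + 1]
        return self.query_ids[lo:hi], self.query_pos[lo:hi]


def build_query_index(queries: Sequence[SequenceRecord], k: int) -> KmerIndex:
    """Index every ambiguity-free, unmasked k-window of every query.

    Deterministic: same queries, same bits. A fully masked query set yields
    an index with zero postings (with a warning), not an error.
    """
    if not MIN_K <= k <= MAX_K:
        raise ValueError(f"word size k must be in [{MIN_K}, {MAX_K}], got {k}")
    if not queries:
        raise ValueError("query set must be non-empty")

    all_codes, all_qids, all_qpos = [], [], []
    for qid, rec in enumerate(queries):
        codes, valid = window_codes(rec.residues, rec.mask, k)
        idx = np.nonzero(valid)[0]
        all_codes.append(codes[idx])
        all_qids.append(np.full(len(idx), qid, dtype=np.int32))
        all_qpos.append(idx.astype(np.int32))

    codes = np.concatenate(all_codes) if all_codes else np.empty(0, dtype=np.int64)
    qids = np.concatenate(all_qids) if all_qids else np.empty(0, dtype=np.int32)
    qpos = np.concatenate(all_qpos) if all_qpos else np.empty(0, dtype=np.int32)

    if len(codes) == 0:
        warnings.warn("query index has zero postings (all windows masked or ambiguous)")

    # sort by (code, query_id, query_pos); input is already (query_id, pos)
    # ordered, so a stable sort on code alone gives the full ordering.
    order = np.argsort(codes, kind="stable")
    codes, qids, qpos = codes[order], qids[order], qpos[order]

    key_space = 20 ** k
    counts = np.bincount(codes, minlength=key_space)
    offsets = np.zeros(key_space + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    return KmerIndex(k=k, offsets=offsets, query_ids=qids, query_pos=qpos)


def lookup_kmer(index: KmerIndex, code: int) -> Tuple[np.ndarray, np.ndarray]:
    """Functional alias for :meth:`KmerIndex.lookup`."""
    return index.lookup(code)
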