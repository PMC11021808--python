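"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorized code paths:
k-mer windows are enumerated with nested Python loops and diagonal votes
are counted in plain dictionaries, so they can arbitrate the CSR index and
the batched scan kernel.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from seedvote import ScoringScheme, SequenceRecord
from seedvote.alphabet import CANONICAL, EXCLUDED


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


def make_record(rec_id: str, seq: str, mask=None) -> SequenceRecord:
    from seedvote.seqio import record_from_string

    rec = record_from_string(rec_id, seq)
    if mask is not None:
        rec.mask[:] = mask
    return rec


def random_records(n: int, lo: int, hi: int, seed: int,
                   prefix: str = "r") -> List[SequenceRecord]:
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        residues = rng.integers(0, 20, size=length).astype(np.uint8)
        out.append(SequenceRecord(id=f"{prefix}{i}", description="", residues=residues))
    return out


# ---------------------------------------------------------------- oracles

def enumerate_windows(record: SequenceRecord, k: int) -> List[Tuple[int, int]]:
    """(code, position) for every valid k-window, by direct enumeration."""
    out = []
    for start in range(record.length - k + 1):
        code = 0
        ok = True
        for j in range(start, start + k):
            o = int(record.residues[j])
            if o >= EXCLUDED or record.mask[j]:
                ok = False
                break
            code = code * 20 + o
        if ok:
            out.append((code, start))
    return out


def brute_force_votes(queries: Sequence[SequenceRecord],
                      subjects: Sequence[SequenceRecord], k: int,
                      bin_width: int, subject_offset: int = 0
                      ) -> Dict[Tuple[int, int, int], int]:
    """Shared-k-mer counts per (query, subject, diagonal bin), by brute force."""
    votes: Dict[Tuple[int, int, int], int] = {}
    for sid, subj in enumerate(subjects):
        subj_windows = enumerate_windows(subj, k)
        for qid, query in enumerate(queries):
            by_code: Dict[int, List[int]] = {}
            for code, pos in enumerate_windows(query, k):
                by_code.setdefault(code, []).append(pos)
            for code, s_pos in subj_windows:
                for q_pos in by_code.get(code, ()):
                    key = (qid, subject_offset + sid,
                           (s_pos - q_pos) // bin_width)
                    votes[key] = votes.get(key, 0) + 1
    return votes


def blosum62_pair_score(a: str, b: str) -> int:
    """BLOSUM62 entry straight from Biopython (independent of seedvote.scoring)."""
    from Bio.Align import substitution_matrices

    return int(substitution_matrices.load("BLOSUM62")[a, b])
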