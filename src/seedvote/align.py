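"""Banded Smith-Waterman resolution of seed candidates.

Each promoted candidate is resolved by an affine-gap (Gotoh, three-matrix)
local alignment restricted to a band of diagonals around the candidate's
representative diagonal: only cells with |(s_pos - q_pos) - center| <=
band_width are computed, so cost is O(band_width * subject_span) rather
than O(m * n). A full-matrix implementation with the identical scoring and
tie-breaking contract (:func:`reference_smith_waterman`) serves as the
testing oracle: whenever the optimum path fits in the band the two agree
exactly.

Tie-breaking is deterministic throughout: traceback prefers a diagonal move,
then a gap in the subject string, then a gap in the query string; among
equal-scoring end cells the smallest subject position wins, then the
smallest query position.

Gap convention (BLAST-style): a gap of length L costs gap_open + L * gap_extend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numba import njit

from .alphabet import decode
from .scoring import ScoringScheme
from .seqio import SequenceRecord

NEG = -(10 ** 12)  # effectively -inf for int64 DP

OP_DIAG = 0   # consume one residue of each
OP_VGAP = 1   # gap in subject string (consumes query)
OP_HGAP = 2   # gap in query string (consumes subject)


@dataclass
class AlignmentResult:
    """One resolved HSP.

    Coordinates are 0-based half-open; :func:`seedvote.seqio.tabular_line`
    converts to 1-based inclusive at the output boundary. ``bit_score`` and
    ``evalue`` are filled by the statistics stage.
    """

    query_id: str
    subject_id: str
    raw_score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aligned_query: str
    aligned_subject: str
    bit_score: float = 0.0
    evalue: float = float("inf")
    identity_pct: float = 0.0
    align_length: int = 0
    mismatches: int = 0
    gap_opens: int = 0
    query_coverage: float = 0.0


@njit(cache=True)
def _banded_score(q, s, center, w, mat, go, ge):  # pragma: no cover
    """Score-only banded Gotoh; returns (best, end_i, end_j).

    Rolling two-row storage; band index b in [1, 2w+1] maps to
    j = i + center - w + (b - 1) with one padding cell on each side.
    """
    m, n = q.shape[0], s.shape[0]
    W = 2 * w + 1
    Hp = np.full(W + 2, NEG, np.int64)  # previous row
    Fp = np.full(W + 2, NEG, np.int64)
    Hc = np.full(W + 2, NEG, np.int64)
    Fc = np.full(W + 2, NEG, np.int64)
    Ec = np.full(W + 2, NEG, np.int64)

    for b in range(1, W + 1):
        j = center - w + (b - 1)
        Hp[b] = 0 if 0 <= j <= n else NEG
    best = 0
    best_i = 0
    best_j = 0
    for i in range(1, m + 1):
        for b in range(W + 2):
            Hc[b] = NEG
            Fc[b] = NEG
            Ec[b] = NEG
        for b in range(1, W + 1):
            j = i + center - w + (b - 1)
            if j < 0 or j > n:
                continue
            if j == 0:
                Hc[b] = 0
                continue
            e = Hc[b - 1] - go - ge
            if Ec[b - 1] - ge > e:
                e = Ec[b - 1] - ge
            f = Hp[b + 1] - go - ge
            if Fp[b + 1] - ge > f:
                f = Fp[b + 1] - ge
            h = Hp[b] + mat[q[i - 1], s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hc[b] = h
            Ec[b] = e
            Fc[b] = f
            if h > best or (h == best and h > 0 and
                            (j < best_j or (j == best_j and i < best_i))):
                best = h
                best_i = i
                best_j = j
        Hp, Hc = Hc, Hp
        Fp, Fc = Fc, Fp
    return best, best_i, best_j


@njit(cache=True)
def _banded_fill(q, s, center, w, mat, go, ge):  # pragma: no cover
    """Full banded Gotoh fill; returns (H, E, F, best, end_i, end_j)."""
    m, n = q.shape[0], s.shape[0]
    W = 2 * w + 1
    H = np.full((m + 1, W + 2), NEG, np.int64)
    E = np.full((m + 1, W + 2), NEG, np.int64)
    F = np.full((m + 1, W + 2), NEG, np.int64)
    for b in range(1, W + 1):
        j = center - w + (b - 1)
        if 0 <= j <= n:
            H[0, b] = 0
    best = 0
    best_i = 0
    best_j = 0
    for i in range(1, m + 1):
        for b in range(1, W + 1):
            j = i + center - w + (b - 1)
            if j < 0 or j > n:
                continue
            if j == 0:
                H[i, b] = 0
                continue
            e = H[i, b - 1] - go - ge
            if E[i, b - 1] - ge > e:
                e = E[i, b - 1] - ge
            f = H[i - 1, b + 1] - go - ge
            if F[i - 1, b + 1] - ge > f:
                f = F[i - 1, b + 1] - ge
            h = H[i - 1, b] + mat[q[i - 1], s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, b] = h
            E[i, b] = e
            F[i, b] = f
            if h > best or (h == best and h > 0 and
                            (j < best_j or (j == best_j and i < best_i))):
                best = h
                best_i = i
                best_j = j
    return H, E, F, best, best_i, best_j


def _traceback_banded(q, s, center, w, mat, go, ge, H, E, F, end_i, end_j):
    """Recover the optimal path from the banded matrices.

    Move preference: diagonal, then gap-in-subject (vertical), then
    gap-in-query (horizontal); inside a gap, closing it beats extending.
    """
    ops = []
    i, j = end_i, end_j
    state = 0  # 0=H, 1=E (horizontal), 2=F (vertical)
    while True:
        b = j - i - center + w + 1
        if state == 0:
            h = H[i, b]
            if h == 0:
                break
            if i >= 1 and j >= 1 and h == H[i - 1, b] + mat[q[i - 1], s[j - 1]]:
                ops.append(OP_DIAG)
                i -= 1
                j -= 1
            elif h == F[i, b]:
                state = 2
            elif h == E[i, b]:
                state = 1
            else:  # unreachable under a correct fill
                raise AssertionError("banded traceback lost its path")
        elif state == 2:  # vertical: consume query, gap in subject
            f = F[i, b]
            ops.append(OP_VGAP)
            if f == H[i - 1, b + 1] - go - ge:
                state = 0
            i -= 1
        else:  # horizontal: consume subject, gap in query
            e = E[i, b]
            ops.append(OP_HGAP)
            if e == H[i, b - 1] - go - ge:
                state = 0
            j -= 1
    ops.reverse()
    return ops, i, j


def _result_from_ops(query: SequenceRecord, subject: SequenceRecord,
                     ops, q_start: int, s_start: int,
                     end_i: int, end_j: int, raw: int) -> AlignmentResult:
    aq, asub = [], []
    qi, sj = q_start, s_start
    qstr = decode(query.residues)
    sstr = decode(subject.residues)
    for op in ops:
        if op == OP_DIAG:
            aq.append(qstr[qi])
            asub.append(sstr[sj])
            qi += 1
            sj += 1
        elif op == OP_VGAP:
            aq.append(qstr[qi])
            asub.append("-")
            qi += 1
        else:
            aq.append("-")
            asub.append(sstr[sj])
            sj += 1
    result = AlignmentResult(
        query_id=query.id, subject_id=subject.id, raw_score=int(raw),
        q_start=q_start, q_end=end_i, s_start=s_start, s_end=end_j,
        aligned_query="".join(aq), aligned_subject="".join(asub),
    )
    return alignment_statistics(result, query.length)


def banded_raw_score(query: SequenceRecord, subject: SequenceRecord,
                     center_diagonal: int, band_width: int,
                     scheme: ScoringScheme) -> int:
    """Best local score inside the band (no traceback); 0 if none positive."""
    if band_width < 1:
        raise ValueError("band_width must be >= 1")
    best, _, _ = _banded_score(
        query.residues.astype(np.int64), subject.residues.astype(np.int64),
        center_diagonal, band_width, scheme.matrix.astype(np.int64),
        scheme.gap_open, scheme.gap_extend)
    return int(best)


def banded_smith_waterman(query: SequenceRecord, subject: SequenceRecord,
                          center_diagonal: int, band_width: int,
                          scheme: ScoringScheme) -> Optional[AlignmentResult]:
    """Affine-gap local alignment restricted to the band; None if score <= 0."""
    if band_width < 1:
        raise ValueError("band_width must be >= 1")
    qa = query.residues.astype(np.int64)
    sa = subject.residues.astype(np.int64)
    mat = scheme.matrix.astype(np.int64)
    H, E, F, best, ei, ej = _banded_fill(qa, sa, center_diagonal, band_width,
                                         mat, scheme.gap_open, scheme.gap_extend)
    if best <= 0:
        return None
    ops, qs, ss = _traceback_banded(qa, sa, center_diagonal, band_width, mat,
                                    scheme.gap_open, scheme.gap_extend,
                                    H, E, F, ei, ej)
    return _result_from_ops(query, subject, ops, qs, ss, ei, ej, best)


def reference_smith_waterman(query: SequenceRecord, subject: SequenceRecord,
                             scheme: ScoringScheme) -> Optional[AlignmentResult]:
    """Full-matrix Gotoh local alignment: the unbanded testing oracle.

    Written as the straightforward textbook dynamic programme, independent
    of the banded code path, with the identical scoring and tie-breaking
    contract.
    """
    m, n = query.length, subject.length
    q, s = query.residues, subject.residues
    mat = scheme.matrix
    go, ge = scheme.gap_open, scheme.gap_extend

    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        row_q = q[i - 1]
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - go - ge, E[i, j - 1] - ge)
            f = max(H[i - 1, j] - go - ge, F[i - 1, j] - ge)
            h = max(0, H[i - 1, j - 1] + mat[row_q, s[j - 1]], e, f)
            H[i, j], E[i, j], F[i, j] = h, e, f
            if h > best or (h == best and h > 0 and
                            (j < bj or (j == bj and i < bi))):
                best, bi, bj = h, i, j
    if best <= 0:
        return None

    ops = []
    i, j, state = bi, bj, 0
    while True:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if i >= 1 and j >= 1 and h == H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]:
                ops.append(OP_DIAG)
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 2
            elif h == E[i, j]:
                state = 1
            else:
                raise AssertionError("reference traceback lost its path")
        elif state == 2:
            ops.append(OP_VGAP)
            if F[i, j] == H[i - 1, j] - go - ge:
                state = 0
            i -= 1
        else:
            ops.append(OP_HGAP)
            if E[i, j] == H[i, j - 1] - go - ge:
                state = 0
            j -= 1
    ops.reverse()
    return _result_from_ops(query, subject, ops, i, j, bi, bj, best)


def alignment_statistics(result: AlignmentResult, query_length: int) -> AlignmentResult:
    """Fill identity, mismatch, gap and coverage fields from the gapped strings.

    identity_pct = 100 * identical columns / alignment length; gap_opens
    counts maximal gap runs in either string; query_coverage is the aligned
    query span over the query length (a hit "covers half the query" at
    coverage >= 0.5).
    """
    aq, asub = result.aligned_query, result.aligned_subject
    if len(aq) != len(asub):
        raise ValueError("gapped strings must have equal length")
    length = len(aq)
    matches = mismatches = 0
    gap_opens = 0
    in_gap = False
    for a, b in zip(aq, asub):
        if a == "-" or b == "-":
            if not in_gap:
                gap_opens += 1
                in_gap = True
        else:
            in_gap = False
            if a == b:
                matches += 1
            else:
                mismatches += 1
    result.align_length = length
    result.mismatches = mismatches
    result.gap_opens = gap_opens
    result.identity_pct = 100.0 * matches / length if length else 0.0
    result.query_coverage = ((result.q_end - result.q_start) / query_length
                             if query_length else 0.0)
    return result


def rescore_alignment(result: AlignmentResult, scheme: ScoringScheme,
                      query: SequenceRecord, subject: SequenceRecord) -> int:
    """Re-score the traceback column by column (test utility).

    Diagonal columns score through the matrix; each maximal gap run costs
    gap_open + run_length * gap_extend. Equals raw_score for any alignment
    the DP produced.
    """
    score = 0
    qi, sj = result.q_start, result.s_start
    prev_gap = None  # which string held the previous gap column
    for a, b in zip(result.aligned_query, result.aligned_subject):
        if a == "-":
            score -= scheme.gap_extend + (scheme.gap_open if prev_gap != "q" else 0)
            prev_gap = "q"
            sj += 1
        elif b == "-":
            score -= scheme.gap_extend + (scheme.gap_open if prev_gap != "s" else 0)
            prev_gap = "s"
            qi += 1
        else:
            score += int(scheme.matrix[query.residues[qi], subject.residues[sj]])
            prev_gap = None
            qi += 1
            sj += 1
    return score


def dedup_overlapping(results, min_overlap: float = 0.5):
    """Drop HSPs of one (query, subject) pair whose subject spans overlap.

    Results must share query and subject. Keeps the higher raw score when
    two spans overlap by at least ``min_overlap`` of the shorter span;
    ties keep the earlier subject start.
    """
    kept: list[AlignmentResult] = []
    for cand in sorted(results, key=lambda r: (-r.raw_score, r.s_start, r.q_start)):
        redundant = False
        for k in kept:
            lo = max(cand.s_start, k.s_start)
            hi = min(cand.s_end, k.s_end)
            shorter = min(cand.s_end - cand.s_start, k.s_end - k.s_start)
            if shorter > 0 and (hi - lo) / shorter >= min_overlap:
                redundant = True
                break
        if not redundant:
            kept.append(cand)
    kept.sort(key=lambda r: (r.s_start, r.q_start))
    return kept
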