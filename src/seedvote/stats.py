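"""Karlin-Altschul statistics: bit scores, E-values, hit filtering/ranking.

bits = (lambda * raw - ln K) / ln 2 and E = m * n * 2**(-bits), with m the
query length and n the total residue count of the *full* database (summed
over every batch before scanning), so E-values do not depend on how the
database was batched. No effective-length (edge) correction is applied; the
raw search-space product is used.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence

from .align import AlignmentResult
from .scoring import ScoringScheme


def bit_score(raw: float, scheme: ScoringScheme) -> float:
    """Normalized score in bits: (lambda * raw - ln K) / ln 2.

    Defined for any real raw score (zero bits at raw = ln(K)/lambda, which is
    negative); HSPs reaching this stage always carry a positive raw score.
    """
    return (scheme.lam * raw - math.log(scheme.K)) / math.log(2.0)


def expect_value(bits: float, query_length: int, database_residues: int) -> float:
    """Expected chance hits at this bit score: E = m * n * 2**(-bits)."""
    if query_length <= 0 or database_residues <= 0:
        raise ValueError("query_length and database_residues must be positive")
    return query_length * database_residues * math.pow(2.0, -bits)


def attach_statistics(hits: Sequence[AlignmentResult], scheme: ScoringScheme,
                      query_lengths: Dict[str, int],
                      database_residues: int) -> None:
    """Fill bit_score and evalue on each hit in place."""
    for hit in hits:
        hit.bit_score = bit_score(hit.raw_score, scheme)
        hit.evalue = expect_value(hit.bit_score, query_lengths[hit.query_id],
                                  database_residues)


def min_raw_score(evalue_cutoff: float, query_length: int,
                  database_residues: int, scheme: ScoringScheme) -> int:
    """Smallest integer raw score whose E-value passes the cutoff.

    Exact inversion of the E-value formula; used to skip tracebacks for
    alignments that cannot be reported. E is strictly decreasing in the raw
    score, so this prefilter never changes the reported hit set.
    """
    # E <= cutoff  <=>  bits >= log2(m n / cutoff)  <=>  raw >= (...)
    bits_needed = math.log2(query_length * database_residues / evalue_cutoff)
    raw = (bits_needed * math.log(2.0) + math.log(scheme.K)) / scheme.lam
    return max(0, math.ceil(raw - 1e-9))


def filter_and_rank_hits(hits: Sequence[AlignmentResult], evalue_cutoff: float,
                         max_target_seqs: int,
                         query_order: Sequence[str]) -> List[AlignmentResult]:
    """E-value filter, deterministic ranking, per-query subject cap.

    Hits with E <= cutoff are grouped by query in query input order; within
    a query they sort by (E asc, bits desc, subject_id asc, coordinates);
    at most ``max_target_seqs`` distinct subjects are kept per query.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    if max_target_seqs < 1:
        raise ValueError("max_target_seqs must be >= 1")
    by_query: Dict[str, List[AlignmentResult]] = {}
    for hit in hits:
        if hit.evalue <= evalue_cutoff:
            by_query.setdefault(hit.query_id, []).append(hit)

    out: List[AlignmentResult] = []
    for qid in query_order:
        group = by_query.get(qid, [])
        group.sort(key=lambda h: (h.evalue, -h.bit_score, h.subject_id,
                                  h.q_start, h.s_start))
        subjects_seen: Dict[str, bool] = {}
        for hit in group:
            if hit.subject_id not in subjects_seen:
                if len(subjects_seen) >= max_target_seqs:
                    continue
                subjects_seen[hit.subject_id] = True
            out.append(hit)
    return out
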