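"""Banded and full Smith-Waterman: scores, tracebacks, statistics."""

import numpy as np
import pytest

from seedvote import (ScoringScheme, alignment_statistics, banded_smith_waterman,
                      reference_smith_waterman)
from seedvote.align import AlignmentResult, banded_raw_score, dedup_overlapping, rescore_alignment

from conftest import blosum62_pair_score, make_record, random_records

WIDE = 500  # band half-width covering any test matrix entirely


class TestBandedSmithWaterman:
    def test_exact_match_scores_sum_of_diagonal(self, scheme):
        q = make_record("q", "MKVL")
        s = make_record("s", "MKVL")
        res = banded_smith_waterman(q, s, 0, WIDE, scheme)
        expected = sum(blosum62_pair_score(c, c) for c in "MKVL")
        assert res.raw_score == expected
        assert res.identity_pct == 100.0
        assert res.aligned_query == "MKVL" == res.aligned_subject

    def test_band_excluding_optimum_returns_none(self, scheme):
        q = make_record("q", "MKVLWCDE")
        s = make_record("s", "AAAAAAAAAAMKVLWCDE")
        # optimum sits on diagonal +10; a narrow band at diagonal -40 misses it
        assert banded_smith_waterman(q, s, -40, 2, scheme) is None

    def test_band_monotone_in_width(self, scheme):
        q, s = random_records(2, 60, 60, seed=60)
        scores = [banded_raw_score(q, s, 0, w, scheme) for w in (1, 4, 8, 20, 60)]
        assert scores == sorted(scores)
        full = reference_smith_waterman(q, s, scheme)
        assert scores[-1] <= (full.raw_score if full else 0)

    def test_oracle_equivalence_random_pairs(self, scheme):
        """Full-band banded alignment equals the unbanded oracle exactly."""
        rng = np.random.default_rng(61)
        for trial in range(30):
            q, s = random_records(2, 10, 80, seed=int(rng.integers(1 << 30)))
            ref = reference_smith_waterman(q, s, scheme)
            band = banded_smith_waterman(q, s, 0, 100, scheme)
            if ref is None:
                assert band is None
            else:
                assert band.raw_score == ref.raw_score
                assert (band.q_start, band.q_end, band.s_start, band.s_end) == \
                    (ref.q_start, ref.q_end, ref.s_start, ref.s_end)

    def test_traceback_rescores_to_raw(self, scheme):
        rng = np.random.default_rng(62)
        for trial in range(20):
            q, s = random_records(2, 20, 80, seed=int(rng.integers(1 << 30)))
            res = banded_smith_waterman(q, s, 0, 100, scheme)
            if res is not None:
                assert rescore_alignment(res, scheme, q, s) == res.raw_score

    def test_ungapping_reproduces_spans(self, scheme):
        q, s = random_records(2, 40, 80, seed=63)
        res = banded_smith_waterman(q, s, 0, 100, scheme)
        assert res is not None
        assert len(res.aligned_query) == len(res.aligned_subject)
        assert len(res.aligned_query.replace("-", "")) == res.q_end - res.q_start
        assert len(res.aligned_subject.replace("-", "")) == res.s_end - res.s_start

    def test_self_alignment_full_identity(self, scheme):
        (rec,) = random_records(1, 120, 120, seed=64)
        res = banded_smith_waterman(rec, rec, 0, 16, scheme)
        assert res.identity_pct == 100.0
        assert res.query_coverage == 1.0
        assert res.gap_opens == 0

    def test_bad_band_width(self, scheme):
        q, s = random_records(2, 10, 10, seed=65)
        with pytest.raises(ValueError):
            banded_smith_waterman(q, s, 0, 0, scheme)


class TestReferenceSmithWaterman:
    def test_single_identical_residue(self, scheme):
        res = reference_smith_waterman(make_record("q", "A"), make_record("s", "A"), scheme)
        assert res.raw_score == blosum62_pair_score("A", "A") > 0

    def test_negative_pair_gives_none(self, scheme):
        # BLOSUM62(A, P) < 0, so no positive-scoring local path exists
        assert blosum62_pair_score("A", "P") < 0
        assert reference_smith_waterman(make_record("q", "A"), make_record("s", "P"),
                                        scheme) is None

    def test_score_symmetry(self, scheme):
        rng = np.random.default_rng(66)
        for trial in range(10):
            a, b = random_records(2, 15, 50, seed=int(rng.integers(1 << 30)))
            ra = reference_smith_waterman(a, b, scheme)
            rb = reference_smith_waterman(b, a, scheme)
            assert (ra.raw_score if ra else 0) == (rb.raw_score if rb else 0)

    def test_gap_cost_convention(self, scheme):
        """A single-residue deletion costs gap_open + gap_extend."""
        q = make_record("q", "WWWWWCWWWWW")
        s = make_record("s", "WWWWWWWWWW")
        res = reference_smith_waterman(q, s, scheme)
        per_w = blosum62_pair_score("W", "W")
        gapped = 10 * per_w - scheme.gap_open - scheme.gap_extend
        ungapped_best = 5 * per_w  # align one flank only, no gap
        assert res.raw_score == max(gapped, ungapped_best)


class TestAlignmentStatistics:
    def _result(self, aq, asub, q_start=0, s_start=0):
        return AlignmentResult(
            query_id="q", subject_id="s", raw_score=1,
            q_start=q_start, q_end=q_start + len(aq.replace("-", "")),
            s_start=s_start, s_end=s_start + len(asub.replace("-", "")),
            aligned_query=aq, aligned_subject=asub)

    def test_identical_columns(self):
        res = alignment_statistics(self._result("MKVLWCDEAC", "MKVLWCDEAC"), 10)
        assert (res.identity_pct, res.mismatches, res.gap_opens) == (100.0, 0, 0)
        assert res.query_coverage == 1.0

    def test_single_gap_run(self):
        res = alignment_statistics(self._result("MK--VL", "MKAAVL"), 20)
        assert res.gap_opens == 1
        assert res.align_length == 6
        assert res.mismatches == 0
        assert res.identity_pct == pytest.approx(100 * 4 / 6)

    def test_half_coverage_counts_as_covering(self):
        aq = "M" * 50
        res = alignment_statistics(self._result(aq, aq), 100)
        assert res.query_coverage == 0.5
        assert res.query_coverage >= 0.5  # the sensitivity gate

    def test_mismatch_and_two_gap_runs(self):
        res = alignment_statistics(self._result("MK-VLW-C", "MKAVLYAC"), 8)
        assert res.gap_opens == 2
        assert res.mismatches == 1  # W vs Y


class TestDedupOverlapping:
    def _hsp(self, score, s_start, s_end):
        return AlignmentResult(query_id="q", subject_id="s", raw_score=score,
                               q_start=0, q_end=s_end - s_start,
                               s_start=s_start, s_end=s_end,
                               aligned_query="", aligned_subject="")

    def test_overlapping_keeps_higher_score(self):
        kept = dedup_overlapping([self._hsp(50, 0, 100), self._hsp(30, 10, 90)])
        assert [h.raw_score for h in kept] == [50]

    def test_disjoint_spans_both_kept(self):
        kept = dedup_overlapping([self._hsp(50, 0, 40), self._hsp(30, 60, 100)])
        assert sorted(h.raw_score for h in kept) == [30, 50]

    def test_small_overlap_both_kept(self):
        kept = dedup_overlapping([self._hsp(50, 0, 50), self._hsp(30, 40, 120)])
        # overlap 10 over shorter span 50 = 20% < 50%
        assert len(kept) == 2
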