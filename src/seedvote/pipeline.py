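"""End-to-end search orchestration.

Stages per database batch — mask, scan/vote/promote, banded align — run
under a producer-consumer scheduler: different batches may occupy different
stages concurrently, each batch enters each stage exactly once, and a final
merge re-establishes batch order, so output is byte-identical whatever the
batch budget or worker count. Total database residues are taken from a
preliminary metadata pass over the whole database, so E-values are global
and batch-invariant.
"""

from __future__ import annotations

import dataclasses
import logging
import threading
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, IO, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from . import masking
from .align import AlignmentResult, banded_raw_score, banded_smith_waterman, dedup_overlapping
from .kmer_index import MAX_K, MIN_K, build_query_index
from .scoring import ScoringScheme
from .seqio import DatabaseBatch, SequenceRecord, read_fasta, split_database, write_tabular_hits
from .stats import attach_statistics, filter_and_rank_hits, min_raw_score
from .vote import ScanCounter, extract_candidates, scan_batch_and_vote

logger = logging.getLogger("seedvote")


@dataclass
class SearchConfig:
    """All search tunables.

    k and the vote threshold are the sensitivity dials: k = 4 with
    vote_threshold = 1 is the slowest, most sensitive mode (every single
    k-mer hit is aligned). Round-trips losslessly through YAML.
    """

    k: int = 4
    vote_threshold: int = 2          # P0: min votes in a diagonal bin
    bin_width: int = 16
    band_width: int = 16
    merge_adjacent: bool = True
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    batch_budget: int = 10 ** 8      # residues per database batch
    evalue_cutoff: float = 10.0
    max_target_seqs: int = 500
    mask_database: bool = True
    mask_queries: bool = False
    mask_threshold: float = masking.DEFAULT_MASK_THRESHOLD
    mask_max_period: int = masking.DEFAULT_MAX_PERIOD
    worker_count: int = 1
    rng_seed: int = 0                # fixtures only; the search is deterministic
    output_format: str = "6"

    def __post_init__(self) -> None:
        if not MIN_K <= self.k <= MAX_K:
            raise ValueError(f"k must be in [{MIN_K}, {MAX_K}]")
        if self.vote_threshold < 1:
            raise ValueError("vote_threshold must be >= 1")
        for name in ("bin_width", "band_width", "batch_budget",
                     "max_target_seqs", "worker_count", "mask_max_period"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.matrix_name != "BLOSUM62":
            raise ValueError("only the BLOSUM62 matrix is supported")
        self.scheme()  # validates gap costs and lambda/K

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(gap_open=self.gap_open, gap_extend=self.gap_extend,
                             lam=self.lam, K=self.K)

    def to_yaml(self, path: Union[str, Path, None] = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "SearchConfig":
        text = Path(source).read_text() if isinstance(source, Path) else source
        if isinstance(source, str) and "\n" not in source and Path(source).exists():
            text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SearchStats:
    """Per-stage counters (conservation: hits <= alignments <= candidates <= buckets)."""

    n_queries: int = 0
    n_subjects: int = 0
    database_residues: int = 0
    n_batches: int = 0
    windows_scanned: int = 0
    total_votes: int = 0
    vote_buckets: int = 0
    candidates_promoted: int = 0
    alignments_computed: int = 0
    hits_emitted: int = 0

    def log(self) -> None:
        for f in dataclasses.fields(self):
            logger.info("stat %s=%s", f.name, getattr(self, f.name))


class StageError(RuntimeError):
    """A pipeline stage failed for one batch; downstream stages were cancelled."""

    def __init__(self, stage_name: str, batch_index: int, cause: BaseException):
        super().__init__(f"stage {stage_name!r} failed on batch {batch_index}: {cause}")
        self.stage_name = stage_name
        self.batch_index = batch_index
        self.cause = cause


def stage_scheduler(stages: Sequence[Tuple[str, Callable]], batches: Sequence,
                    worker_count: int = 1) -> List:
    """Run every batch through every stage with a worker pool.

    Batches may occupy different stages concurrently; each batch enters each
    stage exactly once and in order. Results come back in batch order, so
    output is independent of worker count and interleaving. On failure the
    error of the earliest batch is raised and nothing is emitted.
    """
    if worker_count < 1:
        raise ValueError("worker_count must be >= 1")

    def run_one(idx: int, payload):
        for name, fn in stages:
            try:
                payload = fn(payload)
            except Exception as exc:  # cancel downstream stages for this batch
                raise StageError(name, idx, exc) from exc
        return payload

    results: Dict[int, object] = {}
    errors: List[StageError] = []
    with ThreadPoolExecutor(max_workers=worker_count) as pool:
        futures = {pool.submit(run_one, i, b): i for i, b in enumerate(batches)}
        for fut, idx in futures.items():
            try:
                results[idx] = fut.result()
            except StageError as exc:
                errors.append(exc)
    if errors:
        raise min(errors, key=lambda e: e.batch_index)
    return [results[i] for i in sorted(results)]


def _load(source, what: str) -> List[SequenceRecord]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"{what} file not found: {path}")
        return read_fasta(path)
    return list(source)


def run_search(queries, database, config: Optional[SearchConfig] = None,
               out: Union[str, Path, IO[str], None] = None,
               counter: Optional[ScanCounter] = None) -> Tuple[List[AlignmentResult], SearchStats]:
    """Search query proteins against a protein database.

    ``queries`` and ``database`` are FASTA paths or lists of
    :class:`SequenceRecord`. Returns the ranked hits and per-stage counters;
    when ``out`` is given the hits are also written in BLAST outfmt-6.
    """
    config = config or SearchConfig()
    scheme = config.scheme()
    stats = SearchStats()

    query_records = _load(queries, "query")
    db_records = _load(database, "database")
    stats.n_queries = len(query_records)
    stats.n_subjects = len(db_records)

    if not query_records:
        if out is not None:
            write_tabular_hits([], out)
        return [], stats

    # metadata pass: global residue total, fixed before any batch is scanned
    db_residues = int(sum(r.length for r in db_records))
    stats.database_residues = db_residues
    query_lengths = {r.id: r.length for r in query_records}

    if config.mask_queries:
        for rec in query_records:
            masking.mask_low_complexity(rec, max_period=config.mask_max_period,
                                        mask_threshold=config.mask_threshold)
    index = build_query_index(query_records, config.k)
    batches = split_database(db_records, config.batch_budget)
    stats.n_batches = len(batches)

    lock = threading.Lock()

    def stage_mask(batch: DatabaseBatch) -> DatabaseBatch:
        if config.mask_database:
            for rec in batch.records:
                masking.mask_low_complexity(rec, max_period=config.mask_max_period,
                                            mask_threshold=config.mask_threshold)
        return batch

    def stage_scan(batch: DatabaseBatch):
        votes = scan_batch_and_vote(index, batch, config.bin_width, counter)
        candidates = extract_candidates(votes, config.vote_threshold,
                                        config.merge_adjacent)
        n_rows = len(votes.query_ids)
        if n_rows:
            key_change = ((votes.query_ids[1:] != votes.query_ids[:-1])
                          | (votes.subject_ids[1:] != votes.subject_ids[:-1])
                          | (votes.bins[1:] != votes.bins[:-1]))
            buckets = 1 + int(np.count_nonzero(key_change))
        else:
            buckets = 0
        with lock:
            stats.windows_scanned += votes.n_windows
            stats.total_votes += votes.total_votes
            stats.vote_buckets += buckets
            stats.candidates_promoted += len(candidates)
        logger.debug("stage=scan batch=%d votes=%d buckets=%d candidates=%d",
                     batch.batch_index, votes.total_votes, buckets, len(candidates))
        return batch, candidates

    def stage_align(payload):
        batch, candidates = payload
        results: List[AlignmentResult] = []
        by_pair: Dict[Tuple[int, int], List[AlignmentResult]] = {}
        for cand in candidates:
            query = query_records[cand.query_id]
            subject = db_records[cand.subject_id]
            raw = banded_raw_score(query, subject, cand.representative_diagonal,
                                   config.band_width, scheme)
            needed = min_raw_score(config.evalue_cutoff, query.length,
                                   db_residues, scheme)
            if raw <= 0 or raw < needed:
                continue
            aln = banded_smith_waterman(query, subject,
                                        cand.representative_diagonal,
                                        config.band_width, scheme)
            if aln is not None:
                by_pair.setdefault((cand.query_id, cand.subject_id), []).append(aln)
        for key in sorted(by_pair):
            results.extend(dedup_overlapping(by_pair[key]))
        with lock:
            stats.alignments_computed += len(candidates)
        logger.debug("stage=align batch=%d alignments=%d kept=%d",
                     batch.batch_index, len(candidates), len(results))
        return results

    stages = [("mask", stage_mask), ("scan", stage_scan), ("align", stage_align)]
    per_batch = stage_scheduler(stages, batches, config.worker_count)

    all_hits: List[AlignmentResult] = [h for batch_hits in per_batch for h in batch_hits]
    attach_statistics(all_hits, scheme, query_lengths, db_residues)
    ranked = filter_and_rank_hits(all_hits, config.evalue_cutoff,
                                  config.max_target_seqs,
                                  [r.id for r in query_records])
    stats.hits_emitted = len(ranked)
    stats.log()
    if out is not None:
        write_tabular_hits(ranked, out)
    return ranked, stats
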