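"""Substitution scoring and Karlin-Altschul parameters.

The substitution matrix is BLOSUM62, loaded from Biopython and re-indexed
onto the package's encoded alphabet (ordinals 0..19 for the canonical
residues, the shared excluded ordinal scoring through the X column). The
gapped lambda/K constants for BLOSUM62 with gap penalties 11/1 are the
standard published values; they are configuration, not estimated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import ALPHABET_SIZE, CANONICAL

_blosum_cache = None


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 over the encoded alphabet: (21, 21) int32, symmetric.

    Row/column 20 (the excluded ordinal) carries the X scores, so ambiguous
    residues are alignable but never favourable.
    """
    global _blosum_cache
    if _blosum_cache is None:
        bl = substitution_matrices.load("BLOSUM62")
        letters = CANONICAL + "X"
        mat = np.empty((ALPHABET_SIZE, ALPHABET_SIZE), dtype=np.int32)
        for i, a in enumerate(letters):
            for j, b in enumerate(letters):
                mat[i, j] = int(bl[a, b])
        _blosum_cache = mat
    return _blosum_cache.copy()


@dataclass
class ScoringScheme:
    """Alignment scoring: substitution matrix, affine gap costs, lambda/K.

    gap_open is the cost of opening a gap (charged once per run) and
    gap_extend the cost per gap column, BLAST convention: a gap of length L
    costs gap_open + L * gap_extend.
    """

    matrix: np.ndarray = field(default_factory=blosum62_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267  # gapped Karlin-Altschul lambda, BLOSUM62 11/1
    K: float = 0.041    # gapped Karlin-Altschul K, BLOSUM62 11/1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int32)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("substitution matrix must be square")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not 0 < self.K < 1:
            raise ValueError("K must be in (0, 1)")
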