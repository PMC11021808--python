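"""Tandem-repeat / low-complexity soft-masking of sequences before seeding.

The model is a two-state hidden process per position: *background* versus
*repeat with period p* for p = 1..max_period, with a geometrically decaying
prior over periods. A forward-backward pass computes, at each position, the
posterior probability that the position lies in a tandem repeat of some
nearby offset; positions whose posterior reaches ``mask_threshold`` are
soft-masked — excluded from k-mer seeding but still available to alignment.

Emission odds for "this residue repeats the residue p positions back" come
from the substitution matrix: ratio(a, b) = exp(lambda_u * S(a, b)) with the
ungapped BLOSUM62 lambda, so identities push the posterior up and mismatches
pull it down in proportion to how surprising they are under homology.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .scoring import blosum62_matrix
from .seqio import SequenceRecord

#: Ungapped Karlin-Altschul lambda for BLOSUM62 (standard value).
_LAMBDA_UNGAPPED = 0.3176

#: Default parameters (the tantan published defaults).
DEFAULT_MAX_PERIOD = 50
DEFAULT_REPEAT_PROB = 0.005
DEFAULT_REPEAT_DECAY = 0.9
DEFAULT_REPEAT_END = 0.05
DEFAULT_MASK_THRESHOLD = 0.9

_ratio_matrix_cache = None


def _ratio_matrix() -> np.ndarray:
    """exp(lambda_u * S) likelihood-ratio matrix over the encoded alphabet."""
    global _ratio_matrix_cache
    if _ratio_matrix_cache is None:
        _ratio_matrix_cache = np.exp(_LAMBDA_UNGAPPED * blosum62_matrix().astype(np.float64))
    return _ratio_matrix_cache


@njit(cache=True)
def _fb_posterior(seq, ratio, max_period, p_start, decay, p_end):  # pragma: no cover
    """Forward-backward repeat posterior per position (scaled, O(n * P))."""
    n = seq.shape[0]
    P = max_period
    prior = np.empty(P)
    acc = 1.0
    for p in range(P):
        prior[p] = acc
        acc *= decay
    prior /= prior.sum()

    # emissions as likelihood ratios against the background state
    em = np.ones((n, P))
    for i in range(n):
        for p in range(P):
            back = i - (p + 1)
            if back >= 0:
                em[i, p] = ratio[seq[i], seq[back]]

    # forward, normalized per position (scales cancel in the posterior)
    f_b = np.empty(n)
    f_r = np.empty((n, P))
    prev_b = 1.0
    prev_r = np.zeros(P)
    for i in range(n):
        r_sum = prev_r.sum()
        nb = prev_b * (1.0 - p_start) + p_end * r_sum
        total = nb
        for p in range(P):
            fr = (prev_r[p] * (1.0 - p_end) + prev_b * p_start * prior[p]) * em[i, p]
            f_r[i, p] = fr
            total += fr
        f_b[i] = nb / total
        for p in range(P):
            f_r[i, p] /= total
        prev_b = f_b[i]
        prev_r = f_r[i]

    # backward, normalized per position
    b_b = 1.0
    b_r = np.ones(P)
    posterior = np.empty(n)
    for i in range(n - 1, -1, -1):
        num = 0.0
        for p in range(P):
            num += f_r[i, p] * b_r[p]
        den = f_b[i] * b_b + num
        posterior[i] = num / den if den > 0.0 else 0.0
        if i == 0:
            break
        # transition into position i happens from state at i-1
        new_b = (1.0 - p_start) * b_b
        total = 0.0
        for p in range(P):
            new_b += p_start * prior[p] * em[i, p] * b_r[p]
        new_r = np.empty(P)
        for p in range(P):
            new_r[p] = p_end * b_b + (1.0 - p_end) * em[i, p] * b_r[p]
            total += new_r[p]
        total += new_b
        b_b = new_b / total
        for p in range(P):
            b_r[p] = new_r[p] / total
    return posterior


def repeat_posterior(record: SequenceRecord,
                     max_period: int = DEFAULT_MAX_PERIOD,
                     repeat_prob_start: float = DEFAULT_REPEAT_PROB,
                     repeat_decay: float = DEFAULT_REPEAT_DECAY,
                     repeat_end: float = DEFAULT_REPEAT_END) -> np.ndarray:
    """Per-position posterior probability of being in the repeat state."""
    if max_period < 1:
        raise ValueError("max_period must be >= 1")
    for name, val in (("repeat_prob_start", repeat_prob_start),
                      ("repeat_decay", repeat_decay),
                      ("repeat_end", repeat_end)):
        if not 0.0 < val < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {val}")
    if record.length == 0:
        return np.zeros(0)
    return _fb_posterior(record.residues.astype(np.int64), _ratio_matrix(),
                         max_period, repeat_prob_start, repeat_decay, repeat_end)


def mask_low_complexity(record: SequenceRecord,
                        max_period: int = DEFAULT_MAX_PERIOD,
                        repeat_prob_start: float = DEFAULT_REPEAT_PROB,
                        repeat_decay: float = DEFAULT_REPEAT_DECAY,
                        mask_threshold: float = DEFAULT_MASK_THRESHOLD,
                        repeat_end: float = DEFAULT_REPEAT_END) -> SequenceRecord:
    """Soft-mask tandem-repeat positions of ``record`` in place.

    Residues and length are never altered; only ``record.mask`` is updated
    (OR-ed with the new decision, so repeated calls are idempotent).
    Returns the same record for chaining.
    """
    if not 0.0 < mask_threshold < 1.0:
        raise ValueError(f"mask_threshold must be in (0, 1), got {mask_threshold}")
    if record.length == 0:
        return record
    post = repeat_posterior(record, max_period, repeat_prob_start,
                            repeat_decay, repeat_end)
    record.mask |= post >= mask_threshold
    return record
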