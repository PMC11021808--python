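"""Reproducible synthetic proteomes and planted homologs.

Decoy sequences are i.i.d. draws from a canonical-residue frequency table
(uniform by default — harder for a k-mer seeder than biased natural
composition, since shared words are rarer). Homologs are planted by
per-position substitution (replacement uniform over the other 19 residues)
plus geometric-length indels, with the realized edit counts recorded in the
child's description for provenance.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .alphabet import CANONICAL
from .seqio import SequenceRecord


def generate_proteome(n: int, length_range: tuple = (100, 500), seed: int = 0,
                      frequencies: Optional[Sequence[float]] = None,
                      id_prefix: str = "syn") -> List[SequenceRecord]:
    """Generate ``n`` random protein sequences, ids ``{prefix}_0001`` ...

    Lengths are uniform over the closed ``length_range``; residues i.i.d.
    from ``frequencies`` over the 20 canonical residues (uniform default).
    Bit-identical for identical arguments.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length range {length_range}")
    if frequencies is None:
        freqs = np.full(20, 1.0 / 20.0)
    else:
        freqs = np.asarray(frequencies, dtype=float)
        if freqs.shape != (20,) or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("frequencies must be 20 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n)))
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        residues = rng.choice(20, size=length, p=freqs).astype(np.uint8)
        records.append(SequenceRecord(
            id=f"{id_prefix}_{i + 1:0{width}d}", description="",
            residues=residues))
    return records


def plant_homolog(parent: SequenceRecord, substitution_rate: float = 0.3,
                  indel_rate: float = 0.0, max_indel: int = 10,
                  seed: int = 0, child_id: Optional[str] = None) -> SequenceRecord:
    """Derive a diverged copy of ``parent``.

    Each position is substituted with probability ``substitution_rate``
    (replacement uniform over the 19 other residues; ambiguous parent
    positions are left untouched). Before each position, with probability
    ``indel_rate``, an insertion or deletion event occurs (equal odds);
    event lengths are Geometric(0.5) on {1, 2, ...}, capped at ``max_indel``. The
    description records the parent id and realized edit counts.
    """
    for name, rate in (("substitution_rate", substitution_rate),
                       ("indel_rate", indel_rate)):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must be in [0, 1), got {rate}")
    if max_indel < 1:
        raise ValueError("max_indel must be >= 1")
    rng = np.random.default_rng(seed)
    out: List[int] = []
    n_sub = n_ins = n_del = 0
    i = 0
    residues = parent.residues
    while i < len(residues):
        if indel_rate > 0.0 and rng.random() < indel_rate:
            length = min(int(rng.geometric(0.5)), max_indel)
            if rng.random() < 0.5:
                out.extend(int(r) for r in rng.integers(0, 20, size=length))
                n_ins += length
            else:
                i += length
                n_del += length
                continue
        if i >= len(residues):
            break
        res = int(residues[i])
        if res < 20 and rng.random() < substitution_rate:
            repl = int(rng.integers(0, 19))
            if repl >= res:
                repl += 1
            out.append(repl)
            n_sub += 1
        else:
            out.append(res)
        i += 1
    child = SequenceRecord(
        id=child_id or f"{parent.id}_hom",
        description=f"parent={parent.id} subs={n_sub} ins={n_ins} del={n_del}",
        residues=np.asarray(out, dtype=np.uint8),
    )
    return child


def plant_homolog_set(parents: Sequence[SequenceRecord],
                      substitution_rate: float = 0.3, indel_rate: float = 0.0,
                      max_indel: int = 10, seed: int = 0) -> List[SequenceRecord]:
    """One child per parent, with per-child seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=len(parents))
    return [
        plant_homolog(p, substitution_rate, indel_rate, max_indel,
                      seed=int(child_seeds[i]), child_id=f"{p.id}_hom")
        for i, p in enumerate(parents)
    ]
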