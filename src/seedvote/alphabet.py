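"""Amino-acid alphabet and ordinal encoding.

The 20 canonical residues get ordinals 0..19 in alphabetical order, so the
k-mer key space is exactly 20**k. Every ambiguity / non-standard code
(B, J, Z, X, U, O and the stop ``*``) collapses to a single "excluded"
ordinal that can never participate in a seed but still scores through the
substitution matrix's X column during alignment.
"""

from __future__ import annotations

import numpy as np

#: Canonical residues, alphabetical; index == ordinal.
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"

#: Codes accepted on input but excluded from seeding.
AMBIGUOUS = "BJZXUO*"

#: Ordinal shared by every ambiguous code.
EXCLUDED = len(CANONICAL)  # 20

#: Number of encodable symbols (20 canonical + 1 excluded).
ALPHABET_SIZE = EXCLUDED + 1

_ENCODE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(CANONICAL):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
for _c in AMBIGUOUS:
    _ENCODE[ord(_c)] = EXCLUDED
    if _c != "*":
        _ENCODE[ord(_c.lower())] = EXCLUDED


class AlphabetError(ValueError):
    """A character outside the protein alphabet was encountered."""


def encode(sequence: str) -> np.ndarray:
    """Encode a residue string to ordinals (uint8).

    Raises :class:`AlphabetError` naming the offending character and its
    0-based position if any character is outside the alphabet.
    """
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    if raw.size and raw.max() >= 128:
        bad = int(np.argmax(raw >= 128))
        raise AlphabetError(
            f"non-alphabet character {sequence[bad]!r} at position {bad}"
        )
    ords = _ENCODE[raw]
    if ords.size and ords.min() < 0:
        bad = int(np.argmax(ords < 0))
        raise AlphabetError(
            f"non-alphabet character {sequence[bad]!r} at position {bad}"
        )
    return ords.astype(np.uint8)


def decode(ordinals: np.ndarray) -> str:
    """Inverse of :func:`encode`; the excluded ordinal renders as 'X'."""
    table = CANONICAL + "X"
    return "".join(table[o] for o in ordinals)
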