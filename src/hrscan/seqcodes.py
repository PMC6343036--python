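"""Byte-level sequence helpers: encoding, complement, GC content.

Sequences are held as numpy ``|S1`` arrays. Bases are encoded A,C,G,T -> 0..3;
gaps ('-') and ambiguous residues ('N') encode to MISSING and are excluded from
polymorphism and identity computations (missing-at-site, never mismatch).
"""
from __future__ import annotations

import numpy as np

MISSING = 255

_ENC = np.full(256, MISSING, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
    _ENC[ord(chr(b).lower())] = i

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N", "-": "-"}
_COMP_TABLE = str.maketrans(
    "".join(_COMP) + "".join(k.lower() for k in _COMP),
    "".join(_COMP.values()) + "".join(v.lower() for v in _COMP.values()),
)


def rows_from_strings(seqs) -> np.ndarray:
    """Stack equal-length sequence strings into an (n, L) ``|S1`` array."""
    return np.array([np.frombuffer(s.upper().encode(), dtype="S1") for s in seqs])


def rows_to_strings(rows: np.ndarray) -> list[str]:
    return [r.tobytes().decode() for r in rows]


def encode(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (codes, valid): uint8 base codes with MISSING, and a validity mask."""
    raw = rows.view(np.uint8)
    codes = _ENC[raw]
    return codes, codes != MISSING


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def gc_fraction(row: np.ndarray) -> float:
    """GC fraction of the non-gap, non-N residues of one ``|S1`` row."""
    codes = _ENC[row.view(np.uint8)]
    valid = codes != MISSING
    n = int(valid.sum())
    if n == 0:
        return float("nan")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / n
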