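"""RNA alphabet utilities: encoding, IUPAC degenerate codes, DNA→RNA ingest.

The internal alphabet is RNA (A, C, G, U); DNA input is converted at ingest.
Bases are encoded as integers A=0, C=1, G=2, U=3 (lexicographic order), which
fixes the k-mer enumeration order used throughout.
"""

from __future__ import annotations

import re
from itertools import product

import numpy as np

RNA_BASES = "ACGU"

# IUPAC degenerate nucleotide codes, written in the RNA alphabet.
IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "W": "AU", "S": "CG", "Y": "CU", "R": "AG", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
    "N": "ACGU",
}

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(RNA_BASES):
    _ENCODE[ord(_b)] = _i
_DECODE = np.frombuffer(RNA_BASES.encode(), dtype=np.uint8)


class InvalidParameterError(ValueError):
    """A parameter violates its documented precondition."""


class DegenerateInputError(ValueError):
    """An input is structurally valid but degenerate (empty, all-zero, ...)."""


def to_rna(seq: str) -> str:
    """Convert a DNA or RNA string to the internal RNA alphabet (uppercase)."""
    return seq.upper().replace("T", "U")


def validate_rna(seq: str, *, allow_iupac: bool = False) -> None:
    allowed = set(IUPAC_SETS) if allow_iupac else set(RNA_BASES)
    bad = set(seq) - allowed
    if bad:
        raise InvalidParameterError(
            f"invalid characters {sorted(bad)} in sequence {seq!r}"
        )


def encode_sequences(seqs) -> np.ndarray:
    """Encode equal-length RNA strings as a (n, L) uint8 matrix (A=0..U=3)."""
    seqs = list(seqs)
    if not seqs:
        raise DegenerateInputError("no sequences to encode")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise InvalidParameterError("sequences must have equal length")
    raw = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), L)
    enc = _ENCODE[raw]
    if (enc == 255).any():
        raise InvalidParameterError("sequences contain non-ACGU characters")
    return enc


def decode_matrix(enc: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_sequences`."""
    ascii_mat = _DECODE[enc]
    flat = ascii_mat.tobytes()
    L = enc.shape[1]
    return [flat[i * L:(i + 1) * L].decode() for i in range(enc.shape[0])]


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC motif into a regex matching concrete RNA text."""
    validate_rna(pattern, allow_iupac=True)
    if not pattern:
        raise InvalidParameterError("empty motif")
    parts = []
    for ch in pattern:
        bases = IUPAC_SETS[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def expand_iupac(pattern: str) -> list[str]:
    """Expand an IUPAC motif into its concrete sequences, in product order."""
    validate_rna(pattern, allow_iupac=True)
    if not pattern:
        raise InvalidParameterError("empty motif")
    return ["".join(p) for p in product(*(IUPAC_SETS[c] for c in pattern))]


def is_concrete(pattern: str) -> bool:
    return all(c in RNA_BASES for c in pattern)
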