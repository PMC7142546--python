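"""Internal nucleotide-alphabet helpers.

Sequences are stored in the RNA alphabet (U, not T) throughout the
package; readers accept either alphabet and writers can emit either.
"""

from __future__ import annotations

from .errors import ValidationError

RNA_BASES = "ACGU"
_ALLOWED = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def normalize(seq: str) -> str:
    """Uppercase and convert a DNA/RNA string to the internal U alphabet.

    Raises :class:`ValidationError` on characters outside {A,C,G,T,U,N}.
    """
    s = seq.upper().replace("T", "U")
    if not s:
        raise ValidationError("empty sequence")
    bad = set(s) - _ALLOWED
    if bad:
        raise ValidationError(f"invalid characters in sequence: {sorted(bad)}")
    return s


def to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Hamming distance between equal-length strings, with optional early
    exit once the distance exceeds ``limit`` (returns limit+1 then)."""
    if len(a) != len(b):
        raise ValidationError("hamming distance requires equal lengths")
    d = 0
    if limit is None:
        for x, y in zip(a, b):
            if x != y:
                d += 1
        return d
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d
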