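"""Nucleotide alphabet handling: 2-bit codec, packing, reverse complement.

A KFF file declares one :class:`Encoding`, a bijection from ``{A, C, G, T}``
onto ``{0, 1, 2, 3}``, and every packed sequence in the file uses it.  The
customary example assigns ``A:0, C:1, G:3, T:2``; any of the 24 permutations
is legal.

Packing convention
------------------
Nucleotides are packed four per byte in sequence order, big-endian within the
payload: the *final* nucleotide occupies the two least-significant bits of the
*last* payload byte.  When the length is not a multiple of four, the unused
(padding) bits sit in the most-significant bits of the *first* byte and are
always zero.  Under an order-preserving encoding this makes the numeric value
of a packed k-mer compare exactly like the k-mer's lexicographic rank, for
equal k.

Canonical form is defined on the letter alphabet (``A < C < G < T``),
independent of the file's numeric encoding, so that the canonicity of a k-mer
set survives re-encoding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import AlphabetError, InvalidEncodingError, TruncationError

NUCLEOTIDES = "ACGT"

_NON_ACGT = re.compile(r"[^ACGT]")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# per-encoding lookup tables, keyed by the (a, c, g, t) code tuple
_TABLE_CACHE: dict[tuple[int, int, int, int], tuple[dict, list[str]]] = {}


@dataclass(frozen=True)
class Encoding:
    """A bijective nucleotide -> 2-bit code table.

    Parameters are the codes of A, C, G and T in that order.  Raises
    :class:`InvalidEncodingError` unless they form a permutation of 0..3.
    """

    a: int
    c: int
    g: int
    t: int

    def __post_init__(self) -> None:
        if sorted(self.codes) != [0, 1, 2, 3]:
            raise InvalidEncodingError(
                f"codes {self.codes} are not a permutation of 0..3"
            )

    @property
    def codes(self) -> tuple[int, int, int, int]:
        return (self.a, self.c, self.g, self.t)

    def code_of(self, nucleotide: str) -> int:
        """Return the 2-bit code of a single nucleotide letter."""
        try:
            return self.codes[NUCLEOTIDES.index(nucleotide.upper())]
        except ValueError:
            raise AlphabetError(f"not a nucleotide: {nucleotide!r}") from None

    def letter_of(self, code: int) -> str:
        """Return the nucleotide letter carrying a given 2-bit code."""
        return NUCLEOTIDES[self.codes.index(code)]

    def to_byte(self) -> int:
        """Pack the codes of A, C, G, T into one byte, A in the high bits.

        The customary ``A:0, C:1, G:3, T:2`` table packs to ``0x1E``.
        """
        return (self.a << 6) | (self.c << 4) | (self.g << 2) | self.t

    @classmethod
    def from_byte(cls, byte: int) -> "Encoding":
        """Inverse of :meth:`to_byte`."""
        return cls((byte >> 6) & 3, (byte >> 4) & 3, (byte >> 2) & 3, byte & 3)

    def __str__(self) -> str:
        return ",".join(f"{n}:{c}" for n, c in zip(NUCLEOTIDES, self.codes))


def make_encoding(a: int, c: int, g: int, t: int) -> Encoding:
    """Build an :class:`Encoding` from the four codes of A, C, G, T."""
    for v in (a, c, g, t):
        if not isinstance(v, int) or not 0 <= v <= 3:
            raise InvalidEncodingError(f"code {v!r} outside 0..3")
    return Encoding(a, c, g, t)


#: The customary encoding (A:0, C:1, G:3, T:2), used as the default for
#: every file this library writes.
DEFAULT_ENCODING = Encoding(0, 1, 3, 2)


@dataclass(frozen=True)
class PackedSequence:
    """A 2-bit packed nucleotide sequence.

    ``payload`` holds exactly ``ceil(length / 4)`` bytes; padding bits (when
    ``length % 4 != 0``) occupy the most-significant bits of the first byte
    and are zero.
    """

    payload: bytes
    length: int


def _tables(enc: Encoding) -> tuple[dict, list[str]]:
    """Translation tables for fast bulk (de)coding, cached per encoding.

    Returns ``(letters -> base-4 digit chars, byte -> 4-letter expansion)``.
    """
    key = enc.codes
    cached = _TABLE_CACHE.get(key)
    if cached is None:
        to_digits = str.maketrans(
            {n: str(c) for n, c in zip(NUCLEOTIDES, enc.codes)}
        )
        letter = [enc.letter_of(code) for code in range(4)]
        expand = [
            letter[(b >> 6) & 3] + letter[(b >> 4) & 3]
            + letter[(b >> 2) & 3] + letter[b & 3]
            for b in range(256)
        ]
        cached = (to_digits, expand)
        _TABLE_CACHE[key] = cached
    return cached


def check_alphabet(seq: str) -> str:
    """Upper-case ``seq`` and raise :class:`AlphabetError` on non-ACGT input.

    The error names the first offending position; ambiguity codes such as N
    are rejected — the format has no representation for them.
    """
    seq = seq.upper()
    hit = _NON_ACGT.search(seq)
    if hit is not None:
        raise AlphabetError(
            f"non-ACGT character {hit.group()!r} at position {hit.start()}"
        )
    return seq


def encode_sequence(seq: str, enc: Encoding = DEFAULT_ENCODING) -> PackedSequence:
    """Pack a nucleotide string at 2 bits per base.

    The sequence is interpreted as a base-4 numeral under ``enc`` and written
    big-endian into ``ceil(len(seq) / 4)`` bytes, which realizes the
    right-aligned convention documented in the module docstring.
    """
    seq = check_alphabet(seq)
    n = len(seq)
    if n == 0:
        return PackedSequence(b"", 0)
    to_digits, _ = _tables(enc)
    value = int(seq.translate(to_digits), 4)
    return PackedSequence(value.to_bytes((n + 3) // 4, "big"), n)


def decode_sequence(packed: PackedSequence, enc: Encoding = DEFAULT_ENCODING) -> str:
    """Inverse of :func:`encode_sequence`.

    Raises :class:`TruncationError` when the payload is shorter than the
    ``ceil(length / 4)`` bytes the declared length requires.
    """
    need = (packed.length + 3) // 4
    if len(packed.payload) < need:
        raise TruncationError(
            f"payload of {len(packed.payload)} bytes cannot hold "
            f"{packed.length} nucleotides (need {need})"
        )
    if packed.length == 0:
        return ""
    _, expand = _tables(enc)
    letters = "".join(expand[b] for b in packed.payload)
    return letters[len(letters) - packed.length:]


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement; an involution on ACGT strings."""
    seq = check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement.

    The comparison is on letters (A < C < G < T) regardless of any file
    encoding, so both strands of a k-mer map to one stable representative.
    """
    kmer = check_alphabet(kmer)
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc
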