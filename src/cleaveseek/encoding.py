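"""2-bit integer encoding of nucleotide sequences.

Every nucleotide is stored in two bits and a whole sequence becomes a single
integer by concatenating the per-base bit pairs, first (5') base in the most
significant position.  Small RNAs and messenger RNAs use *inverse* bit codes:

    base   sRNA code   mRNA code
    A        00          11
    C        01          10
    G        10          01
    T/U      11          00

The inversion is what makes the encoding useful: a sRNA k-mer and the mRNA
k-mer it pairs with position-by-position (antiparallel, Watson-Crick) encode
to the *same* integer, so exact-complement lookup reduces to integer
equality.  All 7-mers therefore live in [0, 16383] and exact matching over a
transcriptome becomes binary search over sorted integer lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

Mode = Literal["sRNA", "mRNA"]

#: per-base 2-bit codes in sRNA orientation; mRNA code is the bitwise inverse
_SRNA_CODE = {"A": 0b00, "C": 0b01, "G": 0b10, "T": 0b11, "U": 0b11}
_SRNA_BASE = {0b00: "A", 0b01: "C", 0b10: "G", 0b11: "T"}

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


@dataclass(frozen=True)
class EncodedSeq:
    """An integer-encoded nucleotide sequence.

    Attributes
    ----------
    value : int
        Concatenated 2-bit codes, first base most significant; in
        ``[0, 4**length)``.
    length : int
        Number of nucleotides encoded.
    mode : {"sRNA", "mRNA"}
        Which of the two inverse code tables was used.
    """

    value: int
    length: int
    mode: Mode

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0 <= self.value < 4**self.length:
            raise ValueError(
                f"value {self.value} out of range for length {self.length}"
            )


def base_code(base: str, mode: Mode) -> int:
    """2-bit code of a single base in the given mode."""
    try:
        code = _SRNA_CODE[base]
    except KeyError:
        raise ValueError(f"ambiguous or invalid base {base!r}") from None
    return code if mode == "sRNA" else code ^ 0b11


def encode(sequence: str, mode: Mode = "sRNA") -> EncodedSeq:
    """Encode a DNA/RNA string into its integer representation.

    Parameters
    ----------
    sequence : str
        Non-empty, over {A, C, G, T, U} (case sensitive, expects uppercase).
    mode : {"sRNA", "mRNA"}

    Raises
    ------
    ValueError
        On an empty sequence or any base outside the unambiguous alphabet
        (such sequences must have been filtered out upstream).
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    value = 0
    for base in sequence:
        value = (value << 2) | base_code(base, mode)
    return EncodedSeq(value=value, length=len(sequence), mode=mode)


def decode(code: EncodedSeq) -> str:
    """Invert :func:`encode` for the same mode; returns DNA alphabet (T not U)."""
    value = code.value
    invert = 0 if code.mode == "sRNA" else 0b11
    bases = []
    for _ in range(code.length):
        bases.append(_SRNA_BASE[(value & 0b11) ^ invert])
        value >>= 2
    return "".join(reversed(bases))


def encode_window(sequence: str, mode: Mode = "sRNA") -> int:
    """Bare integer value of ``encode`` — hot-path helper without the dataclass."""
    value = 0
    table = _SRNA_CODE
    invert = 0 if mode == "sRNA" else 0b11
    for base in sequence:
        value = (value << 2) | (table[base] ^ invert)
    return value


def reverse_complement(sequence: str) -> str:
    """Reverse complement in DNA alphabet (U treated as T)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def complement(sequence: str) -> str:
    """Positionwise complement (no reversal), DNA alphabet."""
    return sequence.translate(_COMPLEMENT)
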