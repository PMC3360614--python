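"""Small sequence utilities: alphabet normalization, complements, transcription.

Conventions used throughout the package: sequences are plain upper-case
strings; DNA is over {A,C,G,T,N} ('N' marks draft-quality EST positions),
RNA is over {A,C,G,U}; all coordinates are 0-based half-open.
"""

from __future__ import annotations

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGU")

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


class FormatError(ValueError):
    """Raised when an input file or sequence violates the expected format."""


def normalize(seq: str, alphabet: str = "DNA", *, context: str = "") -> str:
    """Upper-case ``seq`` and convert it to the requested alphabet.

    ``alphabet`` is ``"DNA"`` (U becomes T) or ``"RNA"`` (T becomes U).
    Normalization is idempotent.  Illegal characters raise
    :class:`FormatError` naming ``context`` (typically a record id).
    """
    s = seq.upper()
    if alphabet == "DNA":
        s = s.replace("U", "T")
        allowed = DNA_ALPHABET
    elif alphabet == "RNA":
        s = s.replace("T", "U")
        allowed = RNA_ALPHABET
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    bad = set(s) - allowed
    if bad:
        where = f" in {context}" if context else ""
        raise FormatError(
            f"illegal character(s) {sorted(bad)} for {alphabet}{where}"
        )
    return s


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def transcribe(dna: str) -> str:
    """DNA sense strand -> RNA (T to U)."""
    return dna.replace("T", "U").replace("t", "u")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
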