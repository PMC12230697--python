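"""Validated antisense-oligonucleotide sequences.

An ASO query is a short single-stranded DNA sequence written 5'->3' over
the alphabet {A, T, C, G}. The default length cap of 22 bases mirrors the
longest oligomers the ranking pipeline is tuned for; it is a parameter,
not a chemical limit.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import EmptySequence, IllegalSymbol, TooLong

ALPHABET = ("A", "T", "C", "G")
DEFAULT_MAX_LENGTH = 22


@dataclass(frozen=True)
class AsoSequence:
    """An immutable, validated nucleotide sequence (5'->3').

    Attributes
    ----------
    bases : tuple of str
        One symbol per position, each in ``{A, T, C, G}``.
    """

    bases: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.bases) == 0:
            raise EmptySequence("sequence has no bases")
        bad = [b for b in self.bases if b not in ALPHABET]
        if bad:
            raise IllegalSymbol(f"symbols outside A/T/C/G: {sorted(set(bad))}")

    @property
    def length(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return "".join(self.bases)


def validate_sequence(raw: str, max_length: int = DEFAULT_MAX_LENGTH) -> AsoSequence:
    """Normalize and validate a raw sequence string.

    Normalization upper-cases the input and strips all whitespace, so
    pasted sequences with line breaks or ``5'-``/``-3'`` spacing artifacts
    that reduce to plain letters still validate.

    Parameters
    ----------
    raw : str
        Candidate sequence text.
    max_length : int
        Maximum accepted number of bases (default 22).

    Returns
    -------
    AsoSequence

    Raises
    ------
    EmptySequence
        If no bases remain after normalization.
    IllegalSymbol
        If any normalized character is outside ``{A, T, C, G}``.
    TooLong
        If the sequence exceeds ``max_length`` bases.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    cleaned = "".join(raw.split()).upper()
    if not cleaned:
        raise EmptySequence("empty sequence")
    bad = sorted({c for c in cleaned if c not in ALPHABET})
    if bad:
        raise IllegalSymbol(f"illegal symbols {bad}; expected only A, T, C, G")
    if len(cleaned) > max_length:
        raise TooLong(f"{len(cleaned)} bases exceeds the maximum of {max_length}")
    return AsoSequence(tuple(cleaned))
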