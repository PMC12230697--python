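"""Modified-sequence output notation: writer and parser.

The CSV output notation renders each base as a token and each linkage as
a separator: ``*`` for a phosphorothioate (PS) linkage, nothing for a
phosphodiester (PO) one. Unmodified (DNA) bases are bare letters. LNA
bases keep their base letter, e.g. ``[LNA T]``. MOE tokens follow the
pyrimidine conventions of MOE chemistry: an MOE-modified T is named as
the uridine analogue ``[2’-MOE(U)]`` and an MOE-modified C as the
5-methylcytidine analogue ``[2’-MOE 5-Methyl(C)]``. Note the typographic
apostrophe (U+2019) inside the MOE tokens; it is part of the grammar.
"""

from __future__ import annotations

import re

from .errors import NotationError, UnknownChemistry
from .patterns import DNA, LNA, MOE, PO, PS, ModificationPattern
from .sequences import AsoSequence

# (sugar, base) -> token
_TOKENS: dict[tuple[str, str], str] = {
    (MOE, "T"): "[2’-MOE(U)]",
    (MOE, "C"): "[2’-MOE 5-Methyl(C)]",
    (MOE, "A"): "[2’-MOE(A)]",
    (MOE, "G"): "[2’-MOE(G)]",
    (LNA, "T"): "[LNA T]",
    (LNA, "C"): "[LNA C]",
    (LNA, "A"): "[LNA A]",
    (LNA, "G"): "[LNA G]",
}
_TOKEN_TO_SUGAR_BASE = {tok: sb for sb, tok in _TOKENS.items()}

_TOKEN_RE = re.compile(r"\[[^\]]*\]|[ATCG]")


def pattern_to_notation(seq: AsoSequence, pattern: ModificationPattern) -> str:
    """Render a (sequence, pattern) pair in the output notation.

    Raises
    ------
    UnknownChemistry
        If a position's sugar has no notation rule.
    ValueError
        If the pattern length does not match the sequence.
    """
    if pattern.length != seq.length:
        raise ValueError(
            f"pattern length {pattern.length} != sequence length {seq.length}"
        )
    parts: list[str] = []
    for i, (base, sugar) in enumerate(zip(seq.bases, pattern.sugar)):
        if sugar == DNA:
            parts.append(base)
        else:
            tok = _TOKENS.get((sugar, base))
            if tok is None:
                raise UnknownChemistry(f"no notation rule for {sugar} {base}")
            parts.append(tok)
        if i < pattern.length - 1:
            parts.append("*" if pattern.linkage[i] == PS else "")
    return "".join(parts)


def parse_notation(text: str, modification_type: str | None = None):
    """Parse a notation string back into (AsoSequence, ModificationPattern).

    The parser is the inverse of :func:`pattern_to_notation`. The
    modification type is inferred from the tokens present; an all-DNA
    string defaults to LNA unless ``modification_type`` is given.

    Raises
    ------
    NotationError
        On any text that the writer could not have produced.
    """
    bases: list[str] = []
    sugars: list[str] = []
    linkages: list[str] = []
    pos = 0
    expect_base = True
    n = len(text)
    if not text:
        raise NotationError("empty notation string")
    while pos < n:
        if not expect_base:
            if text[pos] == "*":
                linkages.append(PS)
                pos += 1
            else:
                linkages.append(PO)
            expect_base = True
            continue
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise NotationError(f"unexpected character {text[pos]!r} at offset {pos}")
        tok = m.group(0)
        if tok.startswith("["):
            try:
                sugar, base = _TOKEN_TO_SUGAR_BASE[tok]
            except KeyError:
                raise NotationError(f"unknown modified-base token {tok}") from None
            sugars.append(sugar)
            bases.append(base)
        else:
            sugars.append(DNA)
            bases.append(tok)
        pos = m.end()
        expect_base = False
    if expect_base:
        raise NotationError("notation ends with a dangling linkage")
    non_dna = {s for s in sugars if s != DNA}
    if len(non_dna) > 1:
        raise NotationError(f"mixed modification chemistries {sorted(non_dna)}")
    chem = next(iter(non_dna)) if non_dna else (modification_type or LNA)
    if modification_type is not None and non_dna and chem != modification_type:
        raise NotationError(
            f"notation uses {chem} but {modification_type} was expected"
        )
    seq = AsoSequence(tuple(bases))
    pattern = ModificationPattern(
        sugar=tuple(sugars), linkage=tuple(linkages), modification_type=chem
    )
    return seq, pattern
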