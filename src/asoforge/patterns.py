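"""Enumeration of chemical-modification patterns.

A modification pattern assigns a sugar chemistry (DNA, LNA or 2'-MOE) to
every position of an ASO and a backbone chemistry (PO or PS) to every
internucleotide linkage. Generated patterns use a single non-DNA sugar
chemistry at a time and a uniformly phosphorothioate (PS) backbone — the
combination used for gapmer screening — while the type itself can carry
any mixture for extensibility.

Positions are 1-based and counted 5'->3' throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .errors import WingOverlap
from .sequences import AsoSequence

DNA = "DNA"
LNA = "LNA"
MOE = "MOE"
SUGARS = (DNA, LNA, MOE)
MODIFICATION_TYPES = (LNA, MOE)

PO = "PO"
PS = "PS"
LINKAGES = (PO, PS)

#: Default cap on eagerly consumed full enumerations (2**18 patterns).
DEFAULT_ENUMERATION_CAP = 1 << 18


@dataclass(frozen=True)
class ModificationPattern:
    """Per-position sugar and per-linkage backbone chemistry of one variant.

    Attributes
    ----------
    sugar : tuple of str
        One of ``DNA``/``LNA``/``MOE`` per base position (length *l*).
    linkage : tuple of str
        One of ``PO``/``PS`` per internucleotide gap (length *l* - 1).
    modification_type : str
        The single non-DNA chemistry this pattern is allowed to use.
    """

    sugar: tuple[str, ...]
    linkage: tuple[str, ...]
    modification_type: str

    def __post_init__(self) -> None:
        if len(self.linkage) != len(self.sugar) - 1:
            raise ValueError(
                f"need {len(self.sugar) - 1} linkages for {len(self.sugar)} bases,"
                f" got {len(self.linkage)}"
            )
        bad_sugar = set(self.sugar) - set(SUGARS)
        if bad_sugar:
            raise ValueError(f"unknown sugar chemistries: {sorted(bad_sugar)}")
        bad_link = set(self.linkage) - set(LINKAGES)
        if bad_link:
            raise ValueError(f"unknown linkage chemistries: {sorted(bad_link)}")
        non_dna = {s for s in self.sugar if s != DNA}
        if non_dna - {self.modification_type}:
            raise ValueError(
                f"pattern mixes chemistries {sorted(non_dna)};"
                f" only {self.modification_type} is allowed besides DNA"
            )
        if self.modification_type not in MODIFICATION_TYPES:
            raise ValueError(f"unknown modification type {self.modification_type!r}")

    @property
    def length(self) -> int:
        return len(self.sugar)

    @property
    def modified_positions(self) -> tuple[int, ...]:
        """1-based positions carrying the non-DNA chemistry."""
        return tuple(i + 1 for i, s in enumerate(self.sugar) if s != DNA)

    def modified_indicator(self) -> tuple[int, ...]:
        """0/1 vector over positions: 1 where the sugar is modified."""
        return tuple(int(s != DNA) for s in self.sugar)


def _pattern_from_bits(bits: Iterable[int], chem: str, length: int) -> ModificationPattern:
    sugar = tuple(chem if b else DNA for b in bits)
    return ModificationPattern(
        sugar=sugar, linkage=(PS,) * (length - 1), modification_type=chem
    )


def enumerate_full_patterns(
    seq: AsoSequence, chem: str, cap: int | None = DEFAULT_ENUMERATION_CAP
) -> Iterator[ModificationPattern]:
    """Stream all ``2**l`` sugar-modification patterns of a sequence.

    Every position independently takes DNA or ``chem``; every linkage is
    PS. Patterns are yielded in binary-counting order with position 1
    (the 5' end) as the least-significant bit, so the all-DNA pattern
    comes first and the fully modified pattern last.

    Parameters
    ----------
    seq : AsoSequence
    chem : str
        ``"LNA"`` or ``"MOE"``.
    cap : int or None
        Maximum number of patterns to yield (default ``2**18``); ``None``
        streams the full space. The cap guards against accidentally
        materializing the ``2**22``-variant space of a maximum-length
        query.
    """
    if chem not in MODIFICATION_TYPES:
        raise ValueError(f"chem must be one of {MODIFICATION_TYPES}, got {chem!r}")
    l = seq.length
    total = 1 << l
    n = total if cap is None else min(total, cap)
    for code in range(n):
        bits = [(code >> i) & 1 for i in range(l)]
        yield _pattern_from_bits(bits, chem, l)


def enumerate_gapmer_wing_patterns(
    seq: AsoSequence,
    chem: str,
    wing_len: int = 5,
    variable_wing_positions: frozenset[int] | set[int] = frozenset({2, 3, 4, 5}),
) -> list[ModificationPattern]:
    """Enumerate gapmer patterns that vary only inside the two wings.

    The oligomer is split into a 5' wing of ``wing_len`` bases, a central
    DNA gap, and a 3' wing of ``wing_len`` bases. Within each wing the
    positions listed in ``variable_wing_positions`` (1-based, counted
    from the outer terminus of that wing inward) independently take DNA
    or ``chem``; the remaining wing positions are fixed as ``chem``, the
    conventional modified-terminus anchoring of gapmer designs. All
    linkages are PS.

    With the defaults (5-nt wings, variable positions 2-5) a 16-mer
    yields ``2**4 = 16`` cases per wing and ``16 * 16 = 256`` patterns.

    Returns the deduplicated list in deterministic order: binary counting
    over the 5' wing's variable positions (outermost variable position
    least significant), then over the 3' wing's.

    Raises
    ------
    WingOverlap
        If ``2 * wing_len`` exceeds the sequence length.
    """
    if chem not in MODIFICATION_TYPES:
        raise ValueError(f"chem must be one of {MODIFICATION_TYPES}, got {chem!r}")
    l = seq.length
    if 2 * wing_len > l:
        raise WingOverlap(f"two wings of {wing_len} nt do not fit in {l} bases")
    variable = sorted(variable_wing_positions)
    if any(p < 1 or p > wing_len for p in variable):
        raise ValueError(f"variable positions {variable} outside 1..{wing_len}")

    # per-wing assignments: bit i of the code toggles variable[i]
    wing_cases: list[tuple[int, ...]] = []
    for code in range(1 << len(variable)):
        wing = [1] * wing_len  # fixed wing positions anchored as modified
        for i, pos in enumerate(variable):
            wing[pos - 1] = (code >> i) & 1
        wing_cases.append(tuple(wing))

    seen: set[tuple[str, ...]] = set()
    out: list[ModificationPattern] = []
    for wing3 in wing_cases:
        for wing5 in wing_cases:
            # 3' wing positions are counted from the 3' terminus inward
            bits = list(wing5) + [0] * (l - 2 * wing_len) + list(reversed(wing3))
            pat = _pattern_from_bits(bits, chem, l)
            if pat.sugar not in seen:
                seen.add(pat.sugar)
                out.append(pat)
    return out
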