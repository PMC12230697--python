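"""Exception hierarchy for asoforge."""


class AsoforgeError(Exception):
    """Base class for all asoforge errors."""


class IllegalSymbol(AsoforgeError):
    """Sequence contains a character outside the A/T/C/G alphabet."""


class TooLong(AsoforgeError):
    """Sequence exceeds the configured maximum length."""


class EmptySequence(AsoforgeError):
    """Sequence contains no bases after normalization."""


class WingOverlap(AsoforgeError):
    """Gapmer wings would overlap: 2 * wing_len > sequence length."""


class UnknownChemistry(AsoforgeError):
    """A sugar chemistry with no output-notation rule."""


class NotationError(AsoforgeError):
    """A modified-sequence notation string that does not parse."""


class MissingFragment(AsoforgeError):
    """No fragment-library entry for a (base, sugar) combination."""


class AssemblyFailure(AsoforgeError):
    """The assembled oligonucleotide failed chemical sanitization."""


class ParseError(AsoforgeError):
    """Invalid SMILES input."""


class UnknownElement(AsoforgeError):
    """Element outside the featurization vocabulary (strict mode only)."""


class ShapeMismatch(AsoforgeError):
    """Feature dimensions do not match the model configuration."""


class Divergence(AsoforgeError):
    """Training loss became non-finite."""


class LengthMismatch(AsoforgeError):
    """Pattern length does not match the oracle specification."""


class CheckpointError(AsoforgeError):
    """Model checkpoint is inconsistent with its stored configuration."""
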