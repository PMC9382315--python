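"""Exception hierarchy for codonlogo.

Every error raised on a user-facing code path derives from
:class:`CodonLogoError`, so the CLI can catch one type and exit cleanly.
"""


class CodonLogoError(Exception):
    """Base class for all codonlogo errors."""


class EmptyInputError(CodonLogoError):
    """The input FASTA contained no records."""


class AlignmentError(CodonLogoError):
    """Records do not form a valid alignment (unequal lengths)."""


class FrameError(CodonLogoError):
    """Alignment length is not a multiple of three."""


class AlphabetError(CodonLogoError):
    """A sequence contains a character outside the allowed alphabet."""


class UndefinedFractionError(CodonLogoError):
    """Ambiguity fraction is undefined (all-gap sequence)."""


class EmptyAfterFilterError(CodonLogoError):
    """Filtering removed every sequence."""


class DegenerateColumnError(CodonLogoError):
    """A codon position has zero counted codons (all gap-codons)."""


class AlphabetMismatchError(CodonLogoError):
    """Observed entropy exceeds the chosen Smax (alphabet too small)."""


class ContractError(CodonLogoError):
    """An internal numeric contract was violated (e.g. unnormalized row)."""


class ConfigError(CodonLogoError):
    """Invalid run configuration (bad enum value, out-of-range option)."""
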