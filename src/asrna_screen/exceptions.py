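"""Exception hierarchy for the antisense-RNA screening toolkit."""


class AsrnaScreenError(Exception):
    """Base class for all toolkit errors."""


class MalformedRecordError(AsrnaScreenError):
    """A record in an input file violates a structural invariant (names the line)."""


class DuplicateIdentifierError(AsrnaScreenError):
    """Two records share an identifier that must be unique."""


class InvalidStrandError(AsrnaScreenError):
    """A strand character outside the accepted alphabet for the record type."""


class InvalidSequenceError(AsrnaScreenError):
    """A nucleotide outside {A, C, G, T, N} (names the offending position)."""


class TableParseError(AsrnaScreenError):
    """A tabular cell could not be parsed (names the cell)."""


class InsufficientFlankError(AsrnaScreenError):
    """A design window extends past the contig edge."""


class ZeroControlError(AsrnaScreenError):
    """A 5S control lane has zero signal, so normalisation is undefined."""


class InsufficientDataError(AsrnaScreenError):
    """Not enough shared measurements to call a response category."""


class GenerationError(AsrnaScreenError):
    """Synthetic-data geometry or parameterisation is impossible."""
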