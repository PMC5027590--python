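"""Exception hierarchy shared across the package."""


class DaccspotError(Exception):
    """Base class for all package-specific errors."""


class UnknownPropertyError(DaccspotError, KeyError):
    """A property name is not present in the active property table."""


class DegeneratePropertyError(DaccspotError, ValueError):
    """A property has zero variance across the dinucleotide classes."""


class InvalidSequenceError(DaccspotError, ValueError):
    """A sequence contains characters outside the A/C/G/T alphabet."""


class SequenceLengthError(DaccspotError, ValueError):
    """A sequence is too short for the requested lag."""


class ShapeError(DaccspotError, ValueError):
    """Matrix dimensions do not match what a model or operation expects."""


class ProtocolError(DaccspotError, ValueError):
    """A cross-validation protocol precondition is violated."""


class FastaError(DaccspotError, ValueError):
    """Malformed or inconsistent FASTA / label input."""


class GenerationError(DaccspotError, ValueError):
    """An infeasible synthetic-data specification."""
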