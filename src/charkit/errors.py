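"""Exception hierarchy shared by all assay modules."""


class CharkitError(Exception):
    """Base class for all charkit errors."""


class InvalidInputError(CharkitError, ValueError):
    """An argument violates a precondition (wrong sign, empty series, ...)."""


class SchemaError(CharkitError, ValueError):
    """A tabular or sequence input file does not match the expected schema."""


class NoBurstError(CharkitError):
    """A one-step growth series never rises above the detection threshold."""


class DegenerateInputError(CharkitError):
    """The series is malformed for the requested analysis (e.g. already risen)."""


class NumericalError(CharkitError):
    """A simulation or fit produced non-finite values."""
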