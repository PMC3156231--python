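"""Exception hierarchy shared across the package."""


class NrpredError(Exception):
    """Base class for all package errors."""


class InputError(NrpredError):
    """Unreadable, unwritable or empty input."""


class ValidationError(NrpredError):
    """A sequence record failed validation."""


class DuplicateIdentifierError(ValidationError):
    """Two records in one dataset share an identifier."""


class TooShortError(ValidationError):
    """A sequence (or signal) is shorter than an operation requires."""


class DimensionError(NrpredError):
    """A feature block has the wrong number of components."""


class ParameterError(NrpredError):
    """An algorithm parameter is out of its valid range."""


class LeakageError(NrpredError):
    """Test data overlaps the training reference set."""
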