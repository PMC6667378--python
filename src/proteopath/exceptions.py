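"""Exception hierarchy for proteopath."""


class ProteopathError(Exception):
    """Base class for all proteopath errors."""


class ProteoformParseError(ProteopathError, ValueError):
    """A proteoform notation string could not be parsed."""


class InvalidCoordinateError(ProteoformParseError):
    """A modification site is zero, negative, or not an integer."""


class InvalidPtmTypeError(ProteoformParseError):
    """A PTM type identifier is not five decimal digits."""


class InputValidationError(ProteopathError, ValueError):
    """An input record violates its declared constraints."""


class ConfigurationError(ProteopathError):
    """Missing files or infeasible parameters."""


class IntegrityError(ProteopathError):
    """A knowledge base contains dangling or inconsistent references."""
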