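"""Exception hierarchy shared across the package."""


class ReamsimError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ReamsimError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ReamsimError):
    """Data violates a structural invariant (lengths, monotonicity, units)."""


class ParameterError(ReamsimError):
    """A parameter is outside its admissible range."""
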