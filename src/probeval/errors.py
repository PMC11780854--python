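"""Exception hierarchy shared across the package.

``FormatError`` signals malformed external files, ``ValidationError``
signals semantically invalid data (invariant violations, impossible
parameter values), and ``DegenerateDataError`` signals inputs on which a
statistic is mathematically undefined (single-class labels, empty valid
sets, zero variance).  The command-line layer maps these onto distinct
exit codes.
"""


class ProbevalError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ProbevalError):
    """A file does not conform to its expected external format."""


class ValidationError(ProbevalError):
    """Data violate a documented invariant or precondition."""


class ProfilePairingError(ValidationError):
    """Two profiles that must describe the same RNA do not match."""


class DegenerateDataError(ProbevalError):
    """The requested statistic is undefined on this input."""
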