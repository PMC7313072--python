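"""Exception hierarchy.

All trarep errors derive from :class:`TrarepError` so the CLI can map user
errors to exit code 1 and anything else to 2.
"""


class TrarepError(Exception):
    """Base class for all errors raised by trarep."""


class InvalidNameError(TrarepError):
    """A gene name is empty or malformed."""


class ReferenceValidationError(TrarepError):
    """A reference segment violates an anchor or alphabet invariant."""


class ReferenceConfigError(TrarepError):
    """The reference files are inconsistent (e.g. a missing anchor entry)."""


class ParameterError(TrarepError):
    """A simulation or pipeline parameter is out of range."""


class ConfigurationError(TrarepError):
    """A run configuration cannot be satisfied (e.g. missing spike-in gene)."""


class JunctionError(TrarepError):
    """A recombination request would destroy a conserved anchor."""


class RetryExhaustedError(TrarepError):
    """Random redraws failed to produce a productive junction."""


class InvalidInputError(TrarepError):
    """A read or sequence fails basic input validation."""
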