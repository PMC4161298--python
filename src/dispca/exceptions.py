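"""Exception hierarchy for dispca.

All errors raised on bad user input derive from :class:`DispcaError` so
callers (and the CLI) can catch one base class.
"""


class DispcaError(ValueError):
    """Base class for all dispca input/usage errors."""


class FormatError(DispcaError):
    """A file does not conform to the expected external format."""


class ValidationError(DispcaError):
    """Input data violates an invariant (e.g. p-value outside (0, 1])."""


class ConfigurationError(DispcaError):
    """A parameter is outside its allowed range or inconsistent with the data."""
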