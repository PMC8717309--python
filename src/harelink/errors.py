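"""Exception hierarchy.

Validation failures (bad user input, impossible dimensions, schema problems)
derive from :class:`ValidationError` so the CLI can map them to exit code 2;
everything else surfaces as exit code 1.
"""


class HarelinkError(Exception):
    """Base class for all package errors."""


class ValidationError(HarelinkError):
    """Invalid input data or configuration."""


class InvalidDimensionError(ValidationError):
    """A seed dimension, mass or volume is non-positive where positivity is required."""


class MissingTraitError(ValidationError):
    """A required trait (typically seed height) is absent."""


class ExcludedSpeciesError(ValidationError):
    """Species cannot enter a computation (e.g. zero control germination capacity)."""


class UndefinedCorrelationError(ValidationError):
    """Pearson correlation undefined (constant column)."""


class TreeError(ValidationError):
    """Malformed, unrooted or otherwise unusable phylogeny."""


class TransformError(ValidationError):
    """A log transform was requested on a non-positive value."""
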