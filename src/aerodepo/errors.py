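"""Exception hierarchy shared by all pipeline stages.

Validation problems (bad shapes, negative activities, incomplete
configuration) and data inconsistencies (e.g. more activity in the empty
nebulizer than in the full one) are kept distinct so the command-line
layer can map them to different exit codes.
"""


class AerodepoError(Exception):
    """Base class for all package errors."""


class ValidationError(AerodepoError):
    """Input violates a structural precondition (exit code 2 in the CLI)."""


class EmptyRunError(ValidationError):
    """An impactor run with zero total activity cannot be reduced."""


class ExtrapolationError(ValidationError):
    """A requested quantile lies outside the attained cumulative range."""

    def __init__(self, q: float, nearest: float):
        self.q = q
        self.nearest = nearest
        super().__init__(
            f"quantile {q:g} is outside the attained cumulative range; "
            f"nearest attainable quantile is {nearest:g}"
        )


class ConfigurationError(ValidationError):
    """A correction or run configuration is incomplete for the given data."""


class GeometryError(ValidationError):
    """Synthetic scene footprints are invalid (e.g. overlapping)."""


class DataInconsistencyError(AerodepoError):
    """Physically impossible measurement combination (exit code 3 in the CLI)."""
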