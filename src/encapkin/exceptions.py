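"""Error signals raised by encapkin.

All inherit from built-in exception types so callers can catch broadly
(``ValueError`` for bad inputs/configurations, ``RuntimeError`` for fit
failures) or narrowly by name.
"""


class InvalidConfigError(ValueError):
    """A simulation or run configuration violates its invariants."""


class DegenerateDesignError(ValueError):
    """A regression design has no information (e.g. all times identical)."""


class InsufficientDataError(ValueError):
    """Too few points remain for the requested operation."""


class FitFailureError(RuntimeError):
    """Nonlinear fit did not converge.

    Carries the initializer's parameter estimate in ``initial_result`` so a
    caller can fall back to it deliberately.
    """

    def __init__(self, message, initial_result=None):
        super().__init__(message)
        self.initial_result = initial_result


class SchemaError(ValueError):
    """An input file does not match the expected column schema."""


class JoinError(KeyError):
    """Sample-level join failed; ``missing`` lists the absent sample ids."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class NonPhysicalValueWarning(UserWarning):
    """A computed quantity is outside its physically expected range."""
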