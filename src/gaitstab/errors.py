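"""Exception hierarchy for gaitstab.

All domain failures raise a subclass of :class:`GaitstabError`, so callers
(including the CLI) can distinguish model-level problems from programming
errors.
"""


class GaitstabError(Exception):
    """Base class for all gaitstab domain errors."""


class SingularOrbitError(GaitstabError):
    """The periodic-orbit denominator vanishes for these parameters.

    Raised on the measure-zero parameter lines where the closed-form
    reference state is undefined (progressive: ``2s/omega == b_d``;
    alternating: ``2c == b_p``).
    """


class SingularDesignError(GaitstabError):
    """The regression design matrix is rank deficient.

    Carries the names of the offending (zero-variance or collinear)
    columns in :attr:`columns`.
    """

    def __init__(self, message: str, columns: tuple[str, ...] = ()):
        super().__init__(message)
        self.columns = tuple(columns)


class DivergenceError(GaitstabError):
    """A simulated walker exceeded the divergence guard bound.

    :attr:`step` records the step index reached before the abort.
    """

    def __init__(self, message: str, step: int):
        super().__init__(message)
        self.step = step


class SchemaError(GaitstabError):
    """A CSV file does not match the expected column schema."""


class ConfigError(GaitstabError):
    """A run configuration is invalid (unknown key, missing/duplicate parameter)."""
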