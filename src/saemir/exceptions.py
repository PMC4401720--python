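"""Exception hierarchy shared across the package."""


class SaemirError(Exception):
    """Base class for all errors raised by saemir."""


class FormatError(SaemirError, ValueError):
    """A file or table violates the expected format or its invariants."""


class DesignError(SaemirError, ValueError):
    """The sample design cannot support the requested computation."""


class DegenerateFitError(SaemirError, ArithmeticError):
    """A model fit has zero residual variance; inference is impossible."""


class UndefinedReversibilityError(SaemirError, ArithmeticError):
    """The % change denominator (smoker - nonsmoker mean) is degenerate."""
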