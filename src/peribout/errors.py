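"""Exception hierarchy shared across the package."""


class PeriboutError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PeriboutError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidInputError(PeriboutError, ValueError):
    """An input object violates a precondition (e.g. mismatched grids)."""


class InsufficientDataError(PeriboutError, ValueError):
    """Not enough data to run the operation (e.g. < 2 snips, stream < 60 s)."""


class DegenerateDataError(PeriboutError, ValueError):
    """Data are degenerate for the requested computation (e.g. zero variance)."""


class IncompleteDesignError(PeriboutError, ValueError):
    """A within-subjects table has missing cells."""


class InvalidDesignError(PeriboutError, ValueError):
    """A design is structurally unusable (e.g. a single-level factor)."""


class FormatError(PeriboutError, ValueError):
    """A file on disk does not conform to the expected schema."""


class PeriboutIOError(PeriboutError, OSError):
    """A referenced file is missing or unwritable."""
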