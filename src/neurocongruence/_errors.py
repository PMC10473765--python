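"""Exception hierarchy shared across the package."""


class NeurocongruenceError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NeurocongruenceError):
    """Input violates a documented precondition (bad labels, duplicate keys, ...)."""


class FormatError(NeurocongruenceError):
    """A file is missing required columns or is otherwise malformed."""


class DegenerateInputError(NeurocongruenceError):
    """Numerically degenerate input (constant vector, zero scale, ...)."""


class InsufficientDataError(NeurocongruenceError):
    """Too few observations for the requested estimate."""


class SingularDesignError(NeurocongruenceError):
    """Rank-deficient design matrix in a regression."""


class MissingRegionsError(NeurocongruenceError):
    """One or more regions could not be resolved; carries the offending names."""

    def __init__(self, regions, message=None):
        self.regions = list(regions)
        super().__init__(message or f"unresolvable regions: {', '.join(map(str, self.regions))}")
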