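"""Exception hierarchy shared across the package."""


class OptophysError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OptophysError, ValueError):
    """A parameter violates its documented contract (non-positive rate, etc.)."""


class DegenerateBaselineError(OptophysError, ValueError):
    """The sliding-baseline F is non-positive somewhere, so dF/F is undefined."""

    def __init__(self, first_index: int, last_index: int):
        self.first_index = first_index
        self.last_index = last_index
        super().__init__(
            f"baseline F <= 0 for samples {first_index}..{last_index}; "
            "dF/F is undefined there"
        )


class NormalizationUndefinedError(OptophysError, ValueError):
    """The pre-period mean used for percent-of-pre normalization is zero."""


class InsufficientDataError(OptophysError, ValueError):
    """Too few trials/samples to run the requested statistic."""


class WindowRangeError(OptophysError, ValueError):
    """A requested analysis window falls outside the available data extent."""
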