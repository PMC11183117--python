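"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (configuration vs numerical vs
I/O failures), so library code should raise the most specific class.
"""


class TrajGSAError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TrajGSAError):
    """Invalid configuration, unsupported option, or mismatched declarations."""


class InvalidInputError(TrajGSAError):
    """Non-finite or otherwise invalid numerical input."""


class DimensionError(TrajGSAError):
    """Inconsistent array shapes or subspace dimensions."""


class ShapeError(TrajGSAError):
    """A trajectory record cannot be reshaped as requested."""


class DegenerateKernelError(TrajGSAError):
    """A kernel row has zero degree; the random walk is undefined."""


class DegenerateResponseError(TrajGSAError):
    """A response with zero variance cannot be normalized."""


class DegenerateVarianceError(TrajGSAError):
    """Total variance estimate is non-positive; indices are undefined."""


class IllConditionedProblemError(TrajGSAError):
    """Regression problem with fewer samples than basis functions."""


class AggregationError(TrajGSAError):
    """Multi-level aggregation failed (e.g. an empty community)."""


class NumericalError(TrajGSAError):
    """An iterative numerical procedure failed to converge."""
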