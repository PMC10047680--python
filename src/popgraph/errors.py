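"""Exception types shared across the pipeline."""


class PopgraphError(Exception):
    """Base class for all package errors."""


class ValidationError(PopgraphError, ValueError):
    """Input data violates a contract (non-finite voxels, bad labels...)."""


class ShapeError(PopgraphError, ValueError):
    """Array dimensions are inconsistent with the requested operation."""


class ConfigurationError(PopgraphError, ValueError):
    """A configuration value is unusable for the given data (e.g. an
    amplitude band that contains no DFT bin)."""


class SizingError(PopgraphError, ValueError):
    """A grid is too small to host the requested structure."""


class ConvergenceError(PopgraphError, RuntimeError):
    """An iterative solver failed to converge within its budget."""


class DivergenceError(PopgraphError, RuntimeError):
    """Training produced a non-finite loss."""
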