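"""Exception types shared across the package."""


class FCAMSegError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FCAMSegError, ValueError):
    """A parameter is outside its documented domain."""


class FormatError(FCAMSegError, ValueError):
    """An input file or array does not match the expected format."""


class DegenerateRegionError(FCAMSegError, ValueError):
    """A region is too small to carry neighborhood statistics (< 2 sites)."""


class ZeroMassError(FCAMSegError, ValueError):
    """An aura matrix has zero total mass and cannot be normalized."""


class TrainingError(FCAMSegError, ValueError):
    """Classifier training received degenerate inputs."""
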