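"""Exception hierarchy for the wgsmap toolkit."""


class WgsmapError(Exception):
    """Base class for all toolkit errors."""


class MapStructureError(WgsmapError):
    """A genome/genetic-map object violates a structural invariant."""


class MapMismatchError(WgsmapError):
    """Two objects that must share a genetic map do not."""


class PoolExhaustionError(WgsmapError):
    """Rejection sampling hit its attempt cap before filling the pool."""


class UnsupportedDesignError(WgsmapError):
    """An operation was asked about a cross design it is not defined for."""


class InsufficientDataError(WgsmapError):
    """Too few observations for the requested fit."""


class NoSignalError(WgsmapError):
    """All bins are empty: no peak can be called."""


class NoClusterError(WgsmapError):
    """No chain of homozygous variants satisfies the cluster rule."""


class NoIntervalError(WgsmapError):
    """The smoothed curve never reaches the calling threshold."""


class VcfParseError(WgsmapError):
    """A pool VCF could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class NoAllelicDepthError(WgsmapError):
    """A pool VCF lacks per-allele read counts (AD) for its sample."""
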