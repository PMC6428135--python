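"""Exception hierarchy shared across the package."""


class LdnekitError(Exception):
    """Base class for all package-specific errors."""


class ParseError(LdnekitError):
    """A PED/MAP file could not be parsed; the message names the offending line."""


class ValidationError(LdnekitError):
    """A genotype matrix or marker map violates a structural invariant."""


class EmptyCohortError(LdnekitError):
    """A filter removed every sample."""


class InsufficientDataError(LdnekitError):
    """Too few informative individuals for an estimate."""


class MonomorphicMarkerError(LdnekitError):
    """LD is undefined because a marker is monomorphic among informative calls."""


class UndefinedEstimateError(LdnekitError):
    """An Ne point estimate is undefined for the given bin."""


class LayoutError(LdnekitError):
    """A synthetic fixture layout is inconsistent."""


class AlignmentError(LdnekitError):
    """Two inputs that must share a grid or key set do not."""


class ConfigError(LdnekitError):
    """An invalid run or bin configuration."""
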