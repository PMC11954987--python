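"""Exception types shared across the package."""


class BrainPatchError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BrainPatchError, ValueError):
    """A parameter violates its documented precondition."""


class InvalidInputError(BrainPatchError, ValueError):
    """An input array or trial violates a structural precondition."""


class DegenerateChannelError(BrainPatchError, ValueError):
    """A channel has zero variance and cannot be standardized."""


class SessionFormatError(BrainPatchError, ValueError):
    """An on-disk session container is malformed or inconsistent."""


class MissingPositionError(BrainPatchError, KeyError):
    """A (channel, time-slot) pair has no learned positional embedding."""


class DegeneratePatchError(BrainPatchError, ValueError):
    """A patch has zero norm; the cosine reconstruction loss is undefined."""


class LabelMappingError(BrainPatchError, KeyError):
    """A (dataset, label) pair is absent from the label amalgamation map."""


class ConfigError(BrainPatchError, ValueError):
    """An experiment or generator configuration is invalid or incomplete."""
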