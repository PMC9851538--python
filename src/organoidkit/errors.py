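"""Exception types shared across the toolkit."""


class OrganoidKitError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(OrganoidKitError, ValueError):
    """A simulation or pipeline configuration violates an invariant.

    The message names the violated invariant.
    """


class ParameterError(OrganoidKitError, ValueError):
    """An analysis parameter is out of range (e.g. cutoff above Nyquist)."""


class DataQualityError(OrganoidKitError, ValueError):
    """The data themselves preclude the requested computation
    (e.g. a flat baseline with zero standard deviation)."""
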