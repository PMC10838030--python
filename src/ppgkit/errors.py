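"""Exception hierarchy for ppgkit.

Every error raised by the library derives from :class:`PPGKitError`, so
callers (notably the CLI, which must keep processing the remaining signals
when one fails) can catch a single base class.
"""


class PPGKitError(Exception):
    """Base class for all ppgkit errors."""


class FormatError(PPGKitError):
    """A file does not conform to the expected on-disk format."""


class BoundsError(PPGKitError):
    """A requested window or index range falls outside the signal."""


class ResolutionError(PPGKitError):
    """The sampling rate is too low to resolve a requested feature."""


class InsufficientBeatsError(PPGKitError):
    """Fewer beats than the minimum required were detected."""


class CyclicityError(PPGKitError):
    """No credible cycle length could be estimated from the signal."""


class MalformedPulseError(PPGKitError):
    """A pulse lacks the basic structure (e.g. a systolic maximum)."""


class DegenerateAttractorError(PPGKitError):
    """An attractor density map carries no mass."""


class InsufficientDataError(PPGKitError):
    """A statistical routine received an empty group after filtering."""


class ConfigurationError(PPGKitError):
    """An invalid configuration or cohort specification."""
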