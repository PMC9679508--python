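"""Exception hierarchy for the gaitemg pipeline.

Each stage raises a dedicated subclass so orchestration code can name the
failing stage without string matching.
"""


class GaitEMGError(Exception):
    """Base class for all gaitemg errors."""


class IngestError(GaitEMGError):
    """A trial bundle is missing a required file or cannot be read."""


class SynchronizationError(GaitEMGError):
    """Kinematic and EMG records do not cover the same time span."""


class SchemaError(GaitEMGError):
    """Unknown marker or muscle label, or malformed bundle contents."""


class ConfigurationError(GaitEMGError):
    """Invalid parameter (cutoff above Nyquist, bad scenario, bad alpha...)."""


class FilteringError(GaitEMGError):
    """Signal too short for the requested zero-phase filter."""


class InsufficientStridesError(GaitEMGError):
    """Fewer than the minimum number of gait events for a limb."""


class NormalizationError(GaitEMGError):
    """No surviving baseline strides to define a reference contraction."""


class PairingError(GaitEMGError):
    """Subject sets of the two compared conditions do not match."""


class DegenerateFieldError(GaitEMGError):
    """Zero variance with nonzero mean at a node of a t-field."""
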