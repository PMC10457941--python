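"""Exception hierarchy for impactkin."""


class ImpactKinError(Exception):
    """Base class for all impactkin errors."""


class InvalidParameterError(ImpactKinError, ValueError):
    """A parameter is outside its admissible range (e.g. cutoff >= Nyquist)."""


class InvalidInputError(ImpactKinError, ValueError):
    """Input data violate a precondition (length, co-sampling, missing channel)."""


class ConfigError(ImpactKinError, ValueError):
    """A sensor/geometry/run configuration is inconsistent or malformed."""


class FormatError(ImpactKinError, ValueError):
    """A file does not conform to the expected on-disk format."""


class AlignmentError(ImpactKinError, ValueError):
    """Paired traces could not be time-aligned (e.g. no threshold crossing)."""


class DegenerateInputError(ImpactKinError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class InsufficientDataError(ImpactKinError, ValueError):
    """Too few trials/pairs to assemble the requested report."""


class ImplausibleGeometryError(ImpactKinError, ValueError):
    """A sensor placement is physically implausible for a head-mounted device."""
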