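"""Exception hierarchy shared by all pipeline stages."""


class ZebraphysError(Exception):
    """Base class for all package errors."""


class SchemaError(ZebraphysError):
    """An input file does not match the documented column schema."""


class ValidationError(ZebraphysError):
    """Data violate a structural invariant (monotonic frames, positive axes, ...)."""


class ConfigurationError(ZebraphysError):
    """Acquisition configuration is missing or inconsistent."""


class InsufficientDataError(ZebraphysError):
    """Too few samples/beats/frames for the requested computation."""


class PairingError(ZebraphysError):
    """Atrial and ventricular beat series cannot be paired."""


class AlignmentError(ZebraphysError):
    """Time series do not overlap enough to be aligned."""


class DataQualityError(ZebraphysError):
    """A physiologically impossible result signals upstream mis-detection."""


class SimSpecError(ZebraphysError):
    """A simulation specification is infeasible."""
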