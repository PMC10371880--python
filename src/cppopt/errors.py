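"""Exception types shared across the package."""


class CppoptError(Exception):
    """Base class for all package-specific errors."""


class CadenceError(CppoptError):
    """Sampling intervals are incompatible (non-integer ratio)."""


class AlignmentError(CppoptError):
    """Two series do not share a common time grid."""


class ConfigurationError(CppoptError):
    """An invalid or inconsistent configuration value."""


class GapError(CppoptError):
    """An operation requiring gap-free input received gapped data."""


class PatientSpecError(CppoptError):
    """An invalid virtual-patient specification."""
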