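"""Exception hierarchy, mapped to CLI exit codes by :mod:`maskingnet.cli`."""


class MaskingNetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MaskingNetError):
    """Invalid geometry, wiring or engine configuration (exit code 2)."""


class GenerationError(MaskingNetError):
    """Pattern generation could not satisfy its constraints."""


class NumericalError(MaskingNetError):
    """Numerical instability during integration (exit code 3)."""


class CalibrationError(MaskingNetError):
    """Conductance calibration failed its contract (exit code 4)."""
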