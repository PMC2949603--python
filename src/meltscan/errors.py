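"""Exception hierarchy for the meltscan pipeline."""


class MeltScanError(Exception):
    """Base class for all meltscan errors."""


class AmpliconError(MeltScanError):
    """Invalid amplicon definition or variant placement."""


class ThermoError(MeltScanError):
    """Nearest-neighbor summation cannot be carried out (e.g. terminal mismatch)."""


class CurveAnalysisError(MeltScanError):
    """Curve preprocessing precondition violated (no decay, degenerate range, ...)."""


class CallingError(MeltScanError):
    """Positive calling / screening pipeline misuse."""


class AnnotationError(MeltScanError):
    """Reading-frame inconsistency or untranslatable variant context."""


class ConfigError(MeltScanError):
    """Invalid or unknown configuration content."""
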