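"""Exception hierarchy for nimargin."""


class NimarginError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NimarginError, ValueError):
    """A scenario or strategy is internally inconsistent (e.g. exam ages
    that do not align with the model cycle grid)."""


class CalibrationError(NimarginError, RuntimeError):
    """The requested cumulative event rate cannot be realised by any
    non-negative hazard multiplier."""


class EquipoiseError(NimarginError, RuntimeError):
    """The equipoise search failed: no sign change of the outcome gap in
    the admissible bracket."""
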