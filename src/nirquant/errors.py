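"""Exception hierarchy for nirquant."""


class NirquantError(Exception):
    """Base class for all nirquant errors."""


class GridError(NirquantError):
    """Invalid wavenumber grid specification."""


class DesignError(NirquantError):
    """Invalid mixture-design specification."""


class DomainError(NirquantError):
    """Value outside its physical domain (e.g. mass fraction not in [0, 100])."""


class FormatError(NirquantError):
    """Malformed spectra file or report table."""


class DegenerateSpectrumError(NirquantError):
    """A spectrum that cannot be normalized or scatter-corrected."""


class DimensionError(NirquantError):
    """Mismatched array shapes or grids."""


class SplitError(NirquantError):
    """Invalid calibration/prediction partition request."""


class ConfigError(NirquantError):
    """Invalid algorithm configuration."""


class ReportError(NirquantError):
    """Incomplete or empty evaluation report."""
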