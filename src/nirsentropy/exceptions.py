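"""Exception hierarchy shared across the package."""


class NirsEntropyError(Exception):
    """Base class for all package errors."""


class SeriesFormatError(NirsEntropyError):
    """Malformed series file: bad header, non-uniform grid, gap too long."""


class SeriesDomainError(NirsEntropyError):
    """Saturation values outside the physical [0, 100] range."""


class SeriesTooShortError(NirsEntropyError):
    """Intraoperative window shorter than the 100-point applicability floor."""


class WindowError(NirsEntropyError):
    """Baseline/intraop window violates its contract (size, ordering)."""


class DegenerateToleranceError(NirsEntropyError):
    """Coefficient-based tolerance requested on a constant series (SD = 0)."""


class DegenerateTableError(NirsEntropyError):
    """2x2 table with a zero margin."""


class ConfigurationError(NirsEntropyError):
    """Inconsistent analysis settings (e.g. surrogate count vs alpha)."""


class CalibrationError(NirsEntropyError):
    """Requested calibration target outside the achievable range."""
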