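"""Exception hierarchy for the optirlipid pipeline.

Every stage raises a subclass of :class:`OptirError` so that the CLI can map
failures onto a named stage and a non-zero exit code.
"""


class OptirError(Exception):
    """Base class for all optirlipid errors."""


class ParseError(OptirError):
    """A delimited-text file could not be parsed; the message names the line."""


class FormatError(OptirError):
    """An image or table file has the wrong structure (e.g. RGB TIFF)."""


class AxisRangeError(OptirError):
    """A wavenumber axis lies outside the supported mid-IR range."""


class AxisMismatchError(OptirError):
    """Two spectra that must share an axis do not."""


class CoverageError(OptirError):
    """A power spectrum does not cover the wavenumbers it must normalize."""


class NormalizationError(OptirError):
    """Normalization is impossible (non-positive anchor or power)."""


class FitError(OptirError):
    """A least-squares fit failed or its result is unusable."""


class EstimationError(OptirError):
    """A derived estimate (e.g. profile FWHM) is outside its validity domain."""


class CalibrationError(OptirError):
    """A calibration curve is degenerate (non-positive slope)."""


class MetricsError(OptirError):
    """A per-cell metric cannot be formed (e.g. missing amide-I area)."""


class GeometryError(OptirError):
    """Image shapes, pixel sizes or coordinates are inconsistent."""


class ConfigError(OptirError):
    """A run configuration contains unknown or invalid keys."""


class PipelineError(OptirError):
    """An end-to-end run failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
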