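"""Exception hierarchy for the baumtest pipeline.

Every stage of the measurement pipeline raises a subclass of
:class:`BaumtestError`, so callers can distinguish "this page has no usable
drawing" from genuine programming errors.  :class:`PipelineError` wraps a
stage failure with the stage name attached, which the CLI reports on stderr.
"""

from __future__ import annotations


class BaumtestError(Exception):
    """Base class for all errors raised by baumtest."""


class FormatError(BaumtestError):
    """Raster input is structurally invalid (e.g. zero-dimension image)."""


class CalibrationError(BaumtestError):
    """No pixel-to-centimetre conversion could be established."""


class NoInkError(BaumtestError):
    """The page contains no detectable ink (zero-contrast image)."""


class NoDrawingError(BaumtestError):
    """Ink was detected but nothing survived cleaning / component selection."""


class GeometryError(BaumtestError):
    """A synthetic drawing specification does not fit on the page."""


class DegenerateInputError(BaumtestError):
    """A statistic is undefined for this input (e.g. constant sample)."""


class InsufficientDataError(BaumtestError):
    """Too few observations for the requested statistic."""


class SchemaError(BaumtestError):
    """A roster or metrics table is missing required columns."""


class PipelineError(BaumtestError):
    """A pipeline stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
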