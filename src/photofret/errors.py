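"""Exception hierarchy for the photometry pipeline."""


class PhotometryError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(PhotometryError):
    """A recording or table is missing required columns or contains bad rows."""


class EmptyRecordingError(SchemaError):
    """A recording file parsed to zero frames."""


class ManifestError(PhotometryError):
    """An experiment manifest is structurally invalid or references absent data."""


class BaselineError(PhotometryError):
    """The pre-treatment (hour-0) FRET baseline is absent or unusable (F0 <= 0)."""


class DegenerateDataError(PhotometryError):
    """Input data cannot support the requested statistic (e.g. zero variance,
    no frames of one LED state, fewer points than the formula needs)."""
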