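"""Exception hierarchy for spectrograin.

All errors derive from :class:`SpectrograinError` so callers can catch the
package's failures with one clause; most also derive from :class:`ValueError`
to behave well in generic numeric code.
"""


class SpectrograinError(Exception):
    """Base class for all spectrograin errors."""


class InvalidArgumentError(SpectrograinError, ValueError):
    """An argument violates a documented precondition."""


class CalibrationError(SpectrograinError, ValueError):
    """Panel calibration is unusable (e.g. a zero panel digital number)."""


class SegmentationError(SpectrograinError, ValueError):
    """Seed segmentation produced an empty region of interest."""


class SpectraParseError(SpectrograinError, ValueError):
    """A spectra table or ENVI file could not be parsed."""


class DegenerateSpectrumError(SpectrograinError, ValueError):
    """A spectrum has no variance where variance is required (SNV, MSC)."""


class StratificationError(SpectrograinError, ValueError):
    """A class is too small for the requested split or fold count."""


class DegenerateTraitError(SpectrograinError, ValueError):
    """A per-class trait has no variance, so correlation is undefined."""


class LookupError_(SpectrograinError, KeyError):
    """A requested grid entry or class is not present."""
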