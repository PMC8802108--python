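"""Exception hierarchy.

All cardiobeat errors derive from :class:`CardiobeatError` so callers can
distinguish bad inputs (``ParameterError``, ``InputError``) from data that is
formally valid but cannot support the requested computation
(``DegenerateDataError``, ``UndefinedMetricError``, ``RecordingRejectedError``).
"""


class CardiobeatError(Exception):
    """Base class for all cardiobeat exceptions."""


class ParameterError(CardiobeatError, ValueError):
    """Invalid simulation or analysis parameters."""


class InputError(CardiobeatError, ValueError):
    """Malformed input data (non-uniform sampling, wrong shape, ...)."""


class UndefinedMetricError(CardiobeatError):
    """A metric is undefined for the given data (e.g. beat rate with < 2 events)."""


class DegenerateDataError(CardiobeatError):
    """Statistical test cannot be computed (e.g. zero variance everywhere)."""


class NormalizationError(CardiobeatError):
    """Baseline normalization impossible (zero or missing baseline)."""


class RecordingRejectedError(CardiobeatError):
    """Multichannel recording failed quality control (< 3 usable channels)."""
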