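"""Exception hierarchy.

All errors raised by this package derive from :class:`SpectralCalError` so
callers can catch everything with one clause; most also derive from
``ValueError`` because they signal invalid inputs.
"""


class SpectralCalError(Exception):
    """Base class for all spectralcal errors."""


class InvalidParameterError(SpectralCalError, ValueError):
    """A decomposition parameter is outside its valid domain (e.g. DER <= 1)."""


class InsufficientDataError(SpectralCalError, ValueError):
    """Too few (or degenerate) measurements for a calibration fit."""


class InconsistentGroupError(SpectralCalError, ValueError):
    """Records mixed across materials or tube voltages where one group is required."""


class GeometryError(SpectralCalError, ValueError):
    """Image/ROI geometry problem: shape mismatch, ROI out of bounds, bad spacing."""


class EmptyRoiError(GeometryError):
    """An ROI selected zero pixels."""


class MetadataError(SpectralCalError, ValueError):
    """Required image metadata (rescale, spacing, labels) missing or inconsistent."""


class PhantomSpecError(SpectralCalError, ValueError):
    """Synthetic phantom specification invalid (overlapping or out-of-body rods, ...)."""


class ZeroTrueConcentrationError(SpectralCalError, ZeroDivisionError):
    """Relative error is undefined for a true concentration of zero."""
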