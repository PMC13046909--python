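"""Pure algebra of image-space two-material decomposition.

In the (HE, LE) plane of a dual-energy acquisition, voxels containing only
the base material (water- or liver-equivalent tissue) lie on the *water line*
``LE = HE`` (slope 1), and voxels containing only the contrast material
(iodine or iron) lie on the *material line* ``LE = DER * HE``, where the
dual-energy ratio DER > 1 is the ratio of the material's low- to high-energy
CT-number response.  A mixed voxel is projected onto the material line along
a direction parallel to the water line; the projection's components are the
contrast-material contribution at each energy.  A weighted blend of the two
components gives the concentration-map (CM) value in HU, a base-material
CT-number mismatch ``delta_base`` is added to the LE - HE difference to
cancel residual calibration offsets, and a scaling factor ``alpha``
(HU per mg/mL) converts CM values to concentrations.

Everything here is elementwise algebra on scalars or numpy arrays; no
fitting, no I/O.  Calibration of DER, delta_base and alpha from phantom
measurements lives in :mod:`spectralcal.calibration`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import InvalidParameterError, ZeroTrueConcentrationError

__all__ = [
    "ArrayLike",
    "VoxelPair",
    "MaterialLineProjection",
    "DecompositionParams",
    "ConcentrationResult",
    "project_to_material_line",
    "cm_measured",
    "cm_corrected",
    "concentration_from_cm",
    "mean_method_concentration",
    "relative_error",
]

ArrayLike = Union[float, np.ndarray]

# DER - 1 appears in every denominator; values this close to the water line
# would amplify noise without bound and are rejected outright.
_DER_MARGIN = 1e-6


def _as_finite(x: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"{name} must be finite, got {x!r}")
    return arr


def _check_der(der: ArrayLike) -> np.ndarray:
    der = _as_finite(der, "der")
    if np.any(der - 1.0 <= _DER_MARGIN):
        raise InvalidParameterError(
            f"dual-energy ratio must exceed 1 (got {der!r}); the material "
            "line must be steeper than the water line"
        )
    return der


def _check_w(w: ArrayLike) -> np.ndarray:
    w = _as_finite(w, "w")
    if np.any((w < 0.0) | (w > 1.0)):
        raise InvalidParameterError(f"weighting factor w must lie in [0, 1], got {w!r}")
    return w


@dataclass(frozen=True)
class VoxelPair:
    """One (low-energy, high-energy) CT-number observation in HU.

    Fields may be scalars or equal-shaped arrays (a whole image pair).
    """

    le: ArrayLike
    he: ArrayLike

    def __post_init__(self) -> None:
        _as_finite(self.le, "le")
        _as_finite(self.he, "he")


@dataclass(frozen=True)
class MaterialLineProjection:
    """Contrast-material components (HU) of a voxel, on the material line."""

    le_cm: ArrayLike
    he_cm: ArrayLike


@dataclass(frozen=True)
class DecompositionParams:
    """Parameters of the corrected two-material decomposition.

    Parameters
    ----------
    der : dual-energy ratio, dimensionless, > 1.
    w : vendor weighting blending the low/high contrast components, in [0, 1].
    delta_base : base-material CT-number mismatch HE_base - LE_base, in HU.
    alpha : concentration scaling factor, HU per mg/mL, > 0.
    """

    der: float
    w: float
    delta_base: float
    alpha: float

    def __post_init__(self) -> None:
        _check_der(self.der)
        _check_w(self.w)
        _as_finite(self.delta_base, "delta_base")
        alpha = _as_finite(self.alpha, "alpha")
        if np.any(alpha <= 0.0):
            raise InvalidParameterError(f"alpha must be positive, got {self.alpha!r}")


@dataclass(frozen=True)
class ConcentrationResult:
    """A concentration-map value (HU) with its concentration (mg/mL)."""

    cm_hu: ArrayLike
    concentration: ArrayLike


def _blend(der: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Scale factor ``DER*w + 1 - w`` blending LE_CM and HE_CM into the CM."""
    return der * w + 1.0 - w


def project_to_material_line(v: VoxelPair, der: ArrayLike) -> MaterialLineProjection:
    """Project a voxel onto the material line parallel to the water line.

    The displacement from the voxel to its projection has equal LE and HE
    components (slope-1 direction), so the base-material part cancels and

        HE_CM = (LE - HE) / (DER - 1),    LE_CM = DER * HE_CM.
    """
    der = _check_der(der)
    le = _as_finite(v.le, "le")
    he = _as_finite(v.he, "he")
    he_cm = (le - he) / (der - 1.0)
    return MaterialLineProjection(le_cm=der * he_cm, he_cm=he_cm)


def cm_measured(v: VoxelPair, der: ArrayLike, w: ArrayLike) -> ArrayLike:
    """Uncorrected concentration-map value ``w*LE_CM + (1-w)*HE_CM`` in HU.

    Equals ``(DER*w + 1 - w) * (LE - HE) / (DER - 1)``; zero on the water
    line (LE = HE) for any DER and w.
    """
    der = _check_der(der)
    w = _check_w(w)
    le = _as_finite(v.le, "le")
    he = _as_finite(v.he, "he")
    return _blend(der, w) * (le - he) / (der - 1.0)


def cm_corrected(v: VoxelPair, p: DecompositionParams) -> ArrayLike:
    """Concentration-map value with the base-material mismatch cancelled.

    Adds ``delta_base = HE_base - LE_base`` to the LE - HE difference so a
    pure-base voxel maps to exactly 0 HU:

        CM_corrected = (DER*w + 1 - w) * (LE - HE + delta_base) / (DER - 1)
    """
    le = _as_finite(v.le, "le")
    he = _as_finite(v.he, "he")
    return _blend(p.der, p.w) * (le - he + p.delta_base) / (p.der - 1.0)


def concentration_from_cm(cm_hu: ArrayLike, alpha: float) -> ArrayLike:
    """Convert concentration-map HU to mg/mL: ``C = CM / alpha``."""
    alpha = _as_finite(alpha, "alpha")
    if np.any(alpha <= 0.0):
        raise InvalidParameterError(f"alpha must be positive, got {alpha!r}")
    return _as_finite(cm_hu, "cm_hu") / alpha


def mean_method_concentration(cm_measured_hu: ArrayLike, p) -> ArrayLike:
    """Concentration (mg/mL) from an *uncorrected* CM value via the mean method.

    ``p`` is any object with attributes ``der_avg``, ``w``, ``delta_base_avg``
    and ``alpha_avg`` (per material and tube voltage; see
    :class:`spectralcal.calibration.MeanMethodParams`).  The mismatch
    correction is applied additively in CM space, then scaled:

        C = (CM_measured + (DER_avg*w + 1 - w) * delta_base_avg / (DER_avg - 1)) / alpha_avg

    Algebraically identical to ``concentration_from_cm(cm_corrected(...))``
    when the CM value came from :func:`cm_measured` with the same DER and w.
    """
    der = _check_der(p.der_avg)
    w = _check_w(p.w)
    alpha = _as_finite(p.alpha_avg, "alpha_avg")
    if np.any(alpha <= 0.0):
        raise InvalidParameterError(f"alpha_avg must be positive, got {alpha!r}")
    delta = _as_finite(p.delta_base_avg, "delta_base_avg")
    cm = _as_finite(cm_measured_hu, "cm_measured_hu")
    return (cm + _blend(der, w) * delta / (der - 1.0)) / alpha


def relative_error(c_measured: ArrayLike, c_true: ArrayLike) -> ArrayLike:
    """Signed percent error ``(C_measured - C_true) / C_true * 100``.

    Raises
    ------
    ZeroTrueConcentrationError
        If any true concentration is zero (the error is undefined there;
        callers exclude such rods rather than receive a number).
    """
    c_true = _as_finite(c_true, "c_true")
    if np.any(c_true == 0.0):
        raise ZeroTrueConcentrationError(
            "relative error is undefined for a true concentration of 0 mg/mL"
        )
    c_measured = _as_finite(c_measured, "c_measured")
    return (c_measured - c_true) / c_true * 100.0
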