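"""Image-level plumbing: load paired energy volumes, measure circular ROIs.

Coordinate convention: in-plane positions are in millimetres with the origin
at the centre of the first pixel, x along columns and y along rows.  ROI
centres are specified in mm (not indices) so a specification survives
resampling.  Pixel membership in a circular ROI is decided by the pixel
centre, which keeps selection deterministic and identical across the two
energy channels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .calibration import RoiMeasurement
from .errors import EmptyRoiError, GeometryError, MetadataError

__all__ = [
    "SpectralImagePair",
    "RoiSpec",
    "load_image_pair",
    "write_fixture_pair",
    "roi_mean",
    "extract_measurements",
]


@dataclass
class SpectralImagePair:
    """Co-registered low/high-energy HU volumes sharing one geometry.

    Arrays are 2-D ``(ny, nx)`` or 3-D ``(nz, ny, nx)``; ``pixel_spacing``
    is the isotropic in-plane spacing in mm.  ``metadata`` carries the
    acquisition labels (material, kv, dose_pct, fat_ring) that propagate
    into ROI measurement tables.
    """

    low: np.ndarray
    high: np.ndarray
    pixel_spacing: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.low = np.asarray(self.low, dtype=float)
        self.high = np.asarray(self.high, dtype=float)
        if self.low.shape != self.high.shape:
            raise GeometryError(
                f"energy channels differ in shape: {self.low.shape} vs {self.high.shape}"
            )
        if self.low.ndim not in (2, 3):
            raise GeometryError(f"expected 2-D or 3-D volumes, got {self.low.ndim}-D")
        if not (self.pixel_spacing > 0):
            raise GeometryError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")


@dataclass(frozen=True)
class RoiSpec:
    """Circular ROI: centre (x, y) in mm, area in cm², optional slice range.

    ``slices`` selects the z extent for 3-D volumes: ``None`` uses the
    central slice, an int a single slice, and a ``(start, stop)`` pair an
    inclusive range whose per-slice means are averaged with equal weights.
    """

    center: tuple[float, float]
    area_cm2: float = 4.0
    slices: int | tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (self.area_cm2 > 0):
            raise GeometryError(f"ROI area must be > 0 cm², got {self.area_cm2}")

    @property
    def radius_mm(self) -> float:
        # 1 cm² = 100 mm²; 4 cm² gives radius ~11.28 mm
        return math.sqrt(self.area_cm2 * 100.0 / math.pi)


# ---------------------------------------------------------------------------
# Loading


def load_image_pair(
    low_path: str | Path, high_path: str | Path, metadata: dict | None = None
) -> SpectralImagePair:
    """Load a paired low/high-energy volume from disk.

    Supported per-channel formats, detected from the path:

    - NIfTI file (``.nii`` / ``.nii.gz``), read with nibabel; voxel values
      are taken as HU already.
    - DICOM series directory, read with pydicom; slices are sorted by
      instance number and rescale slope/intercept applied.
    - Raw-array fixture: a ``.npy`` array plus a JSON sidecar ``<stem>.json``
      with ``pixel_spacing_mm`` and optional ``metadata`` (the format the
      synthetic phantom writer emits).

    Explicit ``metadata`` overrides anything found in sidecars.
    """
    low, sp_low, meta_low = _load_channel(Path(low_path))
    high, sp_high, meta_high = _load_channel(Path(high_path))
    if low.shape != high.shape:
        raise GeometryError(
            f"energy channels differ in shape: {low.shape} vs {high.shape}"
        )
    if not math.isclose(sp_low, sp_high, rel_tol=1e-6):
        raise GeometryError(
            f"energy channels differ in pixel spacing: {sp_low} vs {sp_high} mm"
        )
    merged = {**meta_low, **meta_high, **(metadata or {})}
    return SpectralImagePair(low=low, high=high, pixel_spacing=sp_low, metadata=merged)


def _load_channel(path: Path) -> tuple[np.ndarray, float, dict]:
    if not path.exists():
        raise FileNotFoundError(f"image path does not exist: {path}")
    if path.is_dir():
        return _load_dicom_series(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return _load_nifti(path)
    if name.endswith(".npy"):
        return _load_fixture(path)
    raise MetadataError(f"unrecognized image format: {path}")


def _load_nifti(path: Path) -> tuple[np.ndarray, float, dict]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()
    sx, sy = float(zooms[0]), float(zooms[1])
    if not math.isclose(sx, sy, rel_tol=1e-6):
        raise GeometryError(f"anisotropic in-plane spacing {sx} x {sy} mm not supported")
    # nibabel axes are (x, y[, z]); reorder to (z, y, x) / (y, x)
    data = data.T
    return data, sx, {}


def _load_dicom_series(path: Path) -> tuple[np.ndarray, float, dict]:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise MetadataError(f"no .dcm files in directory {path}")
    slices = []
    spacing = None
    for f in files:
        ds = pydicom.dcmread(str(f))
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise MetadataError(f"{f}: missing rescale slope/intercept")
        sx, sy = (float(v) for v in ds.PixelSpacing)
        if not math.isclose(sx, sy, rel_tol=1e-6):
            raise GeometryError(f"{f}: anisotropic pixel spacing {sx} x {sy}")
        if spacing is None:
            spacing = sx
        elif not math.isclose(spacing, sx, rel_tol=1e-6):
            raise GeometryError(f"{f}: inconsistent pixel spacing within series")
        hu = ds.pixel_array.astype(float) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        slices.append((int(getattr(ds, "InstanceNumber", len(slices))), hu))
    slices.sort(key=lambda t: t[0])
    vol = np.stack([s[1] for s in slices], axis=0)
    if vol.shape[0] == 1:
        vol = vol[0]
    return vol, float(spacing), {}


def _load_fixture(path: Path) -> tuple[np.ndarray, float, dict]:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise MetadataError(f"fixture {path} has no JSON sidecar {sidecar}")
    info = json.loads(sidecar.read_text())
    if "pixel_spacing_mm" not in info:
        raise MetadataError(f"{sidecar}: missing pixel_spacing_mm")
    data = np.load(path)
    return np.asarray(data, dtype=float), float(info["pixel_spacing_mm"]), dict(
        info.get("metadata", {})
    )


def write_fixture_pair(pair: SpectralImagePair, directory: str | Path) -> dict:
    """Write a pair in the raw-array fixture format; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (("low", pair.low), ("high", pair.high)):
        npy = directory / f"{name}.npy"
        np.save(npy, arr)
        sidecar = {
            "pixel_spacing_mm": pair.pixel_spacing,
            "metadata": pair.metadata,
        }
        npy.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        paths[name] = str(npy)
    return paths


# ---------------------------------------------------------------------------
# ROI measurement


def _circle_mask(
    shape: tuple[int, int], spacing: float, center: tuple[float, float], radius: float
) -> np.ndarray:
    ny, nx = shape
    cx, cy = center
    y = np.arange(ny) * spacing
    x = np.arange(nx) * spacing
    dx2 = (x - cx) ** 2
    dy2 = (y - cy) ** 2
    return dy2[:, None] + dx2[None, :] <= radius**2


def _resolve_slices(roi: RoiSpec, nz: int) -> list[int]:
    if roi.slices is None:
        return [nz // 2]
    if isinstance(roi.slices, int):
        idx = [roi.slices]
    else:
        start, stop = roi.slices
        idx = list(range(start, stop + 1))
    for i in idx:
        if not (0 <= i < nz):
            raise GeometryError(f"slice index {i} outside volume of {nz} slices")
    return idx


def roi_mean(pair: SpectralImagePair, roi: RoiSpec) -> tuple[float, float, int]:
    """Mean HU of both channels over a circular ROI.

    Returns ``(le_mean, he_mean, n_pixels)`` where ``n_pixels`` counts the
    in-plane pixels whose centres fall inside the circle.  For 3-D volumes
    the per-slice means over the ROI's slice range are averaged with equal
    weights.  The pixel set is identical for both energies by construction.
    """
    shape2d = pair.low.shape[-2:]
    spacing = pair.pixel_spacing
    cx, cy = roi.center
    r = roi.radius_mm
    extent_x = (shape2d[1] - 0.5) * spacing
    extent_y = (shape2d[0] - 0.5) * spacing
    if cx - r < -0.5 * spacing or cy - r < -0.5 * spacing or cx + r > extent_x or cy + r > extent_y:
        raise GeometryError(
            f"ROI (centre {roi.center} mm, radius {r:.2f} mm) exceeds image bounds"
        )
    mask = _circle_mask(shape2d, spacing, (cx, cy), r)
    n = int(mask.sum())
    if n == 0:
        raise EmptyRoiError(f"ROI at {roi.center} mm selected zero pixels")

    if pair.low.ndim == 2:
        return float(pair.low[mask].mean()), float(pair.high[mask].mean()), n
    idx = _resolve_slices(roi, pair.low.shape[0])
    le = float(np.mean([pair.low[k][mask].mean() for k in idx]))
    he = float(np.mean([pair.high[k][mask].mean() for k in idx]))
    return le, he, n


def extract_measurements(
    pair: SpectralImagePair, rois: Iterable[tuple[RoiSpec, float]]
) -> list[RoiMeasurement]:
    """Measure a list of ``(RoiSpec, known_concentration)`` rods.

    Acquisition metadata (material, kv, dose_pct, fat_ring) is copied from
    the image pair onto every measurement.
    """
    meta = pair.metadata
    out = []
    for roi, concentration in rois:
        le, he, _ = roi_mean(pair, roi)
        out.append(
            RoiMeasurement(
                le_mean=le,
                he_mean=he,
                concentration=float(concentration),
                material=str(meta.get("material", "unknown")),
                kv=str(meta.get("kv", "unknown")),
                dose_pct=float(meta.get("dose_pct", 100.0)),
                fat_ring=bool(meta.get("fat_ring", False)),
            )
        )
    return out
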