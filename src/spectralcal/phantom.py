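"""Synthetic spectral phantom generator with exact ground truth.

Emulates an abdomen-sized spectral QA phantom: an elliptical body of base
material (water- or liver-equivalent), an optional outer fat ring simulating
a larger habitus, and cylindrical rods (20 mm diameter) holding known
contrast-material concentrations.  Rod CT numbers follow the linear spectral
model

    LE(C) = LE_base + s_low * C
    HE(C) = HE_base + (s_low / DER) * C

with ``s_low`` the low-energy HU response per mg/mL and DER the true
dual-energy ratio, so a noiseless phantom round-trips exactly through
calibration.  Noise is independent additive Gaussian per energy channel,
with standard deviation scaled by ``1/sqrt(dose fraction)``; no streaks,
correlations or partial-volume effects are simulated.

The default study replicates a 12-configuration design per material:
two tube voltages (with distinct true DERs), three dose levels and two
fat-ring states.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibration import RoiMeasurement
from .errors import PhantomSpecError
from .roi import RoiSpec, SpectralImagePair, write_fixture_pair

__all__ = [
    "MaterialTruth",
    "RodSpec",
    "PhantomSpec",
    "GroundTruthManifest",
    "generate_phantom",
    "synthetic_measurements",
    "default_truth",
    "default_rods",
    "default_spec",
    "build_study_specs",
    "generate_study",
    "study_roi_specs",
    "IODINE_CONCENTRATIONS",
    "IRON_CONCENTRATIONS",
    "STUDY_KVS",
    "STUDY_DOSES",
    "DEFAULT_ROI_AREA_CM2",
]

#: Rod concentrations of the two insert sets (mg/mL).
IODINE_CONCENTRATIONS = (0.5, 1.0, 2.0, 5.0, 10.0, 15.0)
IRON_CONCENTRATIONS = (2.0, 5.0, 15.0, 25.0)

STUDY_KVS = ("140", "120")
STUDY_DOSES = (100.0, 120.0, 200.0)

#: Default ROI area for synthetic rods.  A circular 4 cm² ROI (radius
#: 11.28 mm) does not fit inside a 20 mm rod (cross-section 3.14 cm²), so
#: synthetic extraction uses 2 cm² (radius 7.98 mm), comfortably inside.
DEFAULT_ROI_AREA_CM2 = 2.0


@dataclass(frozen=True)
class MaterialTruth:
    """True spectral parameters of one contrast material in its base."""

    hu_per_conc_low: float  # HU per mg/mL in the low-energy image
    true_der: float  # dimensionless, > 1
    le_base: float  # base-material low-energy HU
    he_base: float  # base-material high-energy HU

    def __post_init__(self) -> None:
        if self.true_der <= 1.0:
            raise PhantomSpecError(f"true_der must exceed 1, got {self.true_der}")
        if self.hu_per_conc_low <= 0.0:
            raise PhantomSpecError("hu_per_conc_low must be positive")

    @property
    def hu_per_conc_high(self) -> float:
        return self.hu_per_conc_low / self.true_der

    @property
    def delta_base(self) -> float:
        return self.he_base - self.le_base

    def implied_alpha(self, w: float) -> float:
        """Alpha that a calibration run with weighting ``w`` recovers.

        For rods on the linear model, the corrected CM equals
        ``(DER*w + 1 - w) * (s_low / DER) * C``, so alpha is that slope.
        """
        return (self.true_der * w + 1.0 - w) * self.hu_per_conc_high

    def rod_hu(self, concentration: float) -> tuple[float, float]:
        """Noiseless (LE, HE) of a rod at the given concentration."""
        le = self.le_base + self.hu_per_conc_low * concentration
        he = self.he_base + self.hu_per_conc_high * concentration
        return le, he


@dataclass(frozen=True)
class RodSpec:
    """One cylindrical insert: centre (x, y) mm relative to body centre."""

    center: tuple[float, float]
    concentration: float
    diameter_mm: float = 20.0


@dataclass
class PhantomSpec:
    """Full description of one synthetic phantom acquisition."""

    material: str
    kv: str
    truth: MaterialTruth
    rods: list[RodSpec]
    dose_pct: float = 100.0
    fat_ring: bool = False
    body_axes: tuple[float, float] = (150.0, 100.0)  # half-axes, mm
    fat_ring_axes: tuple[float, float] = (175.0, 125.0)
    fat_hu: tuple[float, float] = (-115.0, -95.0)  # (LE, HE) of the ring
    noise_sd: tuple[float, float] = (15.0, 10.0)  # (LE, HE) HU at 100% dose
    shape: tuple[int, int] = (256, 256)
    pixel_spacing: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.noise_sd) < 0:
            raise PhantomSpecError("noise SDs must be >= 0")
        a, b = self.body_axes
        for rod in self.rods:
            x, y = rod.center
            r = rod.diameter_mm / 2.0
            if (x / (a - r)) ** 2 + (y / (b - r)) ** 2 > 1.0:
                raise PhantomSpecError(
                    f"rod at {rod.center} mm (r={r} mm) not fully inside body "
                    f"ellipse with half-axes {self.body_axes} mm"
                )
        for i, r1 in enumerate(self.rods):
            for r2 in self.rods[i + 1 :]:
                d = math.dist(r1.center, r2.center)
                if d < (r1.diameter_mm + r2.diameter_mm) / 2.0:
                    raise PhantomSpecError(
                        f"rods at {r1.center} and {r2.center} mm overlap"
                    )
        if self.fat_ring:
            fa, fb = self.fat_ring_axes
            if fa <= a or fb <= b:
                raise PhantomSpecError("fat ring axes must exceed body axes")

    @property
    def effective_noise_sd(self) -> tuple[float, float]:
        """Channel noise SD after dose scaling (SD ∝ 1/sqrt(dose fraction))."""
        scale = 1.0 / math.sqrt(self.dose_pct / 100.0)
        return (self.noise_sd[0] * scale, self.noise_sd[1] * scale)

    @property
    def metadata(self) -> dict:
        return {
            "material": self.material,
            "kv": self.kv,
            "dose_pct": self.dose_pct,
            "fat_ring": self.fat_ring,
        }


@dataclass
class GroundTruthManifest:
    """Exact noiseless truth of a generated phantom, for validation."""

    material: str
    kv: str
    dose_pct: float
    fat_ring: bool
    true_der: float
    le_base: float
    he_base: float
    delta_base: float
    hu_per_conc_low: float
    noise_sd_effective: tuple[float, float]
    seed: int
    rods: list[dict] = field(default_factory=list)  # center_mm, concentration, le_hu, he_hu

    def implied_alpha(self, w: float) -> float:
        return (self.true_der * w + 1.0 - w) * (self.hu_per_conc_low / self.true_der)


# ---------------------------------------------------------------------------
# Generation


def _ellipse_mask(shape, spacing, center_mm, half_axes) -> np.ndarray:
    ny, nx = shape
    cx, cy = center_mm
    a, b = half_axes
    y = np.arange(ny) * spacing
    x = np.arange(nx) * spacing
    xv = (x - cx) / a
    yv = (y - cy) / b
    return yv[:, None] ** 2 + xv[None, :] ** 2 <= 1.0


def _circle_mask_img(shape, spacing, center_mm, radius) -> np.ndarray:
    ny, nx = shape
    cx, cy = center_mm
    y = np.arange(ny) * spacing
    x = np.arange(nx) * spacing
    dy2 = (y - cy) ** 2
    dx2 = (x - cx) ** 2
    return dy2[:, None] + dx2[None, :] <= radius**2


def generate_phantom(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[SpectralImagePair, GroundTruthManifest]:
    """Rasterize one phantom acquisition and return it with its ground truth.

    Pixel membership is decided by pixel centres (air background at
    -1000 HU, then fat ring, body, rods painted in that order).  Gaussian
    noise with the spec's dose-scaled SDs is added using ``rng`` (or a
    generator seeded from ``spec.seed``).  The manifest records the exact
    noiseless rod values and absolute ROI centres in image coordinates.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape
    sp = spec.pixel_spacing
    center = ((nx - 1) / 2.0 * sp, (ny - 1) / 2.0 * sp)

    low = np.full(spec.shape, -1000.0)
    high = np.full(spec.shape, -1000.0)
    if spec.fat_ring:
        ring = _ellipse_mask(spec.shape, sp, center, spec.fat_ring_axes)
        low[ring], high[ring] = spec.fat_hu
    body = _ellipse_mask(spec.shape, sp, center, spec.body_axes)
    low[body] = spec.truth.le_base
    high[body] = spec.truth.he_base

    manifest_rods = []
    for rod in spec.rods:
        abs_center = (center[0] + rod.center[0], center[1] + rod.center[1])
        mask = _circle_mask_img(spec.shape, sp, abs_center, rod.diameter_mm / 2.0)
        le, he = spec.truth.rod_hu(rod.concentration)
        low[mask] = le
        high[mask] = he
        manifest_rods.append(
            {
                "center_mm": list(abs_center),
                "concentration": rod.concentration,
                "le_hu": le,
                "he_hu": he,
            }
        )

    sd_le, sd_he = spec.effective_noise_sd
    if sd_le > 0:
        low = low + rng.normal(0.0, sd_le, size=spec.shape)
    if sd_he > 0:
        high = high + rng.normal(0.0, sd_he, size=spec.shape)

    pair = SpectralImagePair(
        low=low, high=high, pixel_spacing=sp, metadata=spec.metadata
    )
    manifest = GroundTruthManifest(
        material=spec.material,
        kv=spec.kv,
        dose_pct=spec.dose_pct,
        fat_ring=spec.fat_ring,
        true_der=spec.truth.true_der,
        le_base=spec.truth.le_base,
        he_base=spec.truth.he_base,
        delta_base=spec.truth.delta_base,
        hu_per_conc_low=spec.truth.hu_per_conc_low,
        noise_sd_effective=(sd_le, sd_he),
        seed=spec.seed,
        rods=manifest_rods,
    )
    return pair, manifest


def synthetic_measurements(
    truth: MaterialTruth,
    concentrations: Sequence[float],
    material: str,
    kv: str,
    dose_pct: float = 100.0,
    fat_ring: bool = False,
    noise_sd: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> list[RoiMeasurement]:
    """Rod-level synthetic ROI measurements without rasterizing images.

    Gaussian noise (``noise_sd`` per channel, in HU) is added directly to
    the noiseless rod means — the fast path for Monte-Carlo studies of the
    calibration fits.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    for c in concentrations:
        le, he = truth.rod_hu(c)
        if noise_sd[0] > 0:
            le += rng.normal(0.0, noise_sd[0])
        if noise_sd[1] > 0:
            he += rng.normal(0.0, noise_sd[1])
        out.append(
            RoiMeasurement(
                le_mean=le,
                he_mean=he,
                concentration=c,
                material=material,
                kv=kv,
                dose_pct=dose_pct,
                fat_ring=fat_ring,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Default study design


def default_truth(material: str, kv: str) -> MaterialTruth:
    """True spectral parameters per material and tube voltage.

    DER magnitudes and base offsets are typical of a clinical
    photon-counting system (iodine DER near 2.1 at 120 kV and 2.5 at
    140 kV, iron lower; water base a few HU below zero, liver-equivalent
    base around 50 HU with the high-energy channel reading lower).
    """
    if material == "iodine":
        der = {"120": 2.10, "140": 2.49}[str(kv)]
        return MaterialTruth(
            hu_per_conc_low=26.3, true_der=der, le_base=-2.0, he_base=-7.0
        )
    if material == "iron":
        der = {"120": 1.93, "140": 2.18}[str(kv)]
        return MaterialTruth(
            hu_per_conc_low=8.0, true_der=der, le_base=54.0, he_base=50.0
        )
    raise PhantomSpecError(f"unknown material {material!r}; expected iodine or iron")


def default_rods(material: str) -> list[RodSpec]:
    """Rod layout: 20 mm rods on a 60 mm circle around the body centre."""
    if material == "iodine":
        concentrations = IODINE_CONCENTRATIONS
    elif material == "iron":
        concentrations = IRON_CONCENTRATIONS
    else:
        raise PhantomSpecError(f"unknown material {material!r}")
    n = len(concentrations)
    radius = 60.0
    rods = []
    for i, c in enumerate(concentrations):
        theta = 2.0 * math.pi * i / n
        rods.append(
            RodSpec(
                center=(radius * math.cos(theta), radius * math.sin(theta)),
                concentration=c,
            )
        )
    return rods


def default_spec(
    material: str,
    kv: str = "120",
    dose_pct: float = 100.0,
    fat_ring: bool = False,
    noise_sd: tuple[float, float] = (15.0, 10.0),
    seed: int = 0,
) -> PhantomSpec:
    """One configuration of the default study design."""
    return PhantomSpec(
        material=material,
        kv=str(kv),
        truth=default_truth(material, kv),
        rods=default_rods(material),
        dose_pct=dose_pct,
        fat_ring=fat_ring,
        noise_sd=noise_sd,
        seed=seed,
    )


def build_study_specs(
    material: str,
    seed: int = 0,
    noise_sd: tuple[float, float] = (15.0, 10.0),
) -> list[PhantomSpec]:
    """12-configuration design: 2 kV x 3 dose levels x 2 fat-ring states.

    Each configuration gets its own child seed derived from ``seed`` so the
    study is reproducible while configurations stay independent.
    """
    children = np.random.SeedSequence(seed).spawn(len(STUDY_KVS) * len(STUDY_DOSES) * 2)
    specs = []
    i = 0
    for kv in STUDY_KVS:
        for dose in STUDY_DOSES:
            for ring in (False, True):
                specs.append(
                    default_spec(
                        material,
                        kv=kv,
                        dose_pct=dose,
                        fat_ring=ring,
                        noise_sd=noise_sd,
                        seed=int(children[i].generate_state(1)[0] % (2**31)),
                    )
                )
                i += 1
    return specs


def _config_name(spec: PhantomSpec) -> str:
    ring = "ring" if spec.fat_ring else "noring"
    return f"{spec.material}_{spec.kv}kv_{int(spec.dose_pct)}pct_{ring}"


def generate_study(
    out_dir: str | Path,
    materials: Sequence[str] = ("iodine", "iron"),
    seed: int = 0,
    noise_sd: tuple[float, float] = (15.0, 10.0),
) -> dict:
    """Materialize the full study on disk; returns the study manifest.

    Layout: one directory per configuration holding ``low.npy``,
    ``high.npy``, their JSON sidecars and ``manifest.json``; a top-level
    ``study.json`` lists all configurations.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for m_idx, material in enumerate(materials):
        specs = build_study_specs(material, seed=seed + m_idx, noise_sd=noise_sd)
        for spec in specs:
            pair, manifest = generate_phantom(spec)
            cfg_dir = out_dir / _config_name(spec)
            write_fixture_pair(pair, cfg_dir)
            (cfg_dir / "manifest.json").write_text(
                json.dumps(asdict(manifest), indent=2)
            )
            entries.append(
                {
                    "name": _config_name(spec),
                    "dir": str(cfg_dir.relative_to(out_dir)),
                    **spec.metadata,
                }
            )
    study = {"seed": seed, "noise_sd": list(noise_sd), "configurations": entries}
    (out_dir / "study.json").write_text(json.dumps(study, indent=2))
    return study


def study_roi_specs(
    manifest: GroundTruthManifest | dict, area_cm2: float = DEFAULT_ROI_AREA_CM2
) -> list[tuple[RoiSpec, float]]:
    """ROI specifications (centre + known concentration) from a manifest."""
    rods = manifest["rods"] if isinstance(manifest, dict) else manifest.rods
    return [
        (RoiSpec(center=tuple(r["center_mm"]), area_cm2=area_cm2), r["concentration"])
        for r in rods
    ]
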