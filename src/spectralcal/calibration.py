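"""Phantom-based calibration of the two-material decomposition.

Given ROI-mean CT numbers of phantom rods with known contrast-material
concentrations, three ordinary-least-squares fits per scan configuration
estimate the decomposition parameters:

1. *Base intercepts*: LE and HE each regressed on concentration; the
   y-intercepts are the base-material CT numbers LE_base and HE_base, and
   ``delta_base = HE_base - LE_base``.
2. *Dual-energy ratio*: LE regressed on HE (free intercept); the slope is
   the DER.  The material line is the steeper of the two lines in the
   (HE, LE) plane, so the slope exceeds 1 for iodine and iron.
3. *Concentration scaling*: corrected CM values (using the fitted DER and
   delta_base) regressed on known concentration; the slope is alpha in
   HU per mg/mL.  The intercept should be near 0 after the delta_base
   correction and is kept as a QC diagnostic.

Per-configuration results are then averaged per (material, tube voltage)
across dose levels and fat-ring states — the "mean method" — and those
averages drive the concentration conversion of
:func:`spectralcal.core.mean_method_concentration`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import core
from .core import DecompositionParams, VoxelPair
from .errors import InconsistentGroupError, InsufficientDataError

__all__ = [
    "RoiMeasurement",
    "FitDiagnostics",
    "CalibrationRecord",
    "MeanMethodParams",
    "TABLE_COLUMNS",
    "read_roi_table",
    "write_roi_table",
    "measurements_from_frame",
    "measurements_to_frame",
    "fit_base_intercepts",
    "fit_der",
    "fit_alpha",
    "calibrate_configuration",
    "calibrate_table",
    "aggregate_mean_method",
    "aggregate_table",
    "quantify_with_mean_method",
    "records_to_frame",
    "records_from_frame",
    "save_records",
    "load_records",
    "save_params",
    "load_params",
]

#: Mandatory column schema of the delimited ROI measurement table.
TABLE_COLUMNS = [
    "material",
    "kv",
    "dose_pct",
    "fat_ring",
    "concentration_mg_ml",
    "le_hu",
    "he_hu",
]

#: Columns identifying one scan configuration.
CONFIG_KEYS = ["material", "kv", "dose_pct", "fat_ring"]


@dataclass(frozen=True)
class RoiMeasurement:
    """Rod-level ROI means with the rod's known concentration and metadata."""

    le_mean: float
    he_mean: float
    concentration: float
    material: str
    kv: str
    dose_pct: float = 100.0
    fat_ring: bool = False

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("known concentration must be >= 0 mg/mL")
        if not self.material or not str(self.kv):
            raise ValueError("material and kv labels must be non-empty")


@dataclass(frozen=True)
class FitDiagnostics:
    """OLS diagnostics for one calibration fit."""

    slope: float
    intercept: float
    r_squared: float
    residual_se: float
    n: int


@dataclass(frozen=True)
class CalibrationRecord:
    """Calibrated (delta_base, DER, alpha) for one scan configuration."""

    material: str
    kv: str
    dose_pct: float
    fat_ring: bool
    le_base: float
    he_base: float
    delta_base: float
    der: float
    alpha: float
    w: float = 0.5
    n_rods: int = 0
    diagnostics: dict[str, FitDiagnostics] = field(default_factory=dict)


@dataclass(frozen=True)
class MeanMethodParams:
    """Per-(material, kV) averages driving the mean-method correction."""

    material: str
    kv: str
    delta_base_avg: float
    der_avg: float
    alpha_avg: float
    delta_base_sd: float
    der_sd: float
    alpha_sd: float
    n_configs: int
    w: float

    def __post_init__(self) -> None:
        if self.n_configs < 1:
            raise ValueError("n_configs must be >= 1")


# ---------------------------------------------------------------------------
# ROI table I/O


def measurements_to_frame(measurements: Iterable[RoiMeasurement]) -> pd.DataFrame:
    rows = [
        {
            "material": m.material,
            "kv": m.kv,
            "dose_pct": m.dose_pct,
            "fat_ring": m.fat_ring,
            "concentration_mg_ml": m.concentration,
            "le_hu": m.le_mean,
            "he_hu": m.he_mean,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def measurements_from_frame(frame: pd.DataFrame) -> list[RoiMeasurement]:
    missing = [c for c in TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"ROI table missing required columns: {missing}")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            RoiMeasurement(
                le_mean=float(row.le_hu),
                he_mean=float(row.he_hu),
                concentration=float(row.concentration_mg_ml),
                material=str(row.material),
                kv=str(row.kv),
                dose_pct=float(row.dose_pct),
                fat_ring=_parse_bool(row.fat_ring),
            )
        )
    return out


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes", "with"):
        return True
    if s in ("false", "0", "no", "without"):
        return False
    raise ValueError(f"cannot interpret fat_ring value {x!r} as boolean")


def read_roi_table(path: str | Path) -> list[RoiMeasurement]:
    """Read a comma-separated ROI measurement table (header mandatory)."""
    return measurements_from_frame(pd.read_csv(path, float_precision="round_trip"))


def write_roi_table(measurements: Iterable[RoiMeasurement], path: str | Path) -> None:
    # %.17g keeps the table lossless for float64 round-trips
    measurements_to_frame(measurements).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Fits


def _ols(x: np.ndarray, y: np.ndarray, what: str) -> FitDiagnostics:
    """Free-intercept OLS of y on x; exact-collinear input is an exact fit."""
    n = len(x)
    if n < 2 or np.ptp(x) == 0.0:
        raise InsufficientDataError(
            f"{what}: need >= 2 points with distinct predictor values (got n={n})"
        )
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    rse = math.sqrt(ss_res / (n - 2)) if n > 2 else 0.0
    return FitDiagnostics(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        residual_se=rse,
        n=n,
    )


def _arrays(measurements: Sequence[RoiMeasurement]):
    c = np.array([m.concentration for m in measurements], dtype=float)
    le = np.array([m.le_mean for m in measurements], dtype=float)
    he = np.array([m.he_mean for m in measurements], dtype=float)
    return c, le, he


def _require_distinct_concentrations(c: np.ndarray) -> None:
    if len(np.unique(c)) < 2:
        raise InsufficientDataError(
            "calibration needs measurements at >= 2 distinct concentrations"
        )


def fit_base_intercepts(
    measurements: Sequence[RoiMeasurement],
) -> tuple[float, float, float]:
    """Fit LE and HE vs concentration; return (le_base, he_base, delta_base).

    The intercepts are the base-material CT numbers at zero contrast
    concentration; ``delta_base = he_base - le_base`` is the sign for which
    the corrected CM of a pure-base voxel is exactly zero.
    """
    c, le, he = _arrays(measurements)
    _require_distinct_concentrations(c)
    le_fit = _ols(c, le, "low-energy HU vs concentration")
    he_fit = _ols(c, he, "high-energy HU vs concentration")
    return le_fit.intercept, he_fit.intercept, he_fit.intercept - le_fit.intercept


def fit_der(measurements: Sequence[RoiMeasurement]) -> float:
    """Dual-energy ratio: slope of the free-intercept fit of LE on HE.

    Orientation: the material line is ``LE = DER * HE`` with DER > 1, so the
    low-energy values are the response and the high-energy values the
    predictor.
    """
    c, le, he = _arrays(measurements)
    _require_distinct_concentrations(c)
    return _ols(he, le, "low-energy HU vs high-energy HU").slope


def fit_alpha(
    measurements: Sequence[RoiMeasurement],
    der: float,
    w: float,
    delta_base: float,
) -> float:
    """Concentration scaling: slope of corrected CM vs known concentration.

    Corrected CM values are computed from each rod's ROI means with the
    supplied DER, w and delta_base; alpha carries units HU per mg/mL, so it
    is the slope of CM (HU) regressed on concentration (mg/mL).
    """
    c, le, he = _arrays(measurements)
    _require_distinct_concentrations(c)
    params = DecompositionParams(der=der, w=w, delta_base=delta_base, alpha=1.0)
    cm = np.asarray(core.cm_corrected(VoxelPair(le=le, he=he), params))
    return _ols(c, cm, "corrected CM vs concentration").slope


def _single_configuration(measurements: Sequence[RoiMeasurement]) -> tuple:
    keys = {(m.material, m.kv, m.dose_pct, m.fat_ring) for m in measurements}
    if len(keys) != 1:
        raise InconsistentGroupError(
            f"measurements span {len(keys)} configurations; expected exactly one"
        )
    return keys.pop()


def calibrate_configuration(
    measurements: Sequence[RoiMeasurement], w: float = 0.5
) -> CalibrationRecord:
    """Run the three calibration fits for one scan configuration."""
    if not measurements:
        raise InsufficientDataError("no measurements supplied")
    material, kv, dose_pct, fat_ring = _single_configuration(measurements)
    c, le, he = _arrays(measurements)
    _require_distinct_concentrations(c)

    le_fit = _ols(c, le, "low-energy HU vs concentration")
    he_fit = _ols(c, he, "high-energy HU vs concentration")
    le_base, he_base = le_fit.intercept, he_fit.intercept
    delta_base = he_base - le_base

    der_fit = _ols(he, le, "low-energy HU vs high-energy HU")
    der = der_fit.slope

    params = DecompositionParams(der=der, w=w, delta_base=delta_base, alpha=1.0)
    cm = np.asarray(core.cm_corrected(VoxelPair(le=le, he=he), params))
    alpha_fit = _ols(c, cm, "corrected CM vs concentration")

    return CalibrationRecord(
        material=material,
        kv=kv,
        dose_pct=dose_pct,
        fat_ring=fat_ring,
        le_base=le_base,
        he_base=he_base,
        delta_base=delta_base,
        der=der,
        alpha=alpha_fit.slope,
        w=w,
        n_rods=len(measurements),
        diagnostics={"le_base": le_fit, "he_base": he_fit, "der": der_fit, "alpha": alpha_fit},
    )


def calibrate_table(
    measurements: Sequence[RoiMeasurement] | pd.DataFrame, w: float = 0.5
) -> list[CalibrationRecord]:
    """Calibrate every (material, kV, dose, fat-ring) configuration in a table."""
    if isinstance(measurements, pd.DataFrame):
        measurements = measurements_from_frame(measurements)
    groups: dict[tuple, list[RoiMeasurement]] = {}
    for m in measurements:
        groups.setdefault((m.material, m.kv, m.dose_pct, m.fat_ring), []).append(m)
    return [calibrate_configuration(ms, w=w) for key, ms in sorted(groups.items())]


# ---------------------------------------------------------------------------
# Mean method


def aggregate_mean_method(
    records: Sequence[CalibrationRecord], w: float | None = None
) -> MeanMethodParams:
    """Average delta_base, DER and alpha across one (material, kV) group.

    Means are arithmetic; spreads are sample standard deviations (n - 1
    denominator), reported as 0 for a single record.
    """
    if not records:
        raise InsufficientDataError("no calibration records supplied")
    groups = {(r.material, r.kv) for r in records}
    if len(groups) != 1:
        raise InconsistentGroupError(
            f"records span {sorted(groups)}; aggregate per (material, kV) only"
        )
    material, kv = groups.pop()
    if w is None:
        ws = {r.w for r in records}
        if len(ws) != 1:
            raise InconsistentGroupError(
                "records were calibrated with different w; pass w explicitly"
            )
        w = ws.pop()

    def mean_sd(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        return float(np.mean(arr)), sd

    d_avg, d_sd = mean_sd([r.delta_base for r in records])
    der_avg, der_sd = mean_sd([r.der for r in records])
    a_avg, a_sd = mean_sd([r.alpha for r in records])
    return MeanMethodParams(
        material=material,
        kv=kv,
        delta_base_avg=d_avg,
        der_avg=der_avg,
        alpha_avg=a_avg,
        delta_base_sd=d_sd,
        der_sd=der_sd,
        alpha_sd=a_sd,
        n_configs=len(records),
        w=w,
    )


def aggregate_table(
    records: Sequence[CalibrationRecord], w: float | None = None
) -> list[MeanMethodParams]:
    """Aggregate a mixed list of records into one MeanMethodParams per group."""
    groups: dict[tuple, list[CalibrationRecord]] = {}
    for r in records:
        groups.setdefault((r.material, r.kv), []).append(r)
    return [aggregate_mean_method(rs, w=w) for key, rs in sorted(groups.items())]


def quantify_with_mean_method(
    measurements: Sequence[RoiMeasurement], params: MeanMethodParams
) -> pd.DataFrame:
    """Estimate rod concentrations with and without the mismatch correction.

    Returns one row per rod with the corrected estimate (mean method), the
    uncorrected variant (same formula with delta_base_avg = 0), and signed
    percent errors versus the known concentration.  Rods with a true
    concentration of 0 are still quantified but their error columns are NaN
    (relative error undefined).
    """
    c, le, he = _arrays(list(measurements))
    cm = np.asarray(
        core.cm_measured(VoxelPair(le=le, he=he), der=params.der_avg, w=params.w)
    )
    c_corr = np.asarray(core.mean_method_concentration(cm, params))
    uncorrected = MeanMethodParams(
        material=params.material,
        kv=params.kv,
        delta_base_avg=0.0,
        der_avg=params.der_avg,
        alpha_avg=params.alpha_avg,
        delta_base_sd=0.0,
        der_sd=params.der_sd,
        alpha_sd=params.alpha_sd,
        n_configs=params.n_configs,
        w=params.w,
    )
    c_unc = np.asarray(core.mean_method_concentration(cm, uncorrected))

    nonzero = c != 0.0
    err_corr = np.full_like(c, np.nan)
    err_unc = np.full_like(c, np.nan)
    if np.any(nonzero):
        err_corr[nonzero] = np.asarray(core.relative_error(c_corr[nonzero], c[nonzero]))
        err_unc[nonzero] = np.asarray(core.relative_error(c_unc[nonzero], c[nonzero]))

    frame = measurements_to_frame(measurements)
    frame["cm_measured_hu"] = cm
    frame["concentration_corrected"] = c_corr
    frame["concentration_uncorrected"] = c_unc
    frame["error_corrected_pct"] = err_corr
    frame["error_uncorrected_pct"] = err_unc
    return frame


# ---------------------------------------------------------------------------
# Record serialization (round-trippable key-value JSON + tabular reports)


def records_to_frame(records: Sequence[CalibrationRecord]) -> pd.DataFrame:
    """Tabular per-configuration report (one row per configuration)."""
    return pd.DataFrame(
        [
            {
                "material": r.material,
                "kv": r.kv,
                "dose_pct": r.dose_pct,
                "fat_ring": r.fat_ring,
                "delta_base": r.delta_base,
                "der": r.der,
                "alpha": r.alpha,
                "le_base": r.le_base,
                "he_base": r.he_base,
                "w": r.w,
                "n_rods": r.n_rods,
            }
            for r in records
        ]
    )


def records_from_frame(frame: pd.DataFrame, w: float = 0.5) -> list[CalibrationRecord]:
    """Build records from a table of pre-computed (delta_base, der, alpha).

    Accepts ROI-free calibration tables (e.g. values measured in vendor
    software); base intercepts and diagnostics default to NaN/empty.
    """
    required = CONFIG_KEYS + ["delta_base", "der", "alpha"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"calibration table missing columns: {missing}")
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        records.append(
            CalibrationRecord(
                material=str(d["material"]),
                kv=str(d["kv"]),
                dose_pct=float(d["dose_pct"]),
                fat_ring=_parse_bool(d["fat_ring"]),
                le_base=float(d.get("le_base", math.nan)),
                he_base=float(d.get("he_base", math.nan)),
                delta_base=float(d["delta_base"]),
                der=float(d["der"]),
                alpha=float(d["alpha"]),
                w=float(d.get("w", w)),
                n_rods=int(d.get("n_rods", 0)),
            )
        )
    return records


def save_records(records: Sequence[CalibrationRecord], path: str | Path) -> None:
    payload = []
    for r in records:
        d = asdict(r)
        d["diagnostics"] = {k: asdict(v) for k, v in r.diagnostics.items()}
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=2))


def load_records(path: str | Path) -> list[CalibrationRecord]:
    payload = json.loads(Path(path).read_text())
    records = []
    for d in payload:
        diag = {k: FitDiagnostics(**v) for k, v in d.pop("diagnostics", {}).items()}
        records.append(CalibrationRecord(**d, diagnostics=diag))
    return records


def save_params(params: Sequence[MeanMethodParams], path: str | Path) -> None:
    Path(path).write_text(json.dumps([asdict(p) for p in params], indent=2))


def load_params(path: str | Path) -> list[MeanMethodParams]:
    return [MeanMethodParams(**d) for d in json.loads(Path(path).read_text())]


def params_to_frame(
    params: Sequence[MeanMethodParams], digits: int | None = None
) -> pd.DataFrame:
    """Per-group summary report; with ``digits`` formats mean ± SD strings."""
    rows = []
    for p in params:
        if digits is None:
            rows.append(
                {
                    "material": p.material,
                    "kv": p.kv,
                    "delta_base_avg": p.delta_base_avg,
                    "delta_base_sd": p.delta_base_sd,
                    "der_avg": p.der_avg,
                    "der_sd": p.der_sd,
                    "alpha_avg": p.alpha_avg,
                    "alpha_sd": p.alpha_sd,
                    "n_configs": p.n_configs,
                    "w": p.w,
                }
            )
        else:
            fmt = f"{{:.{digits}f}} ± {{:.{digits}f}}".format
            rows.append(
                {
                    "material": p.material,
                    "kv": p.kv,
                    "delta_base": fmt(p.delta_base_avg, p.delta_base_sd),
                    "der": fmt(p.der_avg, p.der_sd),
                    "alpha": fmt(p.alpha_avg, p.alpha_sd),
                    "n_configs": p.n_configs,
                    "w": p.w,
                }
            )
    return pd.DataFrame(rows)
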