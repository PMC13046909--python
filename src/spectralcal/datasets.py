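"""Bundled example data.

``example_calibration.csv`` holds published per-configuration calibration
values (delta_base in HU, DER, alpha in HU per mg/mL) for iodine-in-water
and iron-in-liver inserts of a spectral abdomen phantom measured on a
clinical photon-counting detector CT: two tube voltages (120/140 kV), three
dose levels (100/120/200 %), with and without a fat ring.  It exercises the
mean-method aggregation without any images.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .calibration import CalibrationRecord, records_from_frame

__all__ = ["example_calibration_frame", "example_calibration_records"]


def example_calibration_frame() -> pd.DataFrame:
    """Example per-configuration calibration table as a DataFrame."""
    with resources.files("spectralcal.data").joinpath(
        "example_calibration.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def example_calibration_records(w: float = 0.5) -> list[CalibrationRecord]:
    """Example calibration values as records ready for aggregation."""
    return records_from_frame(example_calibration_frame(), w=w)
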