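"""Dye-based food-intake quantification.

Consumption is measured through a tracer dye in the food and read on a
plate reader, either as absorbance at 630 nm of dye recovered from
excreta (erioglaucine) or as fluorescence of dye still in the body
(sulforhodamine B).  A standard series of known food amounts defines a
linear calibration curve signal = slope * amount + intercept; unknown
wells are quantified by inverting the curve, dividing by the number of
flies in the well, and (optionally) dividing by feeding duration for a
per-hour rate.  Linearity is the standard assumption for these dyes in
the Beer-Lambert range; the fit warns when r squared < 0.95.

Dead or damaged flies are excluded before quantification via the plate
map's ``alive`` flag (scored visually at the bench).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .arena import PlateMap

R2_WARN_THRESHOLD = 0.95


@dataclass(frozen=True)
class CalibrationPoint:
    """One standard-series point: known food amount vs measured signal."""

    known_amount: float
    signal: float

    def __post_init__(self) -> None:
        if self.known_amount < 0:
            raise ValueError("known_amount must be >= 0")
        if not np.isfinite(self.signal):
            raise ValueError("signal must be finite")


@dataclass(frozen=True)
class StandardCurve:
    """Linear signal-vs-amount calibration with fit diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    signal_kind: str = "absorbance_630"

    def forward(self, amount: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(amount, dtype=np.float64) + self.intercept

    def invert(self, signal: float | np.ndarray) -> float | np.ndarray:
        if self.slope == 0:
            raise ValueError("curve with zero slope is not invertible")
        return (np.asarray(signal, dtype=np.float64) - self.intercept) / self.slope


def fit_standard_curve(
    points: Sequence[CalibrationPoint], signal_kind: str = "absorbance_630"
) -> StandardCurve:
    """Ordinary least-squares line through the calibration series.

    Requires at least two distinct known amounts.  Emits a UserWarning
    when r squared < 0.95 (a sloppy standard series propagates directly
    into every quantified well).
    """
    amounts = np.array([p.known_amount for p in points], dtype=np.float64)
    signals = np.array([p.signal for p in points], dtype=np.float64)
    if len(np.unique(amounts)) < 2:
        raise ValueError("need >= 2 distinct known amounts to fit a line")
    fit = sps.linregress(amounts, signals)
    r2 = float(fit.rvalue**2)
    if r2 < R2_WARN_THRESHOLD:
        warnings.warn(
            f"calibration r^2 = {r2:.3f} < {R2_WARN_THRESHOLD}; check the standard series",
            UserWarning,
            stacklevel=2,
        )
    return StandardCurve(float(fit.slope), float(fit.intercept), r2, signal_kind)


def calibration_from_csv(path, signal_kind: str = "absorbance_630") -> StandardCurve:
    """Fit from a CSV with columns known_amount,signal."""
    df = pd.read_csv(path)
    pts = [CalibrationPoint(a, s) for a, s in zip(df["known_amount"], df["signal"])]
    return fit_standard_curve(pts, signal_kind)


@dataclass(frozen=True)
class PlateReading:
    """One well's plate-reader signal plus the context needed to scale it."""

    well_id: str
    signal: float
    flies_per_well: int = 1
    alive: bool = True
    feeding_duration_h: float = 2.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.signal):
            raise ValueError(f"well {self.well_id}: non-finite signal")
        if self.flies_per_well < 1:
            raise ValueError(f"well {self.well_id}: flies_per_well must be >= 1")
        if self.feeding_duration_h <= 0:
            raise ValueError(f"well {self.well_id}: feeding duration must be > 0")


def quantify(
    reading: PlateReading,
    curve: StandardCurve,
    blank_signal: float = 0.0,
) -> float:
    """Food amount per fly from one well's signal.

    amount = (signal - blank - intercept) / slope / flies_per_well.
    A negative inversion (signal below the curve's zero point, i.e. noise
    around a blank) clamps to 0 with a warning.
    """
    amount_total = float(curve.invert(reading.signal - blank_signal))
    if amount_total < 0:
        warnings.warn(
            f"well {reading.well_id}: signal below calibration zero; clamping amount to 0",
            UserWarning,
            stacklevel=2,
        )
        amount_total = 0.0
    return amount_total / reading.flies_per_well


def per_hour_rate(total: float, duration_h: float) -> float:
    """Consumption rate: total amount divided by feeding duration in hours."""
    if duration_h <= 0:
        raise ValueError("duration_h must be > 0")
    return total / duration_h


def exclude_dead(
    readings: Sequence[PlateReading], platemap: PlateMap
) -> tuple[list[PlateReading], pd.DataFrame]:
    """Drop wells whose plate-map ``alive`` flag is false.

    Returns (retained readings, exclusion report with columns
    well,reason).  Unknown well ids raise.
    """
    known = set(platemap.table["well"])
    unknown = [r.well_id for r in readings if r.well_id not in known]
    if unknown:
        raise ValueError(f"readings reference wells absent from plate map: {unknown}")
    retained: list[PlateReading] = []
    excluded_rows = []
    for r in readings:
        if bool(platemap.table.loc[r.well_id, "alive"]):
            retained.append(r)
        else:
            excluded_rows.append({"well": r.well_id, "reason": "dead_or_damaged"})
    return retained, pd.DataFrame(excluded_rows, columns=["well", "reason"])


def quantify_plate(
    readings: Sequence[PlateReading],
    curve: StandardCurve,
    platemap: Optional[PlateMap] = None,
    blank_signal: float = 0.0,
) -> pd.DataFrame:
    """Quantify a whole plate; dead wells are excluded but still reported.

    Output schema: well,amount_per_fly,rate_per_hour,excluded,reason.
    """
    if platemap is not None:
        retained, report = exclude_dead(readings, platemap)
        excluded_reasons = dict(zip(report["well"], report["reason"]))
    else:
        retained, excluded_reasons = list(readings), {}
    retained_ids = {r.well_id for r in retained}
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # clamp warnings summarized in table
        for r in readings:
            if r.well_id in retained_ids:
                amt = quantify(r, curve, blank_signal)
                rows.append(
                    {
                        "well": r.well_id,
                        "amount_per_fly": amt,
                        "rate_per_hour": per_hour_rate(amt, r.feeding_duration_h),
                        "excluded": False,
                        "reason": "",
                    }
                )
            else:
                rows.append(
                    {
                        "well": r.well_id,
                        "amount_per_fly": np.nan,
                        "rate_per_hour": np.nan,
                        "excluded": True,
                        "reason": excluded_reasons.get(r.well_id, ""),
                    }
                )
    return pd.DataFrame(
        rows, columns=["well", "amount_per_fly", "rate_per_hour", "excluded", "reason"]
    )


def readings_from_csv(
    path, platemap: Optional[PlateMap] = None, feeding_duration_h: float = 2.0
) -> list[PlateReading]:
    """Load plate-reader export CSV with columns well,signal."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        wid = str(row["well"])
        if platemap is not None and wid in set(platemap.table["well"]):
            meta = platemap.table.loc[wid]
            out.append(
                PlateReading(
                    wid,
                    float(row["signal"]),
                    int(meta["flies_per_well"]),
                    bool(meta["alive"]),
                    feeding_duration_h,
                )
            )
        else:
            out.append(PlateReading(wid, float(row["signal"]), feeding_duration_h=feeding_duration_h))
    return out
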