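"""Internal-standardization calibration and inverse concentration prediction.

The calibration function is the least-squares line through
``y = I_analyte / I_IS`` versus ``x = C_analyte / C_IS``, fitted on
per-level replicate means with inverse-variance weights taken from the
replicate scatter at each level.  Weighting is not optional across a
0.05-1000 ug/L range with multiplicative noise: an unweighted fit lets the
absolute scatter of the top standards leak several ug/L of error into the
intercept, destroying sub-ug/L accuracy.  A curve is accepted when its
(weighted) coefficient of determination exceeds 0.995.

Concentration in the undiluted fluid is recovered by inverting the line and
re-applying the dilution factor:

    C = ((I_a/I_IS - intercept) / slope) * C_IS * DF

Predictions may be negative for sub-blank signals; censoring against the
detection limits is the profiling stage's job, not this one's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

R2_ACCEPTANCE = 0.995


@dataclass(frozen=True)
class CalibrationCurve:
    element_symbol: str
    mode: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    level_range: tuple[float, float]
    accepted: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 must lie in [0, 1]")


def fit_curve(records: pd.DataFrame, is_concentration: float) -> CalibrationCurve:
    """Fit the IS-ratio calibration line for one element x mode.

    ``records`` must hold calibration-role rows for a single element and
    mode, with columns ``nominal_conc_ugL``, ``analyte_cps`` and ``is_cps``.
    """
    if (records["is_cps"] <= 0).any():
        raise ValueError("internal-standard intensity must be positive to form ratios")
    elements = records["element"].unique()
    modes = records["mode"].unique()
    if len(elements) != 1 or len(modes) != 1:
        raise ValueError("fit_curve expects records for exactly one element and mode")

    ratios = records["analyte_cps"] / records["is_cps"]
    grouped = ratios.groupby(records["nominal_conc_ugL"])
    by_level = grouped.mean()
    counts = grouped.count()
    sds = grouped.std(ddof=1)
    levels = by_level.index.to_numpy(dtype=float)
    if len(levels) < 3:
        raise ValueError("need at least 3 distinct calibration levels")
    x = levels / is_concentration
    y = by_level.to_numpy(dtype=float)
    # weight each level mean by its standard error; degenerate (replicate-free
    # or noiseless) levels fall back to the smallest observed scatter
    se = (sds / np.sqrt(counts)).to_numpy(dtype=float)
    finite = se[np.isfinite(se) & (se > 0)]
    floor = finite.min() if finite.size else 1.0
    se = np.where(np.isfinite(se) & (se > 0), se, floor)
    slope, intercept = np.polyfit(x, y, 1, w=1.0 / se)
    resid = y - (slope * x + intercept)
    w = 1.0 / se**2
    ybar = np.sum(w * y) / np.sum(w)
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    ss_res = float(np.sum(w * resid**2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CalibrationCurve(
        element_symbol=str(elements[0]),
        mode=str(modes[0]),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=min(1.0, float(r2)),
        n_points=len(levels),
        level_range=(float(levels.min()), float(levels.max())),
        accepted=bool(r2 > R2_ACCEPTANCE and slope > 0),
    )


def fit_all(records: pd.DataFrame, is_concentration: float) -> dict[tuple[str, str], CalibrationCurve]:
    """Fit one curve per (element, mode) from a long-format record table."""
    cal = records[records["role"] == "calibration"]
    if cal.empty:
        raise ValueError("no calibration records found")
    curves: dict[tuple[str, str], CalibrationCurve] = {}
    for (element, mode), group in cal.groupby(["element", "mode"], sort=True):
        curves[(element, mode)] = fit_curve(group, is_concentration)
    return curves


def predict_concentration(
    curve: CalibrationCurve,
    ratio: float | np.ndarray,
    is_concentration: float,
    dilution_factor: float = 1.0,
) -> float | np.ndarray:
    """Invert the calibration line; result is ug/L in the undiluted fluid."""
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive for prediction")
    return (ratio - curve.intercept) / curve.slope * is_concentration * dilution_factor


def predict_records(
    records: pd.DataFrame,
    curves: dict[tuple[str, str], CalibrationCurve],
    is_concentration: float,
) -> pd.Series:
    """Vectorized prediction for every row, using each row's own dilution."""
    out = np.full(len(records), np.nan)
    ratio = (records["analyte_cps"] / records["is_cps"]).to_numpy()
    df = records["dilution_factor"].to_numpy(dtype=float)
    for (element, mode), curve in curves.items():
        mask = ((records["element"] == element) & (records["mode"] == mode)).to_numpy()
        if mask.any():
            out[mask] = predict_concentration(curve, ratio[mask], is_concentration, df[mask])
    return pd.Series(out, index=records.index, name="conc_ugL")


def curves_to_frame(curves: dict[tuple[str, str], CalibrationCurve]) -> pd.DataFrame:
    rows = [
        {
            "element": c.element_symbol,
            "mode": c.mode,
            "slope": c.slope,
            "intercept": c.intercept,
            "r2": c.r_squared,
            "n_points": c.n_points,
            "level_min": c.level_range[0],
            "level_max": c.level_range[1],
            "accepted": c.accepted,
        }
        for c in curves.values()
    ]
    return pd.DataFrame(rows)
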