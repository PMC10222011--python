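"""Limits of detection and quantification from blank replicates.

LOD = 3 s_b / m and LOQ = 10 s_b / m, with s_b the sample standard
deviation (n-1 denominator) of consecutive blank analyte/IS ratios and m
the slope of the ratio calibration line; the ratio units are converted to
concentration through the internal-standard concentration, consistently
with the inverse prediction.  LOQ/LOD is exactly 10/3 by construction.

Limits are expressed in measured-solution concentration (no dilution
re-scaling) unless ``apply_dilution`` is set.  When blanks from several
days are supplied, per-day limits are computed and their arithmetic mean is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve


@dataclass(frozen=True)
class DetectionLimits:
    element_symbol: str
    mode: str
    s_b: float  # blank ratio SD, calibration-y units
    lod: float  # ug/L
    loq: float  # ug/L
    n_blanks: int
    degenerate: bool = False  # constant blanks (s_b == 0)

    def __post_init__(self) -> None:
        if self.lod < 0:
            raise ValueError("LOD must be non-negative")


def compute_limits(
    blanks: pd.DataFrame,
    curve: CalibrationCurve,
    is_concentration: float,
    dilution_factor: float = 1.0,
    apply_dilution: bool = False,
) -> DetectionLimits:
    """Detection limits for one element x mode from its blank records."""
    if len(blanks) < 2:
        raise ValueError("need at least 2 blank replicates")
    if not curve.accepted:
        raise ValueError(
            f"calibration for {curve.element_symbol}/{curve.mode} not accepted; "
            "limits would be meaningless"
        )
    ratios = (blanks["analyte_cps"] / blanks["is_cps"]).to_numpy(dtype=float)
    days = blanks["day"].to_numpy() if "day" in blanks else np.zeros(len(blanks), dtype=int)

    per_day_sb = []
    for day in np.unique(days):
        day_ratios = ratios[days == day]
        if len(day_ratios) >= 2:
            per_day_sb.append(float(np.std(day_ratios, ddof=1)))
    s_b = float(np.mean(per_day_sb)) if per_day_sb else float(np.std(ratios, ddof=1))
    # constant blanks: snap the rounding residue of identical ratios to zero
    if s_b <= 1e-12 * max(abs(float(np.mean(ratios))), np.finfo(float).tiny):
        s_b = 0.0

    scale = is_concentration * (dilution_factor if apply_dilution else 1.0)
    lod = 3.0 * s_b / curve.slope * scale
    loq = 10.0 * s_b / curve.slope * scale
    return DetectionLimits(
        element_symbol=curve.element_symbol,
        mode=curve.mode,
        s_b=s_b,
        lod=lod,
        loq=loq,
        n_blanks=len(blanks),
        degenerate=bool(s_b == 0.0),
    )


def compute_all_limits(
    records: pd.DataFrame,
    curves: dict[tuple[str, str], CalibrationCurve],
    is_concentration: float,
) -> dict[tuple[str, str], DetectionLimits]:
    blanks = records[records["role"] == "blank"]
    out: dict[tuple[str, str], DetectionLimits] = {}
    for (element, mode), group in blanks.groupby(["element", "mode"], sort=True):
        curve = curves.get((element, mode))
        if curve is None or not curve.accepted:
            continue
        out[(element, mode)] = compute_limits(group, curve, is_concentration)
    return out


def limits_to_frame(limits: dict[tuple[str, str], DetectionLimits]) -> pd.DataFrame:
    rows = [
        {
            "element": l.element_symbol,
            "mode": l.mode,
            "s_b": l.s_b,
            "lod_ugL": l.lod,
            "loq_ugL": l.loq,
            "n_blanks": l.n_blanks,
            "degenerate": l.degenerate,
        }
        for l in limits.values()
    ]
    return pd.DataFrame(rows)
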