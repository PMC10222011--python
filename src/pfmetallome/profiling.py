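"""Cohort elemental profiling: mode routing, left-censoring, summaries.

Elements whose isotope suffers polyatomic overlap (Cr-52, Cu-63, Fe-56,
Zn-68) are quantified in He collision-cell mode; all others use no-gas mode
for its lower detection limits.  Arsenic is excluded outright: its dominant
interference pathway is not removed by the collision gas, so no acquisition
mode yields accurate values.

Concentrations are censored against the routed mode's limits: below LOD,
between LOD and LOQ (reported only as "<LOQ"), or quantified (>= LOQ,
boundary inclusive).  Summary statistics (mean, SD, SEM, min, max) are
computed over quantified values only — no LOD/2-style imputation — while
the detection percentage counts every sample at or above the LOD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, predict_concentration
from .limits import DetectionLimits

HE_ROUTED = ("Cr", "Cu", "Fe", "Zn")
EXCLUDED = ("As",)

QUANTIFIED = "quantified"
BELOW_LOQ = "below_LOQ"
BELOW_LOD = "below_LOD"
EXCLUDED_STATUS = "excluded"


@dataclass(frozen=True)
class ElementResult:
    sample_id: int
    element_symbol: str
    mode_used: str
    concentration: float  # ug/L in the undiluted fluid
    censor_flag: str


@dataclass(frozen=True)
class ElementSummary:
    element_symbol: str
    mode_used: str
    n: int
    n_quantified: int
    mean: float | None  # over quantified values
    sd: float | None
    sem: float | None
    minimum: float | None
    maximum: float | None
    pct_above_lod: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_above_lod <= 100.0:
            raise ValueError("detection percentage must lie in [0, 100]")


def route_mode(element: str, panel: tuple[str, ...] | None = None) -> str:
    """Acquisition mode used to report one element of the panel."""
    if panel is not None and element not in panel:
        raise KeyError(f"element {element!r} not in the panel")
    if element in EXCLUDED:
        return EXCLUDED_STATUS
    if element in HE_ROUTED:
        return "He"
    return "no-gas"


def censor(conc: float, limits: DetectionLimits, sample_id: int = 0) -> ElementResult:
    """Censor one concentration against LOD/LOQ; negatives are below LOD."""
    if conc < limits.lod:
        flag = BELOW_LOD
    elif conc < limits.loq:
        flag = BELOW_LOQ
    else:
        flag = QUANTIFIED
    return ElementResult(sample_id, limits.element_symbol, limits.mode, conc, flag)


def summarize(results: list[ElementResult]) -> ElementSummary:
    """Cohort summary for one element: censored-aware statistics."""
    if not results:
        raise ValueError("cohort results must be nonempty")
    element = results[0].element_symbol
    mode = results[0].mode_used
    n = len(results)
    detected = sum(1 for r in results if r.censor_flag != BELOW_LOD)
    quantified = [r.concentration for r in results if r.censor_flag == QUANTIFIED]
    nq = len(quantified)
    if nq == 0:
        mean = sd = sem = mn = mx = None
    else:
        arr = np.asarray(quantified)
        mean = float(arr.mean())
        mn = float(arr.min())
        mx = float(arr.max())
        if nq > 1:
            sd = float(arr.std(ddof=1))
            sem = sd / float(np.sqrt(nq))
        else:
            sd = sem = None
    return ElementSummary(element, mode, n, nq, mean, sd, sem, mn, mx,
                          100.0 * detected / n)


def profile_cohort(
    records: pd.DataFrame,
    curves: dict[tuple[str, str], CalibrationCurve],
    limits: dict[tuple[str, str], DetectionLimits],
    is_concentration: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Route, predict, censor and summarize the cohort records.

    Returns (per-sample results, per-element summary) frames.  Excluded
    elements appear in neither; the summary covers the reported panel.
    """
    cohort = records[records["stage"] == "cohort"]
    result_rows = []
    summary_rows = []
    for element in sorted(cohort["element"].unique()):
        mode = route_mode(element)
        if mode == EXCLUDED_STATUS:
            continue
        curve = curves.get((element, mode))
        lim = limits.get((element, mode))
        if curve is None or lim is None:
            continue
        sub = cohort[(cohort["element"] == element) & (cohort["mode"] == mode)]
        results = []
        for _, row in sub.iterrows():
            ratio = row["analyte_cps"] / row["is_cps"]
            conc = float(
                predict_concentration(curve, ratio, is_concentration,
                                      float(row["dilution_factor"]))
            )
            results.append(censor(conc, lim, sample_id=int(row["replicate"])))
        if not results:
            continue
        result_rows.extend(
            {
                "sample": r.sample_id,
                "element": r.element_symbol,
                "mode": r.mode_used,
                "conc_ugL": r.concentration,
                "flag": r.censor_flag,
            }
            for r in results
        )
        s = summarize(results)
        summary_rows.append(
            {
                "element": s.element_symbol,
                "mode": s.mode_used,
                "n": s.n,
                "n_quantified": s.n_quantified,
                "mean_ugL": s.mean,
                "sd_ugL": s.sd,
                "sem_ugL": s.sem,
                "min_ugL": s.minimum,
                "max_ugL": s.maximum,
                "pct_above_lod": s.pct_above_lod,
            }
        )
    results_df = pd.DataFrame(
        result_rows, columns=["sample", "element", "mode", "conc_ugL", "flag"]
    )
    summary_df = pd.DataFrame(
        summary_rows,
        columns=["element", "mode", "n", "n_quantified", "mean_ugL", "sd_ugL",
                 "sem_ugL", "min_ugL", "max_ugL", "pct_above_lod"],
    )
    return results_df, summary_df
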