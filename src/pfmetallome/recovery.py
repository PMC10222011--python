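"""Spike recovery, tolerance classification, dilution choice, mode agreement.

Recovery of an added spike is the blank-referenced fraction of the expected
signal:

    R% = 100 * (I_spiked - I_unspiked) / I_standard

All three inputs are internal-standard-corrected ratios, so a common
rescaling of the raw intensities leaves R unchanged.  The aqueous standard
is measured at the spike level as seen in the measured solution
(spike / dilution factor) and is blank-corrected with the mean calibration
blank before use.  Recoveries in 90-110% lie within the +-10% tolerance
interval; the dilution comparator recommends the factor putting more
elements inside it, breaking ties toward the higher dilution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, predict_concentration
from .limits import DetectionLimits

TOLERANCE = (90.0, 110.0)


@dataclass(frozen=True)
class RecoveryResult:
    element_symbol: str
    mode: str
    dilution_factor: float
    recovery_pct: float
    sem_pct: float
    n: int
    within_tolerance: bool


def recovery_pct(i_spiked: float, i_unspiked: float, i_standard: float) -> float:
    """Blank-referenced spike recovery in percent; inputs are IS-ratio signals."""
    if i_standard <= 0:
        raise ValueError("standard intensity must be positive")
    return 100.0 * (i_spiked - i_unspiked) / i_standard


def _ratio(frame: pd.DataFrame) -> pd.Series:
    return frame["analyte_cps"] / frame["is_cps"]


def _blank_ratio(records: pd.DataFrame, element: str, mode: str) -> float:
    blanks = records[
        (records["role"] == "blank")
        & (records["element"] == element)
        & (records["mode"] == mode)
    ]
    if blanks.empty:
        return 0.0
    return float(_ratio(blanks).mean())


def _classify(recovery: float, tolerance: tuple[float, float]) -> bool:
    return tolerance[0] <= recovery <= tolerance[1]


def interday_recovery(
    records: pd.DataFrame,
    tolerance: tuple[float, float] = TOLERANCE,
) -> list[RecoveryResult]:
    """Mean +- SEM of daily spike recoveries from the validation stage.

    Per day, the daily recovery is the replicate mean of spike recoveries,
    with the day's unspiked aliquots and aqueous standard as references;
    the reported value averages the daily recoveries over days and the SEM
    is their SD / sqrt(n_days).
    """
    stage = records[records["stage"] == "validation"]
    results: list[RecoveryResult] = []
    for (element, mode), group in stage.groupby(["element", "mode"], sort=True):
        blank = _blank_ratio(records, element, mode)
        days = sorted(group["day"].unique())
        if len(days) < 2:
            raise ValueError(f"interday recovery for {element}/{mode} needs >= 2 days")
        daily = []
        for day in days:
            sub = group[group["day"] == day]
            spiked = _ratio(sub[sub["role"] == "spiked_sample"])
            unspiked = float(_ratio(sub[sub["role"] == "sample"]).mean())
            standard = float(_ratio(sub[sub["role"] == "aqueous_standard"]).mean()) - blank
            recs = [recovery_pct(s, unspiked, standard) for s in spiked]
            daily.append(float(np.mean(recs)))
        mean = float(np.mean(daily))
        sem = float(np.std(daily, ddof=1) / np.sqrt(len(daily)))
        df = float(group["dilution_factor"].iloc[0])
        results.append(
            RecoveryResult(element, mode, df, mean, sem, len(daily), _classify(mean, tolerance))
        )
    return results


def dilution_recovery(
    records: pd.DataFrame,
    mode: str = "no-gas",
    tolerance: tuple[float, float] = TOLERANCE,
) -> list[RecoveryResult]:
    """Per-element recovery (mean +- SEM over fluids) at each dilution factor."""
    stage = records[(records["stage"] == "dilution_study") & (records["mode"] == mode)]
    results: list[RecoveryResult] = []
    for (element, df), group in stage.groupby(["element", "dilution_factor"], sort=True):
        blank = _blank_ratio(records, element, mode)
        standard = float(
            _ratio(group[group["role"] == "aqueous_standard"]).mean()
        ) - blank
        spiked = group[group["role"] == "spiked_sample"].set_index("replicate")
        unspiked = group[group["role"] == "sample"].set_index("replicate")
        per_sample = []
        for rep in spiked.index:
            r_sp = spiked.loc[rep, "analyte_cps"] / spiked.loc[rep, "is_cps"]
            r_un = unspiked.loc[rep, "analyte_cps"] / unspiked.loc[rep, "is_cps"]
            per_sample.append(recovery_pct(float(r_sp), float(r_un), standard))
        mean = float(np.mean(per_sample))
        sem = float(np.std(per_sample, ddof=1) / np.sqrt(len(per_sample)))
        results.append(
            RecoveryResult(element, mode, float(df), mean, sem, len(per_sample),
                           _classify(mean, tolerance))
        )
    return results


def compare_dilutions(
    results: list[RecoveryResult],
    tolerance: tuple[float, float] = TOLERANCE,
) -> tuple[pd.DataFrame, float]:
    """Tabulate |R - 100| per element x dilution and recommend a factor.

    The factor putting more elements inside the tolerance interval wins;
    ties go to the higher dilution (stronger matrix mitigation).
    """
    rows = [
        {
            "element": r.element_symbol,
            "dilution_factor": r.dilution_factor,
            "recovery_pct": r.recovery_pct,
            "abs_deviation": abs(r.recovery_pct - 100.0),
            "within_tolerance": _classify(r.recovery_pct, tolerance),
        }
        for r in results
    ]
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no recovery results to compare")
    counts = table.groupby("dilution_factor")["within_tolerance"].sum()
    best = counts.max()
    recommended = float(max(df for df, n in counts.items() if n == best))
    return table, recommended


def recoveries_to_frame(results: list[RecoveryResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element": r.element_symbol,
                "mode": r.mode,
                "dilution": r.dilution_factor,
                "recovery_pct": r.recovery_pct,
                "sem_pct": r.sem_pct,
                "n": r.n,
                "within_tolerance": r.within_tolerance,
            }
            for r in results
        ]
    )


def mode_agreement(
    records: pd.DataFrame,
    curves: dict[tuple[str, str], CalibrationCurve],
    limits: dict[tuple[str, str], DetectionLimits],
    is_concentration: float,
    excluded_elements: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Compare cohort concentrations measured in both acquisition modes.

    Rows are element x sample; concentrations are reported with their
    censoring flags, and absolute/relative differences are filled only when
    both values are quantifiable (>= LOQ) and the element is not excluded
    (elements under spectral interference are not compared).
    """
    cohort = records[records["stage"] == "cohort"]
    rows = []
    for (element, sample), group in cohort.groupby(["element", "replicate"], sort=True):
        row: dict = {"element": element, "sample": int(sample)}
        comparable = element not in excluded_elements
        concs = {}
        for mode in ("no-gas", "He"):
            sub = group[group["mode"] == mode]
            curve = curves.get((element, mode))
            lim = limits.get((element, mode))
            if sub.empty or curve is None or lim is None:
                comparable = False
                continue
            ratio = float(_ratio(sub).iloc[0])
            conc = float(
                predict_concentration(curve, ratio, is_concentration,
                                      float(sub["dilution_factor"].iloc[0]))
            )
            if conc < lim.lod:
                flag = "below_LOD"
            elif conc < lim.loq:
                flag = "below_LOQ"
            else:
                flag = "quantified"
            key = "nogas" if mode == "no-gas" else "he"
            row[f"conc_{key}_ugL"] = conc
            row[f"flag_{key}"] = flag
            concs[mode] = (conc, flag)
        if comparable and all(f == "quantified" for _, f in concs.values()) and len(concs) == 2:
            a, b = concs["no-gas"][0], concs["He"][0]
            row["abs_diff_ugL"] = abs(a - b)
            row["rel_diff"] = abs(a - b) / ((a + b) / 2.0)
            row["comparable"] = True
        else:
            row["abs_diff_ugL"] = np.nan
            row["rel_diff"] = np.nan
            row["comparable"] = False
        rows.append(row)
    return pd.DataFrame(rows)
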