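"""In-house validation statistics: one-way ANOVA precision components and the
Eurachem-style combined/expanded uncertainty budget.

From the balanced n_days x n_rep grid of found spike concentrations, days as
groups:

    s_rep = sqrt(MS_within)                       (repeatability)
    s_ip  = sqrt(max(0, (MS_between - MS_within) / n_rep))   (intermediate precision)

Relative standard-uncertainty contributions at the spike level C:

    u_rep = (100 / C) * s_rep / sqrt(n_rep)
    u_ip  = (100 / C) * s_ip  / sqrt(n_days)
    u_t   = (100 / C) * sqrt(RMS_bias^2 + u_conc^2 + u_prep^2)

with RMS_bias the root-mean-square of per-day mean bias against C, and
u_conc / u_prep the standard uncertainties of the spike solution and the
sample preparation (config constants, in ug/L).  The expanded relative
uncertainty is U = k * sqrt(u_rep^2 + u_ip^2 + u_t^2), coverage factor
k = 2 (~95%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ValidationGrid:
    """Found concentrations of the added spike, indexed (day, replicate)."""

    element_symbol: str
    mode: str
    c_theoretical: float  # ug/L
    values: np.ndarray  # shape (n_days, n_rep)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("validation grid must be 2-D (days x replicates)")
        if values.shape[0] < 2 or values.shape[1] < 2:
            raise ValueError("need >= 2 days and >= 2 replicates per day")
        if np.isnan(values).any():
            raise ValueError("grid must be balanced (no missing cells)")


@dataclass(frozen=True)
class UncertaintyBudget:
    element_symbol: str
    mode: str
    u_rep: float  # %
    u_ip: float  # %
    u_t: float  # %
    rms_bias: float  # ug/L
    u_conc: float  # ug/L
    u_prep: float  # ug/L
    k: float
    U: float  # %

    def __post_init__(self) -> None:
        for name in ("u_rep", "u_ip", "u_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def anova_decompose(grid: ValidationGrid) -> tuple[float, float]:
    """Within-day and between-day standard deviations from one-way ANOVA.

    Returns ``(s_rep, s_ip)`` in concentration units.  The between-group
    variance component is clamped at zero when MS_between < MS_within.
    """
    values = grid.values
    n_days, n_rep = values.shape
    day_means = values.mean(axis=1)
    grand = values.mean()
    ms_within = float(((values - day_means[:, None]) ** 2).sum() / (n_days * (n_rep - 1)))
    ms_between = float(n_rep * ((day_means - grand) ** 2).sum() / (n_days - 1))
    s_rep = np.sqrt(ms_within)
    s_ip = np.sqrt(max(0.0, (ms_between - ms_within) / n_rep))
    return float(s_rep), float(s_ip)


def precision_contributions(
    s_rep: float, s_ip: float, c_theoretical: float, n_rep: int, n_days: int
) -> tuple[float, float]:
    """Relative (%) repeatability and intermediate-precision contributions."""
    if c_theoretical <= 0:
        raise ValueError("spike level must be positive")
    u_rep = 100.0 / c_theoretical * np.sqrt(s_rep**2 / n_rep)
    u_ip = 100.0 / c_theoretical * np.sqrt(s_ip**2 / n_days)
    return float(u_rep), float(u_ip)


def trueness_contribution(
    day_estimates: np.ndarray,
    c_theoretical: float,
    u_conc: float,
    u_prep: float,
) -> tuple[float, float, float]:
    """(RMS_bias, u_Rec, u_t%) from per-day mean found concentrations."""
    if u_conc < 0 or u_prep < 0:
        raise ValueError("uncertainty constants must be non-negative")
    day_estimates = np.asarray(day_estimates, dtype=float)
    if day_estimates.size < 1:
        raise ValueError("need at least one day estimate")
    rms_bias = float(np.sqrt(np.mean((day_estimates - c_theoretical) ** 2)))
    u_rec = float(np.sqrt(rms_bias**2 + u_conc**2 + u_prep**2))
    u_t = 100.0 * u_rec / c_theoretical
    return rms_bias, u_rec, float(u_t)


def expanded_uncertainty(u_rep: float, u_ip: float, u_t: float, k: float = 2.0) -> float:
    """U = k * sqrt(u_rep^2 + u_ip^2 + u_t^2), all in percent."""
    if min(u_rep, u_ip, u_t) < 0:
        raise ValueError("uncertainty components must be non-negative")
    return float(k * np.sqrt(u_rep**2 + u_ip**2 + u_t**2))


def budget_from_grid(
    grid: ValidationGrid,
    u_conc: float,
    u_prep: float,
    k: float = 2.0,
) -> UncertaintyBudget:
    """Full Eurachem budget for one element x mode validation grid."""
    s_rep, s_ip = anova_decompose(grid)
    n_days, n_rep = grid.values.shape
    u_rep, u_ip = precision_contributions(s_rep, s_ip, grid.c_theoretical, n_rep, n_days)
    day_means = grid.values.mean(axis=1)
    rms_bias, _, u_t = trueness_contribution(day_means, grid.c_theoretical, u_conc, u_prep)
    return UncertaintyBudget(
        element_symbol=grid.element_symbol,
        mode=grid.mode,
        u_rep=u_rep,
        u_ip=u_ip,
        u_t=u_t,
        rms_bias=rms_bias,
        u_conc=u_conc,
        u_prep=u_prep,
        k=k,
        U=expanded_uncertainty(u_rep, u_ip, u_t, k),
    )


def build_validation_grids(
    records: pd.DataFrame,
    curves,
    is_concentration: float,
    c_theoretical: float,
) -> dict[tuple[str, str], ValidationGrid]:
    """Found-added concentration grids from the validation-stage records.

    The found added concentration of a spiked sub-sample is its predicted
    concentration minus the same day's mean unspiked-aliquot concentration
    (native level and any common background cancel in the difference).
    """
    from .calibration import predict_concentration

    stage = records[records["stage"] == "validation"]
    grids: dict[tuple[str, str], ValidationGrid] = {}
    for (element, mode), group in stage.groupby(["element", "mode"], sort=True):
        curve = curves.get((element, mode))
        if curve is None or not curve.accepted:
            continue
        days = sorted(group["day"].unique())
        rows = []
        for day in days:
            sub = group[group["day"] == day]
            sp = sub[sub["role"] == "spiked_sample"].sort_values("replicate")
            un = sub[sub["role"] == "sample"]
            df = float(sp["dilution_factor"].iloc[0])
            c_sp = predict_concentration(
                curve, (sp["analyte_cps"] / sp["is_cps"]).to_numpy(), is_concentration, df
            )
            c_un = float(
                np.mean(
                    predict_concentration(
                        curve, (un["analyte_cps"] / un["is_cps"]).to_numpy(),
                        is_concentration, df,
                    )
                )
            )
            rows.append(c_sp - c_un)
        grids[(element, mode)] = ValidationGrid(element, mode, c_theoretical, np.array(rows))
    return grids


def budgets_to_frame(budgets: dict[tuple[str, str], UncertaintyBudget]) -> pd.DataFrame:
    rows = [
        {
            "element": b.element_symbol,
            "mode": b.mode,
            "u_ip": round(b.u_ip, 1),
            "u_rep": round(b.u_rep, 1),
            "u_t": round(b.u_t, 1),
            "U": round(b.U, 1),
            "k": b.k,
            "rms_bias_ugL": b.rms_bias,
        }
        for b in budgets.values()
    ]
    return pd.DataFrame(rows)
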