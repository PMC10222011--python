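"""Configuration and end-to-end orchestration of the validation pipeline.

Stage order mirrors the assay: simulate (or load) records -> calibrate ->
detection limits -> dilution optimization -> interday recovery -> ANOVA /
uncertainty budgets -> cohort profile.  All randomness flows from one seed;
running twice with the same config gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import curves_to_frame, fit_all
from .instrument import (
    RunDesign,
    default_matrix,
    default_panel,
    default_truth,
    generate_study,
)
from .limits import compute_all_limits, limits_to_frame
from .profiling import EXCLUDED, profile_cohort, route_mode
from .recovery import (
    compare_dilutions,
    dilution_recovery,
    interday_recovery,
    mode_agreement,
    recoveries_to_frame,
)
from .uncertainty import budget_from_grid, budgets_to_frame, build_validation_grids


@dataclass(frozen=True)
class PipelineConfig:
    design: RunDesign = field(default_factory=RunDesign)
    tolerance: tuple[float, float] = (90.0, 110.0)
    u_conc_rel: float = 0.005  # spike-solution standard uncertainty, fraction of C
    u_prep_rel: float = 0.010  # preparation standard uncertainty, fraction of C
    k: float = 2.0
    he_routed: tuple[str, ...] = ("Cr", "Cu", "Fe", "Zn")
    excluded: tuple[str, ...] = EXCLUDED

    def __post_init__(self) -> None:
        if self.tolerance[0] >= self.tolerance[1]:
            raise ValueError("tolerance bounds must be ordered")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        design_kwargs = raw.pop("design", {})
        for key in ("calibration_levels", "dilution_study_factors"):
            if key in design_kwargs:
                design_kwargs[key] = tuple(design_kwargs[key])
        for key in ("tolerance", "he_routed", "excluded"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(design=RunDesign(**design_kwargs), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(
    config: PipelineConfig,
    records: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame | dict]:
    """Run every stage; return (and optionally write) the report bundle."""
    design = config.design
    is_conc = design.is_concentration

    if records is None:
        records = _stage("simulate")(generate_study, design)

    curves = _stage("calibrate")(fit_all, records, is_conc)
    limits = _stage("limits")(compute_all_limits, records, curves, is_conc)

    dil = _stage("dilution_recovery")(dilution_recovery, records, "no-gas", config.tolerance)
    dil_table, recommended = _stage("compare_dilutions")(compare_dilutions, dil, config.tolerance)

    inter = _stage("interday_recovery")(interday_recovery, records, config.tolerance)

    c = design.spike_concentration
    grids = _stage("validation_grids")(build_validation_grids, records, curves, is_conc, c)
    budgets = {}
    for element in sorted({ch.element_symbol for ch in default_panel()}):
        mode = route_mode(element)
        if mode == "excluded":
            continue
        grid = grids.get((element, mode))
        if grid is None:
            continue
        budgets[(element, mode)] = _stage("uncertainty")(
            budget_from_grid, grid, config.u_conc_rel * c, config.u_prep_rel * c, config.k
        )

    interfered = tuple(config.he_routed) + tuple(config.excluded)
    agreement = _stage("mode_agreement")(
        mode_agreement, records, curves, limits, is_conc, interfered
    )
    cohort_results, cohort_summary = _stage("profile")(
        profile_cohort, records, curves, limits, is_conc
    )

    bundle: dict[str, pd.DataFrame | dict] = {
        "records": records,
        "curves": curves_to_frame(curves),
        "limits": limits_to_frame(limits),
        "dilution_recovery": recoveries_to_frame(dil),
        "dilution_table": dil_table,
        "interday_recovery": recoveries_to_frame(inter),
        "budgets": budgets_to_frame(budgets),
        "mode_agreement": agreement,
        "cohort_results": cohort_results,
        "cohort_summary": cohort_summary,
        "run_log": {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": design.seed,
            "config_hash": config.config_hash(),
            "recommended_dilution_factor": recommended,
            "n_reported_analytes": int(len(budgets)),
            "excluded_elements": list(config.excluded),
        },
    }
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=False)
        else:
            (out / f"{name}.json").write_text(json.dumps(obj, indent=2, default=str) + "\n")
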