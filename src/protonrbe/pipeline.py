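"""End-to-end model comparison: grids in, tables and summaries out.

``run_compare`` evaluates each selected RBE model on co-registered dose /
LET_D grids and produces, per model and tissue: RBE and D_RBE grids, volume
histograms (dose, D_RBE, LET_D) for the PTV, min/max/mean RBE in the PTV,
D_RBE at 95 % / 5 % volume and the mean, and per-field biological
range-shift maps, histograms and means.  Every exported table carries the
configuration hash and package version; excluded-ray counts and
applicability statistics are part of the result bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grids import (PlanConfig, ScalarGrid, StructureMask, compute_drbe_grid,
                    compute_rbe_grid, RBEComputeReport)
from .metrics import (DEFAULT_GRADIENT_THRESHOLD_MM_PER_GY, DEFAULT_LEVELS,
                      DEFAULT_SHIFT_BIN_MM, RangeShiftResult, VolumeHistogram,
                      cumulative_volume_histogram, dose_at_volume,
                      range_shift_analysis)
from .models import (CarabeModel, FixedRBEModel, LEMTable, LEMTableModel,
                     RBEModel, TissueParams, WedenbergModel)

__all__ = [
    "RunConfig",
    "ModelResult",
    "CompareResult",
    "ModelNotApplicableError",
    "build_model",
    "run_compare",
    "export_results",
]

KNOWN_MODELS = ("car", "wed", "lem", "fixed_1.1")


class ModelNotApplicableError(RuntimeError):
    """A requested model cannot be evaluated anywhere on the input grids."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one comparison run."""

    tissue: TissueParams
    models: tuple[str, ...] = ("car", "wed", "lem", "fixed_1.1")
    plan: PlanConfig = field(default_factory=PlanConfig)
    lem_table: LEMTable | None = None
    levels: tuple[float, ...] = DEFAULT_LEVELS
    gradient_threshold: float = DEFAULT_GRADIENT_THRESHOLD_MM_PER_GY
    shift_bin_mm: float = DEFAULT_SHIFT_BIN_MM
    dose_floor_gy: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.models:
            if m not in KNOWN_MODELS:
                raise ValueError(f"unknown model {m!r}; choose from {KNOWN_MODELS}")
        if not all(0.0 < lv < 1.0 for lv in self.levels):
            raise ValueError("levels must be fractions in (0, 1)")
        if not self.gradient_threshold > 0:
            raise ValueError("gradient threshold must be positive")
        if "lem" in self.models and self.lem_table is None:
            raise ValueError("model 'lem' requires a lem_table")

    def config_hash(self) -> str:
        """Short stable hash of the run configuration for output provenance."""
        payload = {
            "tissue": dataclasses.asdict(self.tissue),
            "models": self.models,
            "plan": dataclasses.asdict(self.plan),
            "lem_table": None if self.lem_table is None else
                [self.lem_table.let.tolist(), self.lem_table.alpha.tolist(),
                 self.lem_table.beta.tolist()],
            "levels": self.levels,
            "gradient_threshold": self.gradient_threshold,
            "shift_bin_mm": self.shift_bin_mm,
            "dose_floor_gy": self.dose_floor_gy,
            "seed": self.seed,
        }
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode())
        return digest.hexdigest()[:12]


def build_model(name: str, config: RunConfig) -> RBEModel:
    if name == "car":
        return CarabeModel()
    if name == "wed":
        return WedenbergModel()
    if name == "lem":
        return LEMTableModel(config.lem_table)
    if name == "fixed_1.1":
        return FixedRBEModel(config.plan.reference_rbe)
    raise ValueError(f"unknown model {name!r}")


@dataclass
class ModelResult:
    """Everything computed for one model on one tissue."""

    model: str
    rbe: ScalarGrid
    drbe: ScalarGrid
    report: RBEComputeReport
    rbe_stats: dict[str, float]                 # min/max/mean RBE in PTV
    drbe_stats: dict[str, float]                # d95/d5/mean D_RBE in PTV [Gy(RBE)]
    histograms: dict[str, VolumeHistogram]      # dvh, drbevh, letdvh
    range_shifts: dict[int, RangeShiftResult]   # keyed by field index


@dataclass
class CompareResult:
    config: RunConfig
    models: dict[str, ModelResult]
    reference_drbe: ScalarGrid


def _ptv_stats(rbe: ScalarGrid, ptv: StructureMask) -> dict[str, float]:
    vals = rbe.values[ptv.mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ModelNotApplicableError("model inapplicable over the entire PTV")
    return {"min": float(vals.min()), "max": float(vals.max()),
            "mean": float(vals.mean())}


def run_compare(config: RunConfig, dose: ScalarGrid, let_d: ScalarGrid,
                ptv: StructureMask,
                body: StructureMask | None = None) -> CompareResult:
    """Run the full comparison for every selected model.

    Raises :class:`ModelNotApplicableError` if a requested model has no
    applicable voxel carrying dose (e.g. the CAR model on a
    (alpha/beta)_x = 10 Gy tissue whose LET_D never exceeds 6.2 keV/um); the
    error message carries the applicability report.
    """
    plan = config.plan
    reference = dose.like(plan.reference_rbe * dose.values, "drbe_gy_rbe")
    results: dict[str, ModelResult] = {}
    for name in config.models:
        model = build_model(name, config)
        rbe, report = compute_rbe_grid(model, dose, let_d, config.tissue,
                                       config.dose_floor_gy)
        dosed = dose.values >= config.dose_floor_gy
        if not np.any(np.isfinite(rbe.values) & dosed):
            frac = report.inapplicable_fraction
            raise ModelNotApplicableError(
                f"model {name!r} is inapplicable on every dose-carrying voxel "
                f"({report.n_inapplicable}/{report.n_voxels} voxels masked, "
                f"{frac:.1%}); for the CAR model this occurs when "
                f"LET_D <= 0.62 (alpha/beta)_x everywhere"
            )
        drbe = compute_drbe_grid(rbe, dose, plan)
        hists = {
            "dvh": cumulative_volume_histogram(dose, ptv),
            "drbevh": cumulative_volume_histogram(drbe, ptv),
            "letdvh": cumulative_volume_histogram(let_d, ptv),
        }
        drbe_h = hists["drbevh"]
        shifts: dict[int, RangeShiftResult] = {}
        for k, (axis, direction) in enumerate(plan.beam_axes):
            shifts[k] = range_shift_analysis(
                reference, drbe, beam_axis=axis,
                d_presc=plan.prescription_drbe_per_fraction,
                levels=config.levels, direction=direction,
                gradient_threshold=config.gradient_threshold,
                bin_width_mm=config.shift_bin_mm, body_mask=body,
            )
        results[name] = ModelResult(
            model=name, rbe=rbe, drbe=drbe, report=report,
            rbe_stats=_ptv_stats(rbe, ptv),
            drbe_stats={
                "d95": dose_at_volume(drbe_h, 95.0),
                "d5": dose_at_volume(drbe_h, 5.0),
                "mean": float(np.nanmean(drbe.values[ptv.mask])),
            },
            histograms=hists,
            range_shifts=shifts,
        )
    return CompareResult(config=config, models=results, reference_drbe=reference)


def export_results(result: CompareResult, out_dir) -> dict[str, Path]:
    """Write the comparison tables as CSV/JSON; returns the written paths.

    Columns are fixed-order; every table carries the config hash and the
    package version.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = result.config.config_hash()
    written: dict[str, Path] = {}

    rows = []
    for name, mr in result.models.items():
        rows.append({
            "model": name,
            "rbe_min": mr.rbe_stats["min"], "rbe_max": mr.rbe_stats["max"],
            "rbe_mean": mr.rbe_stats["mean"],
            "drbe_d95_gyrbe": mr.drbe_stats["d95"],
            "drbe_d5_gyrbe": mr.drbe_stats["d5"],
            "drbe_mean_gyrbe": mr.drbe_stats["mean"],
            "n_low_dose": mr.report.n_low_dose,
            "n_inapplicable": mr.report.n_inapplicable,
            "config_hash": cfg_hash, "version": __version__,
        })
    p = out / "ptv_summary.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written["ptv_summary"] = p

    for name, mr in result.models.items():
        for k, rs in mr.range_shifts.items():
            if rs.records:
                p = out / f"range_shift_{name}_field{k}.csv"
                df = pd.DataFrame(rs.records,
                                  columns=["level_pct", "ray_i", "ray_j",
                                           "r_ref_mm", "r_var_mm", "shift_mm",
                                           "excluded_reason"])
                df.insert(0, "model", name)
                df["config_hash"] = cfg_hash
                df.to_csv(p, index=False)
                written[f"range_shift_{name}_field{k}"] = p
            p = out / f"range_shift_{name}_field{k}_summary.json"
            with open(p, "w") as fh:
                json.dump({"model": name, "field": k,
                           "config_hash": cfg_hash, "version": __version__,
                           "levels": rs.summary_dict()}, fh, indent=2)
                fh.write("\n")
            written[f"range_shift_{name}_field{k}_summary"] = p

        for tag, h in mr.histograms.items():
            p = out / f"{tag}_{name}.csv"
            pd.DataFrame({
                "value": h.edges, "volume_pct": h.cumulative_pct,
            }).assign(structure=h.label, quantity=h.quantity,
                      model=name, config_hash=cfg_hash).to_csv(p, index=False)
            written[f"{tag}_{name}"] = p
    return written
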