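"""Voxel-wise application of RBE models to co-registered dose / LET_D grids.

Grids are voxel-centre addressed with 0-based indices; the physical position
of index (i, j, k) is origin + index * spacing.  Dose grids hold per-fraction
absorbed dose in Gy; RBE is evaluated at the fraction dose because the models
are dose dependent, and total RBE-weighted dose is an n_fractions multiple.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .models import RBEModel, TissueParams, _rbe_from_proton_dose_arrays

__all__ = [
    "ScalarGrid",
    "PlanConfig",
    "StructureMask",
    "GridCongruenceError",
    "RBEComputeReport",
    "compute_rbe_grid",
    "compute_drbe_grid",
    "lateral_constant_field_mode",
]

QUANTITY_TAGS = ("dose_gy", "let_d_kev_um", "rbe", "drbe_gy_rbe")


class GridCongruenceError(ValueError):
    """Two grids that must share shape/spacing/origin do not."""


@dataclass
class ScalarGrid:
    """A 3-D scalar field (dose, LET_D, RBE or D_RBE) with geometry metadata.

    values[i, j, k] lives at physical position origin + (i, j, k) * spacing,
    all in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    quantity: str = "dose_gy"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ScalarGrid values must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive componentwise")
        if self.quantity in ("dose_gy", "let_d_kev_um"):
            if np.any(self.values < 0):
                raise ValueError(f"{self.quantity} values must be non-negative")
            if not np.all(np.isfinite(self.values)):
                raise ValueError(f"{self.quantity} values must be finite")
        elif np.any(np.isinf(self.values)):
            # NaN marks model-inapplicable voxels in rbe / drbe grids
            raise ValueError("grid values must not be infinite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Physical coordinates [mm] of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def like(self, values: np.ndarray, quantity: str) -> "ScalarGrid":
        return ScalarGrid(values, self.spacing, self.origin, quantity)


@dataclass(frozen=True)
class PlanConfig:
    """Fractionation scheme and reference-RBE convention of a plan."""

    prescription_drbe_per_fraction: float = 2.0   # Gy(RBE)
    n_fractions: int = 27
    reference_rbe: float = 1.1
    #: (grid axis, direction) per treatment field; +1 enters at index 0
    beam_axes: tuple[tuple[int, int], ...] = ((2, +1),)

    def __post_init__(self) -> None:
        if not self.prescription_drbe_per_fraction > 0:
            raise ValueError("prescription must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if not self.reference_rbe > 0:
            raise ValueError("reference_rbe must be positive")

    @property
    def prescription_dose_per_fraction(self) -> float:
        """Absorbed dose per fraction implied by the reference RBE [Gy]."""
        return self.prescription_drbe_per_fraction / self.reference_rbe


@dataclass
class StructureMask:
    """Boolean voxel mask congruent with the plan grids (PTV, OAR, body)."""

    mask: np.ndarray
    label: str = "PTV"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if self.label.upper() == "PTV" and not self.mask.any():
            raise ValueError("PTV mask must be non-empty")


def check_congruent(a: ScalarGrid, b: ScalarGrid, tol_mm: float = 1e-6) -> None:
    if a.shape != b.shape:
        raise GridCongruenceError(f"shape mismatch: {a.shape} vs {b.shape}")
    if np.any(np.abs(np.subtract(a.spacing, b.spacing)) > tol_mm):
        raise GridCongruenceError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
    if np.any(np.abs(np.subtract(a.origin, b.origin)) > tol_mm):
        raise GridCongruenceError(f"origin mismatch: {a.origin} vs {b.origin}")


@dataclass
class RBEComputeReport:
    """Bookkeeping of the voxel-wise RBE evaluation."""

    model: str
    tissue: str
    n_voxels: int
    n_low_dose: int          # below the floor: assigned the RBE_max asymptote
    n_inapplicable: int      # masked NaN (e.g. CAR below its LET bound)
    dose_floor_gy: float

    @property
    def inapplicable_fraction(self) -> float:
        return self.n_inapplicable / self.n_voxels


def compute_rbe_grid(model: RBEModel, dose: ScalarGrid, let_d: ScalarGrid,
                     tissue: TissueParams, dose_floor_gy: float = 1e-3,
                     ) -> tuple[ScalarGrid, RBEComputeReport]:
    """Evaluate an RBE model voxel-wise on congruent dose / LET_D grids.

    Voxels with dose below ``dose_floor_gy`` receive the zero-dose asymptote
    RBE_max (the finite-dose formula has D in denominators); voxels where the
    model is inapplicable (CAR below its LET bound) are set to NaN.  Both
    populations are counted in the returned report.
    """
    check_congruent(dose, let_d)
    if dose.quantity != "dose_gy" or let_d.quantity != "let_d_kev_um":
        raise ValueError("expected a dose_gy grid and a let_d_kev_um grid")

    let = let_d.values
    rmax, rmin = model.endpoint_arrays(let, tissue)
    low = dose.values < dose_floor_gy
    d_safe = np.where(low, 1.0, dose.values)
    rbe = _rbe_from_proton_dose_arrays(rmax, rmin, tissue.alpha_beta_x, d_safe)
    rbe = np.where(low, rmax, rbe)

    applicable = model.applicability_mask(let, tissue)
    rbe = np.where(applicable, rbe, np.nan)

    report = RBEComputeReport(
        model=model.name,
        tissue=tissue.name or f"ab={tissue.alpha_beta_x:g}",
        n_voxels=int(dose.values.size),
        n_low_dose=int(np.count_nonzero(low)),
        n_inapplicable=int(np.count_nonzero(~applicable)),
        dose_floor_gy=dose_floor_gy,
    )
    return dose.like(rbe, "rbe"), report


def compute_drbe_grid(rbe: ScalarGrid, dose: ScalarGrid, plan: PlanConfig,
                      total: bool = False) -> ScalarGrid:
    """RBE-weighted dose D_RBE = RBE * D, per fraction (default) or total."""
    check_congruent(rbe, dose)
    if rbe.quantity != "rbe" or dose.quantity != "dose_gy":
        raise ValueError("expected an rbe grid and a dose_gy grid")
    drbe = rbe.values * dose.values
    if total:
        drbe = drbe * plan.n_fractions
    return dose.like(drbe, "drbe_gy_rbe")


def lateral_constant_field_mode(let_d: ScalarGrid, beam_axis: int) -> ScalarGrid:
    """Replace each depth slice of a LET_D grid by its central-axis value.

    Emulates a treatment-planning-system approximation in which the mixed
    radiation field composition is taken constant across the lateral plane at
    each depth: every lateral position inherits the LET_D of the voxel
    nearest the field's lateral centroid.  Used upstream of
    :func:`compute_rbe_grid` to build the "TPS"-mode comparison.
    """
    if beam_axis not in (0, 1, 2):
        raise ValueError("beam_axis must be 0, 1 or 2")
    vals = let_d.values
    field_mask = vals > 0
    if not field_mask.any():
        raise ValueError("empty field: no positive LET_D voxels")
    lateral_axes = tuple(ax for ax in range(3) if ax != beam_axis)
    # lateral centroid of the field footprint, then nearest voxel
    idx = [np.arange(n) for n in vals.shape]
    centre = []
    footprint = field_mask.any(axis=beam_axis)
    w = footprint.astype(float)
    for k, ax in enumerate(lateral_axes):
        coords = idx[ax]
        marg = w.sum(axis=1 - k)
        centre.append(int(round((coords * marg).sum() / marg.sum())))
    sl = [slice(None)] * 3
    sl[lateral_axes[0]] = slice(centre[0], centre[0] + 1)
    sl[lateral_axes[1]] = slice(centre[1], centre[1] + 1)
    axis_column = vals[tuple(sl)]          # shape 1 x 1 along lateral axes
    out = np.broadcast_to(axis_column, vals.shape).copy()
    return let_d.like(out, "let_d_kev_um")
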