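"""Plan-level analyses: volume histograms, beam-eye-view fall-off depths,
biological range-shift maps and lateral penumbra widths.

The biological range shift compares, ray by ray in beam-eye-view, the depth
at which the RBE-weighted dose falls to x % of the prescription (x = 90, 80,
50 by default) between a variable-RBE D_RBE profile and the reference
1.1 * physical-dose profile:

    R_x_shift = R_x(varRBE) - R_x(RBE = 1.1)

Rays whose profiles never reach a level are excluded, as are rays whose
distal fall-off is shallower than a gradient threshold (default 30 mm/Gy) on
either profile.  All interpolation is linear in depth; no smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .grids import ScalarGrid, StructureMask, check_congruent

__all__ = [
    "VolumeHistogram",
    "DepthProfile",
    "RangeShiftResult",
    "NOT_REACHED",
    "cumulative_volume_histogram",
    "dose_at_volume",
    "extract_bev_profiles",
    "distal_falloff_depth",
    "falloff_gradient",
    "range_shift",
    "range_shift_summary",
    "range_shift_analysis",
    "lateral_falloff_8020",
    "LateralFalloff",
]

#: sentinel for profiles that never reach a dose level
NOT_REACHED = None

DEFAULT_LEVELS = (0.9, 0.8, 0.5)
DEFAULT_GRADIENT_THRESHOLD_MM_PER_GY = 30.0
DEFAULT_SHIFT_BIN_MM = 0.3


@dataclass
class VolumeHistogram:
    """Cumulative volume histogram V(>= value) in percent of structure volume."""

    edges: np.ndarray                 # bin lower edges, quantity units
    cumulative_pct: np.ndarray        # V(>= edge) [%], non-increasing
    label: str
    quantity: str
    values: np.ndarray | None = None  # masked voxel values (finite), if retained
    n_nan: int = 0

    def volume_at(self, value: float) -> float:
        """V(>= value) [%] by linear interpolation of the cumulative curve."""
        return float(np.interp(value, self.edges, self.cumulative_pct))


def cumulative_volume_histogram(grid: ScalarGrid, mask: StructureMask,
                                bin_width: float | None = None,
                                keep_values: bool = True) -> VolumeHistogram:
    """Cumulative histogram of a scalar quantity over a structure.

    Default bin width is 0.01 Gy for dose-like quantities and 0.1 keV/um for
    LET.  Non-finite voxels (e.g. model-inapplicable NaNs) are dropped and
    counted; percentages are relative to the finite masked volume.
    """
    if grid.shape != mask.mask.shape:
        raise ValueError("mask shape does not match grid")
    if not mask.mask.any():
        raise ValueError(f"empty mask for structure {mask.label!r}")
    if bin_width is None:
        bin_width = 0.1 if grid.quantity == "let_d_kev_um" else 0.01
    vals = grid.values[mask.mask]
    finite = np.isfinite(vals)
    n_nan = int(np.count_nonzero(~finite))
    vals = vals[finite]
    if vals.size == 0:
        raise ValueError("no finite voxels in structure")
    edges = np.arange(0.0, vals.max() + 2 * bin_width, bin_width)
    # V(>= edge): fraction of voxels at or above each lower edge
    sorted_vals = np.sort(vals)
    above = vals.size - np.searchsorted(sorted_vals, edges, side="left")
    cumulative = 100.0 * above / vals.size
    return VolumeHistogram(
        edges=edges,
        cumulative_pct=cumulative,
        label=mask.label,
        quantity=grid.quantity,
        values=sorted_vals if keep_values else None,
        n_nan=n_nan,
    )


def dose_at_volume(h: VolumeHistogram, volume_pct: float) -> float:
    """Quantity value received by at least ``volume_pct`` % of the structure.

    D_95 is the near-minimum (95 % of the volume gets at least this),
    D_5 the near-maximum.  When the histogram retains its voxel values the
    result is the Hazen-interpolated quantile ((k - 0.5)/n plotting
    positions), which matches a sort-based brute-force evaluation; otherwise
    the cumulative curve is inverted by linear interpolation.
    """
    if not 0.0 < volume_pct < 100.0:
        raise ValueError("volume_pct must be in (0, 100)")
    if h.values is not None:
        return float(np.quantile(h.values, 1.0 - volume_pct / 100.0, method="hazen"))
    v = h.cumulative_pct
    e = h.edges
    # cumulative is non-increasing in value; invert on the reversed curve
    return float(np.interp(volume_pct, v[::-1], e[::-1]))


@dataclass
class DepthProfile:
    """1-D samples of a quantity along one beam-eye-view ray."""

    depths: np.ndarray         # mm from the entrance, strictly increasing
    values: np.ndarray
    ray: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.ndim != 1 or self.depths.shape != self.values.shape:
            raise ValueError("depths and values must be matching 1-D arrays")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")


def extract_bev_profiles(grid: ScalarGrid, beam_axis: int,
                         body_mask: StructureMask | None = None,
                         direction: int = +1) -> list[DepthProfile]:
    """One depth profile per lateral voxel column, entrance -> exit.

    ``direction = +1`` means the beam enters at index 0 along ``beam_axis``;
    ``-1`` flips the depth ordering.  Only columns intersecting ``body_mask``
    (or with any positive value, when no mask is given) are returned.
    """
    if beam_axis not in (0, 1, 2):
        raise ValueError(f"beam_axis {beam_axis} not a grid axis")
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    vals = np.moveaxis(grid.values, beam_axis, -1)
    if body_mask is not None:
        if body_mask.mask.shape != grid.shape:
            raise ValueError("body mask shape mismatch")
        footprint = np.moveaxis(body_mask.mask, beam_axis, -1).any(axis=-1)
    else:
        footprint = (vals > 0).any(axis=-1)
    n = vals.shape[-1]
    step = grid.spacing[beam_axis]
    depths = step * np.arange(n)
    profiles = []
    for i, j in zip(*np.nonzero(footprint)):
        column = vals[i, j, :]
        if direction == -1:
            column = column[::-1]
        profiles.append(DepthProfile(depths=depths, values=column.copy(), ray=(int(i), int(j))))
    return profiles


def _distal_crossing(depths: np.ndarray, values: np.ndarray, threshold: float):
    """Distal-most downward crossing of ``threshold`` beyond the profile max."""
    finite = np.isfinite(values)
    if not finite.any() or np.nanmax(values) < threshold:
        return NOT_REACHED
    m = int(np.nanargmax(values))
    idx = NOT_REACHED
    for i in range(m, len(values) - 1):
        if finite[i] and finite[i + 1] and values[i] >= threshold > values[i + 1]:
            idx = i
    if idx is NOT_REACHED:
        return NOT_REACHED
    d0, d1 = depths[idx], depths[idx + 1]
    v0, v1 = values[idx], values[idx + 1]
    return float(d0 + (v0 - threshold) / (v0 - v1) * (d1 - d0))


def distal_falloff_depth(p: DepthProfile, level_fraction: float, d_presc: float):
    """Depth R_x where the profile falls to ``level_fraction * d_presc``.

    Scans distally from the profile maximum and takes the distal-most
    crossing (guarding against proximal dips), locating it by linear
    interpolation between the bracketing samples.  Returns ``NOT_REACHED``
    (None) when the profile never reaches the level.
    """
    if not 0.0 < level_fraction < 1.0:
        raise ValueError("level_fraction must be in (0, 1)")
    return _distal_crossing(p.depths, p.values, level_fraction * d_presc)


def falloff_gradient(p: DepthProfile, d_presc: float):
    """Distal fall-off shallowness (R_20% - R_80%) / (0.6 d_presc) [mm/Gy].

    Returns ``NOT_REACHED`` when either level is not crossed.  Rays with a
    gradient above the threshold (default 30 mm/Gy) are excluded from
    range-shift statistics as too shallow to locate reliably.
    """
    r80 = _distal_crossing(p.depths, p.values, 0.8 * d_presc)
    r20 = _distal_crossing(p.depths, p.values, 0.2 * d_presc)
    if r80 is NOT_REACHED or r20 is NOT_REACHED:
        return NOT_REACHED
    return (r20 - r80) / (0.6 * d_presc)


def range_shift(reference: DepthProfile, variable: DepthProfile,
                levels=DEFAULT_LEVELS, d_presc: float = 2.0,
                gradient_threshold: float = DEFAULT_GRADIENT_THRESHOLD_MM_PER_GY,
                ) -> dict[float, float | str]:
    """Per-level biological range shift R_x(var) - R_x(ref) for one ray.

    ``reference`` is the 1.1 * physical-dose profile, ``variable`` the
    variable-RBE D_RBE profile of the same ray.  Levels where either profile
    fails the gradient filter map to ``"gradient"``; levels not reached by
    either profile map to ``"level"``.
    """
    out: dict[float, float | str] = {}
    g_ref = falloff_gradient(reference, d_presc)
    g_var = falloff_gradient(variable, d_presc)
    gradient_ok = (
        g_ref is not NOT_REACHED and g_var is not NOT_REACHED
        and g_ref <= gradient_threshold and g_var <= gradient_threshold
    )
    for lv in levels:
        r_ref = distal_falloff_depth(reference, lv, d_presc)
        r_var = distal_falloff_depth(variable, lv, d_presc)
        if r_ref is NOT_REACHED or r_var is NOT_REACHED:
            out[lv] = "level"
        elif not gradient_ok:
            out[lv] = "gradient"
        else:
            out[lv] = r_var - r_ref
    return out


@dataclass
class RangeShiftResult:
    """Aggregated biological range shifts over all beam-eye-view rays."""

    levels: tuple[float, ...]
    shift_maps: dict[float, np.ndarray]        # 2-D, NaN where excluded
    histograms: dict[float, tuple[np.ndarray, np.ndarray]]  # (counts, edges)
    mean_shift_mm: dict[float, float]
    n_retained: dict[float, int]
    n_excluded_gradient: dict[float, int]
    n_excluded_level: dict[float, int]
    n_rays: int
    records: list[dict] | None = None   # per-ray detail rows for CSV export

    def summary_dict(self) -> dict:
        """JSON-ready summary keyed by level percentage."""
        return {
            f"{lv:.0%}": {
                "mean": self.mean_shift_mm[lv],
                "n_retained": self.n_retained[lv],
                "n_excluded_gradient": self.n_excluded_gradient[lv],
                "n_excluded_level": self.n_excluded_level[lv],
            }
            for lv in self.levels
        }


def range_shift_summary(per_ray: dict[tuple[int, int], dict[float, float | str]],
                        map_shape: tuple[int, int],
                        levels=DEFAULT_LEVELS,
                        bin_width_mm: float = DEFAULT_SHIFT_BIN_MM) -> RangeShiftResult:
    """Maps, frequency histograms and means of per-ray range shifts.

    The histogram mass at each level equals the retained-ray count;
    retained + excluded(gradient) + excluded(level) = total rays.
    """
    if not per_ray:
        raise ValueError("no rays to summarise")
    maps, hists, means = {}, {}, {}
    n_ret, n_grad, n_lvl = {}, {}, {}
    for lv in levels:
        m = np.full(map_shape, np.nan)
        shifts = []
        grad = lvl = 0
        for (i, j), res in per_ray.items():
            v = res.get(lv, "level")
            if v == "gradient":
                grad += 1
            elif v == "level":
                lvl += 1
            else:
                m[i, j] = v
                shifts.append(v)
        if not shifts:
            raise ValueError(f"zero retained rays at level {lv:.0%}")
        shifts = np.asarray(shifts)
        lo = np.floor(shifts.min() / bin_width_mm) * bin_width_mm
        hi = np.ceil(shifts.max() / bin_width_mm) * bin_width_mm + bin_width_mm
        edges = np.arange(lo, hi + 0.5 * bin_width_mm, bin_width_mm)
        counts, edges = np.histogram(shifts, bins=edges)
        maps[lv] = m
        hists[lv] = (counts, edges)
        means[lv] = float(shifts.mean())
        n_ret[lv], n_grad[lv], n_lvl[lv] = len(shifts), grad, lvl
    return RangeShiftResult(
        levels=tuple(levels), shift_maps=maps, histograms=hists,
        mean_shift_mm=means, n_retained=n_ret,
        n_excluded_gradient=n_grad, n_excluded_level=n_lvl,
        n_rays=len(per_ray),
    )


def range_shift_analysis(reference: ScalarGrid, variable: ScalarGrid,
                         beam_axis: int, d_presc: float,
                         levels=DEFAULT_LEVELS, direction: int = +1,
                         gradient_threshold: float = DEFAULT_GRADIENT_THRESHOLD_MM_PER_GY,
                         bin_width_mm: float = DEFAULT_SHIFT_BIN_MM,
                         body_mask: StructureMask | None = None) -> RangeShiftResult:
    """Full-grid range-shift analysis: profiles, per-ray shifts, summary."""
    check_congruent(reference, variable)
    refs = extract_bev_profiles(reference, beam_axis, body_mask, direction)
    vars_ = extract_bev_profiles(variable, beam_axis, body_mask, direction)
    var_by_ray = {p.ray: p for p in vars_}
    per_ray = {}
    records = []
    for p_ref in refs:
        p_var = var_by_ray.get(p_ref.ray)
        if p_var is None:
            continue
        res = range_shift(p_ref, p_var, levels, d_presc, gradient_threshold)
        per_ray[p_ref.ray] = res
        for lv, v in res.items():
            r_ref = distal_falloff_depth(p_ref, lv, d_presc)
            r_var = distal_falloff_depth(p_var, lv, d_presc)
            records.append({
                "level_pct": round(100 * lv),
                "ray_i": p_ref.ray[0], "ray_j": p_ref.ray[1],
                "r_ref_mm": np.nan if r_ref is NOT_REACHED else r_ref,
                "r_var_mm": np.nan if r_var is NOT_REACHED else r_var,
                "shift_mm": v if isinstance(v, float) else np.nan,
                "excluded_reason": "" if isinstance(v, float) else v,
            })
    lateral_axes = tuple(ax for ax in range(3) if ax != beam_axis)
    map_shape = (reference.shape[lateral_axes[0]], reference.shape[lateral_axes[1]])
    out = range_shift_summary(per_ray, map_shape, levels, bin_width_mm)
    out.records = records
    return out


@dataclass
class LateralFalloff:
    """80-20 % penumbra widths of a lateral profile [mm]."""

    left_mm: float | None
    right_mm: float | None
    mean_mm: float
    central_value: float


def _edge_width(positions, values, centre_idx, central, step, low, high):
    """Width between the high and low crossings on one side of the centre."""
    hi_thr, lo_thr = high * central, low * central
    n = len(values)
    rng = range(centre_idx, n - 1) if step > 0 else range(centre_idx, 0, -1)
    p_hi = p_lo = None
    for i in rng:
        j = i + (1 if step > 0 else -1)
        v0, v1 = values[i], values[j]
        if p_hi is None and v0 >= hi_thr > v1:
            p_hi = positions[i] + (v0 - hi_thr) / (v0 - v1) * (positions[j] - positions[i])
        if p_lo is None and v0 >= lo_thr > v1:
            p_lo = positions[i] + (v0 - lo_thr) / (v0 - v1) * (positions[j] - positions[i])
        if p_hi is not None and p_lo is not None:
            break
    if p_hi is None or p_lo is None:
        return None
    return abs(p_lo - p_hi)


def lateral_falloff_8020(positions, values, centre_index: int | None = None,
                         low: float = 0.2, high: float = 0.8) -> LateralFalloff:
    """80-20 % lateral fall-off width of a plateau-with-edges profile.

    The thresholds are fractions of the central-axis value (the sample at
    ``centre_index``, default the middle of the profile).  Each edge's width
    is the distance between its 80 % and 20 % crossings, located by linear
    interpolation; the mean over the available edges is returned.  A profile
    with no crossing on either side is an error.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if positions.shape != values.shape or positions.ndim != 1:
        raise ValueError("positions and values must be matching 1-D arrays")
    if centre_index is None:
        centre_index = len(values) // 2
    central = values[centre_index]
    if not np.isfinite(central) or central <= 0:
        raise ValueError("central-axis value must be positive and finite")
    right = _edge_width(positions, values, centre_index, central, +1, low, high)
    left = _edge_width(positions, values, centre_index, central, -1, low, high)
    widths = [w for w in (left, right) if w is not None]
    if not widths:
        raise ValueError("no 80-20 % crossing found on either edge")
    return LateralFalloff(left_mm=left, right_mm=right,
                          mean_mm=float(np.mean(widths)), central_value=float(central))
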