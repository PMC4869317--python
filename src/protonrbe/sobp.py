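"""Analytic spread-out-Bragg-peak phantoms: dose + LET_D grids.

A parametric stand-in for Monte Carlo input data, good enough to exercise
every pipeline stage: pristine peaks are an entrance plateau with a Gaussian
Bragg bump and an erfc (Gaussian-straggled) distal edge; an SOBP is a
non-negative-least-squares superposition of pristine peaks fitted to a flat
plateau over the target depth interval; the lateral profile is a
Gaussian-blurred box whose sigma grows linearly with depth; LET_D rises
monotonically with depth, is pinned to a distal-edge value at the distal
20 %-dose depth, and is enhanced off-axis in proportion to the local dose
deficit (a simple monotone surrogate for the stopping-halo physics of
primary protons and higher-LET secondaries).

Defaults emulate the study conditions used throughout: a 150 x 90 x 40 mm
target box centred at 76 mm depth receiving 2 Gy(RBE) / 1.1 = 1.818 Gy
absorbed dose per fraction on a 1 mm isotropic grid, with entrance LET_D
1 keV/um rising to 10 keV/um at the distal edge (the observed distal range
being 8-12 keV/um).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy.optimize import nnls
from scipy.special import erf, ndtr, ndtri

from .grids import ScalarGrid, StructureMask

__all__ = [
    "PristinePeak",
    "SOBPSpec",
    "LETModelParams",
    "SOBPPhantom",
    "TwoFieldPhantom",
    "pristine_depth_dose",
    "optimize_sobp_weights",
    "let_d_depth_curve",
    "generate_sobp_grid",
    "generate_two_field_phantom",
    "default_sobp_spec",
]

# Bragg bump sits this many straggling sigmas proximal of the erfc midpoint
_PEAK_OFFSET_SIGMA = 1.45
# slow quadratic rise of the entrance plateau toward the peak
_ENTRANCE_RISE = 0.3


@dataclass(frozen=True)
class PristinePeak:
    """One pencil-beam depth-dose curve.

    ``range_mm`` is the depth of the distal 80 % point; ``peak_width_mm`` is
    the range-straggling sigma shaping both the Bragg bump and the erfc
    distal edge (distal 80-20 % width ~ 1.6 sigma).
    """

    range_mm: float
    peak_width_mm: float = 2.5
    entrance_peak_ratio: float = 0.30
    sigma_lateral0_mm: float = 4.0
    sigma_lateral_growth: float = 0.05   # mm of sigma per mm of depth

    def __post_init__(self) -> None:
        if not self.range_mm > 0 or not self.peak_width_mm > 0:
            raise ValueError("range and peak width must be positive")
        if not 0.0 < self.entrance_peak_ratio < 1.0:
            raise ValueError("entrance_peak_ratio must be in (0, 1)")

    def sigma_lateral_mm(self, depth_mm) -> np.ndarray:
        """Lateral Gaussian sigma at depth: initial value plus linear growth."""
        return self.sigma_lateral0_mm + self.sigma_lateral_growth * np.asarray(depth_mm, float)


def _pristine_raw(peak: PristinePeak, z: np.ndarray) -> np.ndarray:
    sig = peak.peak_width_mm
    peak_height = ndtr(_PEAK_OFFSET_SIGMA)
    zc = peak.range_mm + ndtri(0.8 * peak_height) * sig
    zp = zc - _PEAK_OFFSET_SIGMA * sig
    edge = ndtr(-(z - zc) / sig)
    r = peak.entrance_peak_ratio
    base = r * (1.0 + _ENTRANCE_RISE * (z / zp) ** 2)
    bump = base + (1.0 - r * (1.0 + _ENTRANCE_RISE)) * np.exp(-((z - zp) ** 2) / (2.0 * sig**2))
    return np.where(z <= zp, bump, 1.0) * edge


def pristine_depth_dose(peak: PristinePeak, depths) -> np.ndarray:
    """Relative depth-dose of one pristine peak, normalised to max = 1.

    The normalisation constant is the curve's true maximum, located
    numerically on a fine internal grid around the Bragg bump so that the
    returned values are independent of the caller's sampling.
    """
    z = np.asarray(depths, dtype=float)
    if np.any(z < 0):
        raise ValueError("depths must be non-negative")
    sig = peak.peak_width_mm
    zfine = np.linspace(max(0.0, peak.range_mm - 6 * sig),
                        peak.range_mm + 2 * sig, 400)
    return _pristine_raw(peak, z) / _pristine_raw(peak, zfine).max()


@dataclass(frozen=True)
class SOBPSpec:
    """Geometry and delivery of the synthetic SOBP field."""

    box_lateral_mm: tuple[float, float] = (150.0, 90.0)
    box_depth_extent_mm: float = 40.0
    box_centre_depth_mm: float = 76.0
    plateau_dose_gy: float = 2.0 / 1.1      # absorbed dose per fraction
    n_peaks: int = 16
    grid_spacing_mm: float = 1.0
    lateral_margin_mm: float = 20.0
    depth_margin_mm: float = 25.0
    peak_width_mm: float = 1.8
    entrance_peak_ratio: float = 0.30
    # calibrated so the RBE=1.1 lateral 80-20 % fall-off at mid-SOBP depth
    # (sigma ~ 7.8 mm -> 13.1 mm penumbra) matches the ~13.3 mm observed for
    # a scanned proton field at this depth
    sigma_lateral0_mm: float = 4.0
    sigma_lateral_growth: float = 0.05
    noise_sigma: float = 0.0                # multiplicative Gaussian, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.plateau_dose_gy > 0:
            raise ValueError("plateau dose must be positive")
        if self.box_centre_depth_mm - 0.5 * self.box_depth_extent_mm <= 0:
            raise ValueError("target box extends above the surface")
        if self.n_peaks < 1:
            raise ValueError("need at least one pristine peak")

    @property
    def depth_interval_mm(self) -> tuple[float, float]:
        half = 0.5 * self.box_depth_extent_mm
        return (self.box_centre_depth_mm - half, self.box_centre_depth_mm + half)

    def pristine_peaks(self) -> list[PristinePeak]:
        # The Bragg maximum sits ~0.9 sigma proximal of the nominal (distal
        # 80 %) range, so the deepest peak is pushed that far past the distal
        # box edge to hold the plateau all the way to it.
        z0, z1 = self.depth_interval_mm
        peak_height = ndtr(_PEAK_OFFSET_SIGMA)
        deepest = z1 + (_PEAK_OFFSET_SIGMA - ndtri(0.8 * peak_height)) * self.peak_width_mm
        ranges = np.linspace(z0, deepest, self.n_peaks) if self.n_peaks > 1 else [deepest]
        return [
            PristinePeak(
                range_mm=float(r),
                peak_width_mm=self.peak_width_mm,
                entrance_peak_ratio=self.entrance_peak_ratio,
                sigma_lateral0_mm=self.sigma_lateral0_mm,
                sigma_lateral_growth=self.sigma_lateral_growth,
            )
            for r in ranges
        ]


def default_sobp_spec(**overrides) -> SOBPSpec:
    """The default study phantom; keyword overrides replace single fields."""
    return replace(SOBPSpec(), **overrides) if overrides else SOBPSpec()


@dataclass(frozen=True)
class LETModelParams:
    """Parameters of the analytic LET_D model."""

    entrance_let_kev_um: float = 1.0
    distal_let_kev_um: float = 10.0         # pinned at the distal 20 %-dose depth
    lateral_enhancement: float = 1.5        # asymptotic off-axis factor
    rise_per_mm: float = 0.01               # linear growth term through the SOBP
    edge_sharpness_mm: float = 2.0          # e-folding of the distal surge

    def __post_init__(self) -> None:
        if not self.distal_let_kev_um > self.entrance_let_kev_um > 0:
            raise ValueError("need distal LET > entrance LET > 0")
        if self.lateral_enhancement < 1.0:
            raise ValueError("lateral enhancement must be >= 1")


def optimize_sobp_weights(peaks: list[PristinePeak], spec: SOBPSpec,
                          fit_step_mm: float = 0.5) -> np.ndarray:
    """Non-negative least-squares pristine-peak weights for a flat plateau.

    The summed depth-dose is fitted to ``spec.plateau_dose_gy`` on the target
    depth interval only; the entrance and distal fall-off follow from the
    physics of the weighted sum.  Raises if no peak covers the target.
    """
    if not peaks:
        raise ValueError("no pristine peaks supplied")
    z0, z1 = spec.depth_interval_mm
    if max(p.range_mm for p in peaks) < z1 - 1e-9:
        raise ValueError("deepest peak does not reach the distal target edge")
    zfit = np.linspace(z0, z1, max(2, int(round((z1 - z0) / fit_step_mm)) + 1))
    a = np.column_stack([pristine_depth_dose(p, zfit) for p in peaks])
    if not np.any(a.max(axis=0) > 1e-3):
        raise ValueError("no peak covers the target depth interval")
    b = np.full(len(zfit), spec.plateau_dose_gy)
    weights, _ = nnls(a, b)
    return weights


def _sum_depth_dose(peaks, weights, z) -> np.ndarray:
    return sum(w * pristine_depth_dose(p, z) for p, w in zip(peaks, weights))


def let_d_depth_curve(params: LETModelParams, depths: np.ndarray,
                      distal20_depth_mm: float) -> np.ndarray:
    """Monotone LET_D(z): slow rise through the SOBP, surge across the edge.

    LET_D(0) equals the entrance value and LET_D at ``distal20_depth_mm``
    (the depth where the SOBP dose has fallen to 20 % of the plateau) equals
    the distal-edge value; the curve keeps rising for a few mm beyond.
    """
    z = np.asarray(depths, dtype=float)
    s = params.edge_sharpness_mm
    raw = params.rise_per_mm * z + np.exp((z - distal20_depth_mm) / s)
    raw0 = np.exp(-distal20_depth_mm / s)
    raw_end = params.rise_per_mm * distal20_depth_mm + 1.0
    f = (raw - raw0) / (raw_end - raw0)
    return params.entrance_let_kev_um + (
        params.distal_let_kev_um - params.entrance_let_kev_um) * f


@dataclass
class SOBPPhantom:
    """A generated single-field phantom and its 1-D building blocks."""

    dose: ScalarGrid
    let_d: ScalarGrid
    ptv: StructureMask
    spec: SOBPSpec
    let_params: LETModelParams
    weights: np.ndarray
    depths_mm: np.ndarray            # voxel-centre depths along the beam axis
    axis_depth_dose_gy: np.ndarray   # fitted on-axis depth-dose curve
    let_depth_curve: np.ndarray
    beam_axis: int = 2
    direction: int = +1


def _lateral_box_profile(x: np.ndarray, half_width: float, sigma: np.ndarray) -> np.ndarray:
    """Gaussian-blurred box transmission on the lateral axis, per depth.

    Returns an (n_x, n_z) array for depth-dependent sigma.
    """
    xx = x[:, None]
    ss = np.maximum(sigma[None, :], 1e-9)
    return 0.5 * (erf((xx + half_width) / (np.sqrt(2.0) * ss))
                  - erf((xx - half_width) / (np.sqrt(2.0) * ss)))


def generate_sobp_grid(spec: SOBPSpec | None = None,
                       let_params: LETModelParams | None = None,
                       depth_length_mm: float | None = None) -> SOBPPhantom:
    """Generate congruent dose / LET_D grids and the PTV mask.

    The beam travels along grid axis 2 (+z, entering at k = 0).  Identical
    spec + seed gives bit-identical grids.
    """
    spec = spec or SOBPSpec()
    let_params = let_params or LETModelParams()
    step = spec.grid_spacing_mm
    z0, z1 = spec.depth_interval_mm
    zmax = depth_length_mm if depth_length_mm is not None else z1 + spec.depth_margin_mm
    if zmax < z1 + 5 * spec.peak_width_mm:
        raise ValueError("grid too shallow for the target box and its fall-off")
    half_x = 0.5 * spec.box_lateral_mm[0] + spec.lateral_margin_mm
    half_y = 0.5 * spec.box_lateral_mm[1] + spec.lateral_margin_mm

    x = np.arange(-half_x, half_x + 0.5 * step, step)
    y = np.arange(-half_y, half_y + 0.5 * step, step)
    z = np.arange(0.0, zmax + 0.5 * step, step)

    peaks = spec.pristine_peaks()
    weights = optimize_sobp_weights(peaks, spec)
    axis_dose = _sum_depth_dose(peaks, weights, z)

    sig_lat = peaks[0].sigma_lateral_mm(z)
    tx = _lateral_box_profile(x, 0.5 * spec.box_lateral_mm[0], sig_lat)   # (nx, nz)
    ty = _lateral_box_profile(y, 0.5 * spec.box_lateral_mm[1], sig_lat)   # (ny, nz)
    transmission = tx[:, None, :] * ty[None, :, :]                        # (nx, ny, nz)
    dose = axis_dose[None, None, :] * transmission

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        dose = np.clip(dose * (1.0 + spec.noise_sigma * rng.standard_normal(dose.shape)), 0.0, None)

    # distal 20 %-dose depth of the on-axis curve (beyond the plateau)
    m = int(np.argmax(axis_dose))
    thr = 0.2 * spec.plateau_dose_gy
    distal = axis_dose[m:]
    below = np.nonzero(distal < thr)[0]
    if len(below) == 0:
        raise ValueError("on-axis curve never falls to 20 % of the plateau")
    i = m + below[0] - 1
    z20 = float(np.interp(thr, [axis_dose[i + 1], axis_dose[i]], [z[i + 1], z[i]]))

    let_z = let_d_depth_curve(let_params, z, z20)
    enh = let_params.lateral_enhancement
    factor = 1.0 + (enh - 1.0) * np.clip(1.0 - transmission, 0.0, 1.0)
    let_vals = let_z[None, None, :] * factor

    origin = (float(x[0]), float(y[0]), 0.0)
    spacing = (step, step, step)
    dose_grid = ScalarGrid(dose, spacing, origin, "dose_gy")
    let_grid = ScalarGrid(let_vals, spacing, origin, "let_d_kev_um")

    in_x = np.abs(x) <= 0.5 * spec.box_lateral_mm[0]
    in_y = np.abs(y) <= 0.5 * spec.box_lateral_mm[1]
    in_z = (z >= z0) & (z <= z1)
    ptv = StructureMask(in_x[:, None, None] & in_y[None, :, None] & in_z[None, None, :], "PTV")

    return SOBPPhantom(
        dose=dose_grid, let_d=let_grid, ptv=ptv, spec=spec, let_params=let_params,
        weights=weights, depths_mm=z, axis_depth_dose_gy=axis_dose,
        let_depth_curve=let_z,
    )


@dataclass
class TwoFieldPhantom:
    """Two opposed fields: combined grids plus the per-field components."""

    dose: ScalarGrid
    let_d: ScalarGrid
    ptv: StructureMask
    fields: tuple[SOBPPhantom, SOBPPhantom]


def generate_two_field_phantom(spec: SOBPSpec | None = None,
                               let_params: LETModelParams | None = None,
                               ) -> TwoFieldPhantom:
    """Two opposed half-weight fields along +z / -z with a shared target box.

    The phantom length is twice the box-centre depth so the box occupies the
    same interval seen from either side; field B is the mirror of field A.
    Combined LET_D is the dose-weighted average of the per-field values (the
    superposition rule for dose-averaged LET); combined dose is the sum.
    """
    spec = spec or SOBPSpec()
    let_params = let_params or LETModelParams()
    half_spec = replace(spec, plateau_dose_gy=0.5 * spec.plateau_dose_gy)
    z0, z1 = spec.depth_interval_mm
    length = 2.0 * spec.box_centre_depth_mm
    if length < z1 + 5 * spec.peak_width_mm:
        raise ValueError("opposed-field targets do not overlap within the phantom")
    field_a = generate_sobp_grid(half_spec, let_params, depth_length_mm=length)

    flip = lambda arr: arr[:, :, ::-1].copy()
    dose_b = field_a.dose.like(flip(field_a.dose.values), "dose_gy")
    let_b = field_a.let_d.like(flip(field_a.let_d.values), "let_d_kev_um")
    field_b = SOBPPhantom(
        dose=dose_b, let_d=let_b, ptv=field_a.ptv, spec=half_spec,
        let_params=let_params, weights=field_a.weights,
        depths_mm=field_a.depths_mm, axis_depth_dose_gy=field_a.axis_depth_dose_gy,
        let_depth_curve=field_a.let_depth_curve, direction=-1,
    )

    da, db = field_a.dose.values, field_b.dose.values
    total = da + db
    with np.errstate(invalid="ignore", divide="ignore"):
        let_mix = np.where(
            total > 0,
            (field_a.let_d.values * da + field_b.let_d.values * db) / np.where(total > 0, total, 1.0),
            0.5 * (field_a.let_d.values + field_b.let_d.values),
        )
    dose_grid = field_a.dose.like(total, "dose_gy")
    let_grid = field_a.let_d.like(let_mix, "let_d_kev_um")
    return TwoFieldPhantom(dose=dose_grid, let_d=let_grid, ptv=field_a.ptv,
                           fields=(field_a, field_b))
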