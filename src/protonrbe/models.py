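"""Linear-quadratic RBE model mathematics for proton beams.

Implements the LQ iso-effect framework relating proton LQ parameters
(alpha, beta) to a photon reference (alpha_x, beta_x), the asymptotic
endpoints RBE_max = alpha/alpha_x (dose -> 0) and RBE_min = sqrt(beta/beta_x)
(dose -> infinity), and the three variable-RBE models compared in this
package:

* Carabe-Fernandez (CAR): both endpoints linear in LET_D with slopes scaled
  by 2.686 Gy / (alpha/beta)_x,
* Wedenberg (WED): RBE_max = 1 + 0.434 * LET / (alpha/beta)_x, beta = beta_x,
* a table-driven local effect model (LEM): alpha(LET), beta(LET) supplied
  externally and interpolated.

All dose arguments are per-fraction absorbed doses in Gy, LET values are
dose-averaged LET in keV/um unless the caller decides otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TissueParams",
    "RBEEndpoints",
    "LQParams",
    "ModelConstants",
    "CONSTANTS",
    "LEMTable",
    "lq_isoeffect_rbe",
    "car_endpoints",
    "wed_endpoints",
    "endpoints_to_lq",
    "rbe_from_photon_dose",
    "rbe_from_proton_dose",
    "car_applicable",
    "car_min_applicable_let",
    "lem_beta_z",
    "lem_table_lq",
    "RBEModel",
    "CarabeModel",
    "WedenbergModel",
    "LEMTableModel",
    "FixedRBEModel",
    "make_synthetic_lem_table",
    "TABLE1_TISSUES",
]

WED_LET_VALIDITY_KEV_UM = 30.0  # alpha/alpha_x stops rising linearly above this


@dataclass(frozen=True)
class ModelConstants:
    """Fixed published coefficients of the CAR and WED models."""

    car_max_intercept: float = 0.834
    car_max_slope: float = 0.154          # um/keV
    car_min_intercept: float = 1.09
    car_min_slope: float = 0.006          # um/keV
    car_reference_ab: float = 2.686       # Gy, V79 (alpha/beta)_x
    wed_q: float = 0.434                  # Gy um/keV
    car_ratio_threshold: float = 0.62     # keV/(um Gy), applicability bound


CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class TissueParams:
    """Photon LQ parameters defining a reference tissue.

    Parameters
    ----------
    alpha_x : float
        Photon linear coefficient [1/Gy].
    beta_x : float
        Photon quadratic coefficient [1/Gy^2].
    d_t : float, optional
        LEM transition dose [Gy] above which the photon survival curve is
        taken exponential with slope S_max = alpha_x + 2 beta_x d_t.  Only
        required by :func:`lem_beta_z`.
    name : str
        Free-form label.
    """

    alpha_x: float
    beta_x: float
    d_t: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.alpha_x > 0 and self.beta_x > 0):
            raise ValueError("alpha_x and beta_x must be positive")
        if self.d_t is not None and not self.d_t > 0:
            raise ValueError("d_t must be positive when given")

    @property
    def alpha_beta_x(self) -> float:
        """Photon (alpha/beta)_x ratio [Gy]."""
        return self.alpha_x / self.beta_x

    @classmethod
    def from_ratio(cls, alpha_x: float, alpha_beta_x: float,
                   d_t: float | None = None, name: str = "") -> "TissueParams":
        """Build a tissue from alpha_x and an exact (alpha/beta)_x ratio.

        The quadratic coefficient is derived as beta_x = alpha_x /
        (alpha/beta)_x so that every ratio-based formula (model endpoint
        scaling, applicability bounds, the dose-dependence closed forms) sees
        the stated ratio exactly.
        """
        if not alpha_beta_x > 0:
            raise ValueError("alpha_beta_x must be positive")
        return cls(alpha_x=alpha_x, beta_x=alpha_x / alpha_beta_x, d_t=d_t, name=name)


#: The two representative tissues used throughout the analyses: a
#: late-responding tissue with (alpha/beta)_x = 2 Gy and an early-responding
#: tissue / typical tumour with (alpha/beta)_x = 10 Gy.  The stated ratio is
#: authoritative (it sets the model endpoint slopes and the CAR
#: applicability bounds), so beta_x is derived from alpha_x and the ratio;
#: for the 2 Gy tissue that gives 0.0615 rather than the independently
#: rounded 0.0616.
TABLE1_TISSUES: dict[str, TissueParams] = {
    "ab2": TissueParams.from_ratio(alpha_x=0.123, alpha_beta_x=2.0, name="ab2"),
    "ab10": TissueParams.from_ratio(alpha_x=0.616, alpha_beta_x=10.0, name="ab10"),
}


@dataclass(frozen=True)
class RBEEndpoints:
    """Asymptotic RBE pair: RBE_max at zero dose, RBE_min at infinite dose."""

    rbe_max: float
    rbe_min: float

    def __post_init__(self) -> None:
        if not (self.rbe_max > 0 and self.rbe_min > 0):
            raise ValueError("endpoints must be positive")


@dataclass(frozen=True)
class LQParams:
    """Proton linear-quadratic coefficients."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")


def _check_let(let) -> np.ndarray:
    let = np.asarray(let, dtype=float)
    if np.any(let < 0):
        raise ValueError("LET must be non-negative")
    return let


def _check_dose(dose, name: str = "dose") -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    if np.any(dose <= 0):
        raise ValueError(f"{name} must be positive")
    return dose


def lq_isoeffect_rbe(lq: LQParams, tissue: TissueParams, photon_dose) -> float | np.ndarray:
    """RBE from the LQ iso-effect condition alpha D + beta D^2 = alpha_x D_x + beta_x D_x^2.

    Returns the positive root of
    ``(alpha_x + beta_x D_x) RBE^2 - alpha RBE - beta D_x = 0``.
    """
    d_x = _check_dose(photon_dose, "photon_dose")
    a = tissue.alpha_x + tissue.beta_x * d_x
    disc = lq.alpha**2 + 4.0 * lq.beta * d_x * a
    assert np.all(disc >= 0)
    rbe = (lq.alpha + np.sqrt(disc)) / (2.0 * a)
    return rbe if rbe.ndim else float(rbe)


def car_endpoints(let: float, tissue: TissueParams,
                  constants: ModelConstants = CONSTANTS) -> RBEEndpoints:
    """Carabe-Fernandez endpoints, linear in LET with reciprocal (alpha/beta)_x scaling."""
    let = float(_check_let(let))
    scale = constants.car_reference_ab / tissue.alpha_beta_x
    return RBEEndpoints(
        rbe_max=constants.car_max_intercept + constants.car_max_slope * scale * let,
        rbe_min=constants.car_min_intercept + constants.car_min_slope * scale * let,
    )


def wed_endpoints(let: float, tissue: TissueParams,
                  constants: ModelConstants = CONSTANTS) -> RBEEndpoints:
    """Wedenberg endpoints: RBE_max = 1 + q LET / (alpha/beta)_x, RBE_min = 1.

    Emits a warning above 30 keV/um, where the linear alpha/alpha_x
    dependence is no longer supported by the underlying data.
    """
    let = float(_check_let(let))
    if let > WED_LET_VALIDITY_KEV_UM:
        warnings.warn(
            f"Wedenberg model queried at LET = {let:.3g} keV/um, beyond its "
            f"{WED_LET_VALIDITY_KEV_UM:g} keV/um validity bound",
            stacklevel=2,
        )
    return RBEEndpoints(
        rbe_max=1.0 + constants.wed_q * let / tissue.alpha_beta_x,
        rbe_min=1.0,
    )


def endpoints_to_lq(e: RBEEndpoints, tissue: TissueParams) -> LQParams:
    """Invert the endpoint definitions: alpha = RBE_max alpha_x, beta = RBE_min^2 beta_x."""
    return LQParams(alpha=e.rbe_max * tissue.alpha_x, beta=e.rbe_min**2 * tissue.beta_x)


def rbe_from_photon_dose(e: RBEEndpoints, tissue: TissueParams, photon_dose) -> float | np.ndarray:
    """RBE as a function of the photon reference dose D_x.

    Closed form obtained by substituting the endpoint definitions into the
    iso-effect root:

    ``RBE = [r RBE_max + sqrt(r^2 RBE_max^2 + 4 D_x (r + D_x) RBE_min^2)] / (2 (r + D_x))``

    with r = (alpha/beta)_x.
    """
    d_x = _check_dose(photon_dose, "photon_dose")
    r = tissue.alpha_beta_x
    num = r * e.rbe_max + np.sqrt(
        r**2 * e.rbe_max**2 + 4.0 * d_x * (r + d_x) * e.rbe_min**2
    )
    rbe = num / (2.0 * (r + d_x))
    return rbe if rbe.ndim else float(rbe)


def _rbe_from_proton_dose_arrays(rbe_max, rbe_min, alpha_beta_x: float, proton_dose):
    """Vectorised kernel shared with the voxel engine."""
    d = np.asarray(proton_dose, dtype=float)
    r = alpha_beta_x
    return (-r / (2.0 * d)
            + np.sqrt(r**2 / 4.0 + rbe_max * r * d + rbe_min**2 * d**2) / d)


def rbe_from_proton_dose(e: RBEEndpoints, tissue: TissueParams, proton_dose) -> float | np.ndarray:
    """RBE as a function of the proton absorbed dose D.

    ``RBE = -r/(2D) + (1/D) sqrt(r^2/4 + RBE_max r D + RBE_min^2 D^2)``,
    r = (alpha/beta)_x.  Consistent with :func:`rbe_from_photon_dose` under
    D_x = RBE * D.  The derivative dRBE/dD is negative exactly when
    RBE_max > RBE_min, which is the basis of the CAR applicability bound.
    """
    d = _check_dose(proton_dose, "proton_dose")
    rbe = _rbe_from_proton_dose_arrays(e.rbe_max, e.rbe_min, tissue.alpha_beta_x, d)
    return rbe if rbe.ndim else float(rbe)


def car_applicable(let, tissue: TissueParams,
                   constants: ModelConstants = CONSTANTS) -> bool | np.ndarray:
    """True where the CAR model is applicable: LET / (alpha/beta)_x > 0.62 (strict).

    Below the bound RBE_max <= RBE_min and the model predicts RBE increasing
    with dose, outside the regime it was fitted for; equality is treated as
    inapplicable because the dose derivative degenerates to zero.
    """
    let = _check_let(let)
    ok = let / tissue.alpha_beta_x > constants.car_ratio_threshold
    return ok if ok.ndim else bool(ok)


def car_min_applicable_let(tissue: TissueParams,
                           constants: ModelConstants = CONSTANTS,
                           tol: float = 1e-9) -> tuple[float, int]:
    """Minimum LET [keV/um] above which CAR is applicable for a tissue.

    Solved by bisecting the :func:`car_applicable` predicate itself rather
    than rearranging the inequality, so the reported bound is exactly the
    edge of the implemented mask.  Returns ``(let_bound, n_evaluations)``.
    """
    lo, hi = 0.0, 100.0 * tissue.alpha_beta_x
    if not car_applicable(hi, tissue, constants):
        raise ValueError("no applicable LET found below search bound")
    n = 1
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        n += 1
        if car_applicable(mid, tissue, constants):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi), n


def lem_beta_z(alpha_z: float, tissue: TissueParams) -> float:
    """Microscopic beta_z from the transition-dose construction.

    ``beta_z = (S_max - alpha_z) / (2 D_t)`` with
    ``S_max = alpha_x + 2 beta_x D_t`` the maximum slope of the photon
    survival curve at the transition dose D_t.  The result may be negative
    when alpha_z exceeds S_max; it is returned as-is (callers decide whether
    that invalidates a table row), never clamped.
    """
    if tissue.d_t is None:
        raise ValueError("tissue.d_t is required for the LEM beta_z helper")
    s_max = tissue.alpha_x + 2.0 * tissue.beta_x * tissue.d_t
    return (s_max - alpha_z) / (2.0 * tissue.d_t)


class LEMTable:
    """LET-keyed table of proton LQ parameters (externally supplied LEM output).

    Rows are (abscissa, alpha, beta) with a strictly increasing abscissa.
    The abscissa is LET in keV/um by default; energy-keyed tables must be
    converted upstream.
    """

    def __init__(self, let: Sequence[float], alpha: Sequence[float],
                 beta: Sequence[float]) -> None:
        let = np.asarray(let, dtype=float)
        alpha = np.asarray(alpha, dtype=float)
        beta = np.asarray(beta, dtype=float)
        if let.ndim != 1 or len(let) < 2:
            raise ValueError("LEM table needs at least two rows")
        if not (len(let) == len(alpha) == len(beta)):
            raise ValueError("LEM table columns must have equal length")
        if np.any(np.diff(let) <= 0):
            raise ValueError("LEM table abscissa must be strictly increasing")
        if np.any(alpha < 0) or np.any(beta < 0):
            raise ValueError("LEM table alpha and beta must be non-negative")
        self.let = let
        self.alpha = alpha
        self.beta = beta

    def __len__(self) -> int:
        return len(self.let)


def lem_table_lq(table: LEMTable, let) -> LQParams | tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear interpolation of (alpha, beta) at the query LET.

    Queries outside the tabulated range clamp to the nearest endpoint with a
    warning; linear extrapolation could produce negative beta.
    Scalar queries return :class:`LQParams`; array queries return
    ``(alpha, beta)`` arrays.
    """
    q = np.asarray(let, dtype=float)
    scalar = q.ndim == 0
    if np.any(q < table.let[0]) or np.any(q > table.let[-1]):
        warnings.warn(
            "LEM table query outside tabulated LET range "
            f"[{table.let[0]:g}, {table.let[-1]:g}] keV/um; clamping",
            stacklevel=2,
        )
    a = np.interp(q, table.let, table.alpha)
    b = np.interp(q, table.let, table.beta)
    if scalar:
        return LQParams(alpha=float(a), beta=float(b))
    return a, b


# --------------------------------------------------------------------------
# Model objects: a uniform endpoints(let, tissue) surface for the voxel engine
# --------------------------------------------------------------------------

class RBEModel:
    """Base class: a model maps (LET, tissue) to asymptotic RBE endpoints."""

    name: str = "base"

    def endpoints(self, let: float, tissue: TissueParams) -> RBEEndpoints:
        rmax, rmin = self.endpoint_arrays(np.asarray([let]), tissue)
        return RBEEndpoints(rbe_max=float(rmax[0]), rbe_min=float(rmin[0]))

    def endpoint_arrays(self, let: np.ndarray, tissue: TissueParams
                        ) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def rbe(self, let: float, tissue: TissueParams, proton_dose) -> float | np.ndarray:
        return rbe_from_proton_dose(self.endpoints(let, tissue), tissue, proton_dose)

    def applicability_mask(self, let: np.ndarray, tissue: TissueParams) -> np.ndarray:
        """Boolean mask of voxels where the model may be evaluated."""
        return np.ones(np.shape(let), dtype=bool)

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}()"


class CarabeModel(RBEModel):
    name = "car"

    def __init__(self, constants: ModelConstants = CONSTANTS) -> None:
        self.constants = constants

    def endpoint_arrays(self, let, tissue):
        let = _check_let(let)
        c = self.constants
        scale = c.car_reference_ab / tissue.alpha_beta_x
        return (c.car_max_intercept + c.car_max_slope * scale * let,
                c.car_min_intercept + c.car_min_slope * scale * let)

    def applicability_mask(self, let, tissue):
        return np.asarray(car_applicable(let, tissue, self.constants))


class WedenbergModel(RBEModel):
    name = "wed"

    def __init__(self, constants: ModelConstants = CONSTANTS) -> None:
        self.constants = constants

    def endpoint_arrays(self, let, tissue):
        let = _check_let(let)
        if np.any(let > WED_LET_VALIDITY_KEV_UM):
            warnings.warn(
                "Wedenberg model queried beyond its 30 keV/um validity bound",
                stacklevel=2,
            )
        rmax = 1.0 + self.constants.wed_q * let / tissue.alpha_beta_x
        return rmax, np.ones_like(rmax)


class LEMTableModel(RBEModel):
    """Table-driven LEM: endpoints from interpolated macroscopic alpha, beta."""

    name = "lem"

    def __init__(self, table: LEMTable, label: str = "lem") -> None:
        self.table = table
        self.name = label

    def endpoint_arrays(self, let, tissue):
        let = _check_let(let)
        a, b = lem_table_lq(self.table, np.atleast_1d(let))
        a = np.reshape(a, np.shape(let))
        b = np.reshape(b, np.shape(let))
        return a / tissue.alpha_x, np.sqrt(b / tissue.beta_x)


class FixedRBEModel(RBEModel):
    """The clinical constant-RBE reference (default 1.1).

    With RBE_max = RBE_min = c the proton-dose formula reduces exactly to c
    for every dose and LET, so the fixed model slots into the same pipeline.
    """

    name = "fixed_1.1"

    def __init__(self, rbe: float = 1.1) -> None:
        if not rbe > 0:
            raise ValueError("fixed RBE must be positive")
        self.fixed_rbe = rbe

    def endpoint_arrays(self, let, tissue):
        let = _check_let(let)
        c = np.full(np.shape(let), self.fixed_rbe, dtype=float)
        return c, c.copy()


def make_synthetic_lem_table(tissue: TissueParams,
                             let_max: float = 30.0,
                             n_rows: int = 61,
                             curvature: float = 0.25) -> LEMTable:
    """Construct a synthetic LEM-like alpha/beta table for a tissue.

    This is a stand-in for externally computed local-effect-model output, not
    a microscopic LEM calculation.  It reproduces the qualitative features of
    published LEM proton tables: alpha(LET) rises with a vanishing slope at
    LET -> 0 and super-linear growth at high LET, with the rate scaled by the
    reciprocal of (alpha/beta)_x; beta(LET) follows the transition-dose
    construction beta = (S_max - alpha)/(2 D_t) and therefore decreases
    monotonically.  Requires ``tissue.d_t``.
    """
    if tissue.d_t is None:
        raise ValueError("synthetic LEM table requires tissue.d_t")
    lets = np.linspace(0.0, let_max, n_rows)
    c = curvature * CONSTANTS.car_reference_ab / tissue.alpha_beta_x
    alpha = tissue.alpha_x * (1.0 + c * lets**2 / (CONSTANTS.car_reference_ab + lets))
    beta = np.array([lem_beta_z(a, tissue) for a in alpha])
    if np.any(beta < 0):
        raise ValueError("synthetic table produced negative beta; lower let_max or curvature")
    return LEMTable(lets, alpha, beta)
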