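"""Threshold times and radii of cell-specific spheres of influence.

A source cell's local concentration falls to the seawater background where

    C_sea = C_cell · (R / (R + √(D·t)))³ · e^(−µ·t)

Without decay (µ = 0) this gives the closed form r* = R·(C_cell/C_sea)^(1/3).
With decay, substituting Y = 2µt/3 turns the balance into Y·e^Y = x form, so
the threshold time has a Lambert-W expression on the principal branch:

    t* ≈ W₀( (k^(−1/3) − R)² · (2µ/3) / D ) / (2µ/3),
    k = C_sea / (C_cell · R³)

The substitution treats the cell-radius offset as decay-free, so the closed
form is exact only in the small-decay limit; here it seeds a Newton refinement
of the exact balance, which converges in a couple of iterations and makes the
profile evaluated at (t*, r*) recover C_sea to machine precision. For H₂O₂
lifetimes (hours–days) the refinement shifts the answer by less than one part
in 10⁶.

Sink cells have an algebraic threshold with no time dependence:
r* = R·(C_sea/C_cell)^(1/3). A bracketed-bisection oracle on the profile
function provides an independent numerical check of both closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw

from .exceptions import GridTooShortError, NoSphereOfInfluenceError, ValidationError
from .gradient import H2O2Params, TimeGrid, _source_concentrations, displacement_radius

__all__ = [
    "ThresholdDerivation",
    "ThresholdResult",
    "source_threshold_lambertw",
    "source_threshold_zero_decay",
    "source_threshold_grid",
    "sink_threshold",
    "bisection_oracle",
]

# Below this value of µ·t_estimate the decay factor is lost in double rounding
# and W₀(x)/x suffers cancellation, so the zero-decay branch takes over.
_MU_T_TOLERANCE = 1e-12


@dataclass(frozen=True)
class ThresholdDerivation:
    """Intermediates of the Lambert-W solution (for auditability).

    ``k`` has units µm⁻³; ``w_argument`` is the dimensionless argument passed
    to W₀ and ``Y = W₀(w_argument) = 2µt/3`` at the (unrefined) solution.
    """

    k: float
    w_argument: float
    Y: float


@dataclass(frozen=True)
class ThresholdResult:
    """Threshold time/radius of a cell-specific sphere of influence.

    ``r_threshold_um`` is measured from the cell centre;
    ``distance_from_surface_um`` subtracts the cell radius. Both conventions
    appear in the literature, so both are reported.
    """

    t_threshold_us: float
    r_threshold_um: float
    cell_radius_um: float
    direction: str
    method: str
    derivation: ThresholdDerivation | None = None

    @property
    def distance_from_surface_um(self) -> float:
        return self.r_threshold_um - self.cell_radius_um


def _require_source(c_cell: float, c_seawater: float) -> None:
    if not (c_seawater > 0 and c_cell > c_seawater):
        raise NoSphereOfInfluenceError(
            f"source threshold needs c_cell > c_seawater > 0, got {c_cell} vs {c_seawater}"
        )


def source_threshold_zero_decay(
    c_cell: float,
    c_seawater: float,
    cell_radius_um: float,
    diffusion_coefficient: float = 1500.0,
) -> ThresholdResult:
    """Zero-decay source threshold: r* = R·(C_cell/C_sea)^(1/3).

    The radius is independent of the diffusion coefficient; D only sets the
    time t* = (r* − R)²/D at which the front reaches it.
    """
    _require_source(c_cell, c_seawater)
    if not cell_radius_um > 0:
        raise ValidationError("cell radius must be positive")
    r = cell_radius_um * np.cbrt(c_cell / c_seawater)
    t = (r - cell_radius_um) ** 2 / diffusion_coefficient
    return ThresholdResult(float(t), float(r), cell_radius_um, "source", "closed_form_zero_decay")


def _newton_refine(params: H2O2Params, cell_radius_um: float, t0: float) -> float:
    """Newton iteration on ln C(t) − ln C_sea = 0, seeded at t0 > 0."""
    R, D, mu = cell_radius_um, params.diffusion_coefficient, params.decay_constant
    log_ratio = np.log(params.c_cell / params.c_seawater)
    t = t0
    for _ in range(50):
        x = np.sqrt(D * t)
        g = log_ratio - 3.0 * np.log((R + x) / R) - mu * t
        if abs(g) < 1e-14:
            break
        dg = -1.5 * x / (t * (R + x)) - mu
        step = g / dg
        t_new = t - step
        if t_new <= 0:  # keep the iterate in-domain
            t_new = t / 2
        t = t_new
    return t


def source_threshold_lambertw(params: H2O2Params, cell_radius_um: float) -> ThresholdResult:
    """Source threshold via the Lambert-W closed form, Newton-refined.

    Falls through to :func:`source_threshold_zero_decay` when µ is small enough
    that decay is numerically invisible (µ·t_estimate below 10⁻¹²). The W₀
    argument is non-negative for all valid inputs, so only the principal branch
    is ever needed.
    """
    _require_source(params.c_cell, params.c_seawater)
    if not cell_radius_um > 0:
        raise ValidationError("cell radius must be positive")
    if not params.diffusion_coefficient > 0:
        raise ValidationError("diffusion coefficient must be positive")
    R, D, mu = cell_radius_um, params.diffusion_coefficient, params.decay_constant

    k = params.c_seawater / (params.c_cell * R**3)
    A = np.cbrt(1.0 / k)  # zero-decay threshold radius, µm from centre
    t_dilution = (A - R) ** 2 / D

    if mu * t_dilution < _MU_T_TOLERANCE:
        base = source_threshold_zero_decay(params.c_cell, params.c_seawater, R, D)
        return ThresholdResult(
            base.t_threshold_us,
            base.r_threshold_um,
            R,
            "source",
            "closed_form_zero_decay",
            ThresholdDerivation(k=float(k), w_argument=0.0, Y=0.0),
        )

    w_arg = (A - R) ** 2 * (2 * mu / 3) / D
    assert w_arg >= -1.0 / np.e, "W argument left the real domain (cannot occur for valid inputs)"
    Y = float(lambertw(w_arg, k=0).real)
    t = Y / (2 * mu / 3)
    t = _newton_refine(params, R, t)
    r = float(displacement_radius(R, D, t))
    return ThresholdResult(
        float(t), r, R, "source", "lambertw", ThresholdDerivation(float(k), float(w_arg), Y)
    )


def source_threshold_grid(
    params: H2O2Params, cell_radius_um: float, grid: TimeGrid | None = None
) -> ThresholdResult:
    """First grid time at which the dilution×decay concentration ≤ C_sea.

    Always at or beyond the continuous threshold; converges to it from above as
    the grid is refined.
    """
    _require_source(params.c_cell, params.c_seawater)
    if not cell_radius_um > 0:
        raise ValidationError("cell radius must be positive")
    grid = grid or TimeGrid.log10()
    r, _, decay = _source_concentrations(params, cell_radius_um, grid.times_us)
    below = decay <= params.c_seawater
    if not np.any(below):
        raise GridTooShortError(
            f"concentration has not reached c_seawater by t = {grid.times_us[-1]} µs; "
            "extend the time grid"
        )
    i = int(np.argmax(below))
    return ThresholdResult(
        float(grid.times_us[i]), float(r[i]), cell_radius_um, "source", "grid_scan"
    )


def sink_threshold(
    c_cell: float,
    c_seawater: float,
    cell_radius_um: float,
    diffusion_coefficient: float = 1500.0,
) -> ThresholdResult:
    """Sink threshold: r* = R·(C_sea/C_cell)^(1/3), no decay term.

    The reported time is when the diffusion front reaches r*; the radius itself
    has no time dependence.
    """
    if not (c_cell > 0 and c_cell < c_seawater):
        raise NoSphereOfInfluenceError(
            f"sink threshold needs 0 < c_cell < c_seawater, got {c_cell} vs {c_seawater}"
        )
    if not cell_radius_um > 0:
        raise ValidationError("cell radius must be positive")
    r = cell_radius_um * np.cbrt(c_seawater / c_cell)
    t = (r - cell_radius_um) ** 2 / diffusion_coefficient
    return ThresholdResult(float(t), float(r), cell_radius_um, "sink", "closed_form_zero_decay")


def bisection_oracle(
    params: H2O2Params, cell_radius_um: float, direction: str = "source"
) -> ThresholdResult:
    """Independent threshold via bracketed bisection on the profile function.

    Solves C(t) = C_sea to 10⁻¹³ relative in t with no algebraic shortcuts;
    intended as a verification oracle for the closed forms.
    """
    if direction not in ("source", "sink"):
        raise ValidationError(f"unknown direction {direction!r}")
    R, D = cell_radius_um, params.diffusion_coefficient

    if direction == "source":
        _require_source(params.c_cell, params.c_seawater)

        def f(t: float) -> float:
            _, _, decay = _source_concentrations(params, R, np.asarray([t]))
            return float(decay[0]) - params.c_seawater

    else:
        if not (0 < params.c_cell < params.c_seawater):
            raise NoSphereOfInfluenceError("sink oracle needs 0 < c_cell < c_seawater")

        def f(t: float) -> float:
            r = float(displacement_radius(R, D, t))
            return params.c_seawater - params.c_cell * (r / R) ** 3

    lo, hi = 0.0, max((R * 10) ** 2 / D, 1.0)
    f_hi = f(hi)
    for _ in range(200):
        if f_hi < 0:
            break
        hi *= 2
        f_hi = f(hi)
    else:
        raise ValidationError("bisection bracket: no sign change found")

    for _ in range(500):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-13 * hi:
            break
    t = 0.5 * (lo + hi)
    r = float(displacement_radius(R, D, t))
    return ThresholdResult(float(t), r, R, direction, "bisection_oracle")
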