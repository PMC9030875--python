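"""H₂O₂ concentration gradients around source and sink cells.

A cell is modelled as a static sphere of radius R maintaining a homeostatic
intracellular concentration C_cell against a seawater background C_sea. Over a
time grid, the diffusion front sits at r(t) = R + √(D·t). For a source cell
(phytoplankton, C_cell > C_sea) the concentration at the front follows
volumetric dilution of the intracellular sphere,

    C(t) = C_cell · (R / r(t))³ · e^(−µ·t)

with an optional pseudo-first-order decay constant µ, floored at C_sea beyond
the threshold where the cell has no further local influence. For a sink cell
(heterotrophic bacterioplankton, C_cell < C_sea) the concentration rises from
the surface as C_cell · (r/R)³, capped at C_sea, with no decay term — the cell
acts on top of any bulk decay to lower the local concentration.

For H₂O₂, whose seawater lifetime is hours to days, decay is negligible over
the ≤100 µs timescales simulated here; the term is retained so the machinery
generalizes to shorter-lived reactive oxygen species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import NoSphereOfInfluenceError, ValidationError

__all__ = [
    "US_PER_HOUR",
    "H2O2Params",
    "decay_constant_from_lifetime",
    "TimeGrid",
    "displacement_radius",
    "ConcentrationProfile",
    "source_profile",
    "sink_profile",
]

US_PER_HOUR = 3.6e9  # µs per hour


def decay_constant_from_lifetime(lifetime_hours: float) -> float:
    """Pseudo-first-order decay constant µ (µs⁻¹) from an e-folding lifetime.

    µ = 1 / lifetime, with the lifetime converted to µs. An infinite lifetime
    gives µ = 0 (no decay).
    """
    if math.isinf(lifetime_hours) and lifetime_hours > 0:
        return 0.0
    if not lifetime_hours > 0:
        raise ValidationError(f"lifetime must be positive, got {lifetime_hours}")
    return 1.0 / (lifetime_hours * US_PER_HOUR)


@dataclass(frozen=True)
class H2O2Params:
    """Physical parameters of the gradient model.

    Concentrations in mol L⁻¹, diffusion coefficient in µm² µs⁻¹, decay
    constant in µs⁻¹. Defaults: homeostatic intracellular 10⁻⁶ M, lowest
    seawater background 10⁻⁹ M, D = 1500, no decay. The cytotoxic window
    (10⁻⁵–10⁻⁴ M) is annotation only and enters no computation.
    """

    c_cell: float = 1e-6
    c_seawater: float = 1e-9
    diffusion_coefficient: float = 1500.0
    decay_constant: float = 0.0
    cytotoxic_low: float = 1e-5
    cytotoxic_high: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("c_cell", "c_seawater", "diffusion_coefficient", "decay_constant"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.cytotoxic_low < self.cytotoxic_high:
            raise ValidationError("cytotoxic_low must be < cytotoxic_high")

    @property
    def ratio(self) -> float:
        """Intracellular : extracellular concentration ratio."""
        return self.c_cell / self.c_seawater

    def with_lifetime(self, lifetime_hours: float) -> "H2O2Params":
        return replace(self, decay_constant=decay_constant_from_lifetime(lifetime_hours))


@dataclass(frozen=True)
class TimeGrid:
    """Simulation times in µs: exactly 0 first, then a log₁₀-spaced series."""

    times_us: np.ndarray = field(default_factory=lambda: TimeGrid.log10().times_us)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_us, dtype=float)
        object.__setattr__(self, "times_us", t)
        if t.ndim != 1 or len(t) < 2:
            raise ValidationError("time grid needs at least two points")
        if t[0] != 0.0:
            raise ValidationError("time grid must start at exactly 0")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_us)

    @classmethod
    def log10(
        cls, t_min_us: float = 1e-3, t_max_us: float = 100.0, points_per_decade: int = 20
    ) -> "TimeGrid":
        """t = 0 followed by log₁₀-spaced points from ``t_min_us`` to ``t_max_us``."""
        if not (0 < t_min_us < t_max_us):
            raise ValidationError("need 0 < t_min_us < t_max_us")
        n_dec = np.log10(t_max_us / t_min_us)
        n = int(round(n_dec * points_per_decade)) + 1
        times = np.concatenate([[0.0], np.logspace(np.log10(t_min_us), np.log10(t_max_us), n)])
        return cls(times)


def displacement_radius(cell_radius_um: float, diffusion_coefficient: float, t_us):
    """Diffusion-front radius r(t) = R + √(D·t) in µm; vectorized over t."""
    t = np.asarray(t_us, dtype=float)
    if np.any(t < 0):
        raise ValidationError("time must be >= 0")
    return cell_radius_um + np.sqrt(diffusion_coefficient * t)


@dataclass
class ConcentrationProfile:
    """Concentration vs time/front-radius for one cell.

    ``conc_dilution_M`` is the dilution-only series; ``conc_decay_M``
    superimposes the decay term (for sinks the two series are identical, as the
    sink model carries no decay). Both are clamped at the seawater background.
    """

    times_us: np.ndarray
    radii_um: np.ndarray
    conc_dilution_M: np.ndarray
    conc_decay_M: np.ndarray
    direction: str
    cell_radius_um: float
    params: H2O2Params

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_us": self.times_us,
                "r_um": self.radii_um,
                "conc_dilution_M": self.conc_dilution_M,
                "conc_decay_M": self.conc_decay_M,
                "direction": self.direction,
            }
        )


def _source_concentrations(params: H2O2Params, cell_radius_um: float, t: np.ndarray):
    """Unclamped dilution-only and dilution×decay series for a source cell."""
    r = displacement_radius(cell_radius_um, params.diffusion_coefficient, t)
    dilution = params.c_cell * (cell_radius_um / r) ** 3
    decay = dilution * np.exp(-params.decay_constant * t)
    return r, dilution, decay


def source_profile(
    params: H2O2Params, cell_radius_um: float, grid: TimeGrid | None = None
) -> ConcentrationProfile:
    """Outward gradient from a source cell, floored at the seawater background."""
    if not params.c_cell > params.c_seawater:
        raise NoSphereOfInfluenceError(
            "source cell needs c_cell > c_seawater; no outward sphere of influence"
        )
    if not cell_radius_um > 0:
        raise ValidationError("cell radius must be positive")
    grid = grid or TimeGrid.log10()
    r, dilution, decay = _source_concentrations(params, cell_radius_um, grid.times_us)
    return ConcentrationProfile(
        times_us=grid.times_us,
        radii_um=r,
        conc_dilution_M=np.maximum(dilution, params.c_seawater),
        conc_decay_M=np.maximum(decay, params.c_seawater),
        direction="source",
        cell_radius_um=cell_radius_um,
        params=params,
    )


def sink_profile(
    params: H2O2Params, cell_radius_um: float, grid: TimeGrid | None = None
) -> ConcentrationProfile:
    """Inward gradient toward a sink cell, capped at the seawater background."""
    if not params.c_cell < params.c_seawater:
        raise NoSphereOfInfluenceError(
            "sink cell needs c_cell < c_seawater; no inward sphere of influence"
        )
    if not cell_radius_um > 0:
        raise ValidationError("cell radius must be positive")
    grid = grid or TimeGrid.log10()
    r = displacement_radius(cell_radius_um, params.diffusion_coefficient, grid.times_us)
    conc = np.minimum(params.c_cell * (r / cell_radius_um) ** 3, params.c_seawater)
    return ConcentrationProfile(
        times_us=grid.times_us,
        radii_um=r,
        conc_dilution_M=conc,
        conc_decay_M=conc.copy(),
        direction="sink",
        cell_radius_um=cell_radius_um,
        params=params,
    )
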