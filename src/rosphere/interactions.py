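"""Habitat-level classification of cell-to-cell diffusional interactions.

Combines the spacing estimator with the threshold radii: a taxon's cells can
interact directly through H₂O₂ when the cell-specific sphere of influence
reaches its neighbours, i.e. when the threshold radius is at least the mean
centre-to-centre spacing at that taxon's suspension density. Inverting the
spacing relation gives, for each cell radius and intracellular:extracellular
concentration ratio, the critical suspension density above which spheres of
influence overlap — the threshold lines of the density × radius plane.

Two configurable conventions matter and both appear in the source material:

* sphere radius measured from the cell centre (default) or from the surface;
* interaction when the sphere spans the full mean spacing (default) or only
  half of it (two neighbouring spheres meeting midway).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import ValidationError
from .geometry import (
    POISSON_NN_CONSTANT,
    CommunityLayout,
    critical_density_for_spacing,
    mean_cell_spacing,
)
from .gradient import H2O2Params
from .taxa import Community, TaxonRecord
from .thresholds import sink_threshold, source_threshold_zero_decay

__all__ = [
    "InteractionAssessment",
    "assess_community",
    "assessments_to_frame",
    "ThresholdLine",
    "threshold_line",
    "Scene",
    "overlay_habitat",
]


def sphere_of_influence_radius(
    cell_radius_um: float, ratio: float, convention: str = "centre"
) -> float:
    """Sphere-of-influence radius (µm) for a cell at a concentration ratio.

    Source convention (ratio > 1): r = R·ratio^(1/3); sink (ratio < 1):
    r = R·(1/ratio)^(1/3). ``convention`` picks centre or surface measurement.
    """
    if convention not in ("centre", "surface"):
        raise ValidationError(f"unknown convention {convention!r}")
    if not ratio > 0 or ratio == 1:
        raise ValidationError(f"ratio must be positive and != 1, got {ratio}")
    if ratio > 1:
        r = source_threshold_zero_decay(ratio, 1.0, cell_radius_um).r_threshold_um
    else:
        r = sink_threshold(ratio, 1.0, cell_radius_um).r_threshold_um
    return r - cell_radius_um if convention == "surface" else r


@dataclass(frozen=True)
class InteractionAssessment:
    """Sphere of influence vs mean spacing for one taxon × habitat record."""

    record: TaxonRecord
    sphere_radius_um: float
    mean_spacing_um: float
    interacting: bool
    ratio_used: float
    direction: str


def assess_community(
    community: Community,
    params: H2O2Params | None = None,
    *,
    source_ratio: float | None = None,
    sink_ratio: float = 0.1,
    criterion: str = "full_spacing",
    convention: str = "centre",
    correction_constant: float = POISSON_NN_CONSTANT,
) -> list[InteractionAssessment]:
    """Classify every record of a community as interacting or not.

    Phototrophs use the zero-decay source threshold at ``source_ratio``
    (default: c_cell/c_seawater from ``params``, 1000 with the default
    parameters); heterotrophs use the sink threshold at ``sink_ratio``
    (default 0.1, the literature intracellular:extracellular estimate).
    ``criterion="half_spacing"`` flags interaction when the sphere reaches
    halfway to the mean neighbour instead of all the way.
    """
    params = params or H2O2Params()
    if source_ratio is None:
        source_ratio = params.ratio
    if not source_ratio > 1:
        raise ValidationError(f"source ratio must exceed 1, got {source_ratio}")
    if not 0 < sink_ratio < 1:
        raise ValidationError(f"sink ratio must lie in (0, 1), got {sink_ratio}")
    if criterion not in ("full_spacing", "half_spacing"):
        raise ValidationError(f"unknown criterion {criterion!r}")

    out = []
    for rec in community:
        ratio = source_ratio if rec.metabolism == "phototroph" else sink_ratio
        direction = "source" if rec.metabolism == "phototroph" else "sink"
        sphere = sphere_of_influence_radius(rec.cell_radius_um, ratio, convention)
        spacing = mean_cell_spacing(rec.cells_per_m3, correction_constant).mean_spacing_um
        reach_needed = spacing if criterion == "full_spacing" else spacing / 2
        out.append(
            InteractionAssessment(
                record=rec,
                sphere_radius_um=float(sphere),
                mean_spacing_um=float(spacing),
                interacting=bool(sphere >= reach_needed),
                ratio_used=ratio,
                direction=direction,
            )
        )
    return out


def assessments_to_frame(assessments: list[InteractionAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon": [a.record.taxon_name for a in assessments],
            "habitat": [a.record.habitat for a in assessments],
            "density_m3": [a.record.cells_per_m3 for a in assessments],
            "radius_um": [a.record.cell_radius_um for a in assessments],
            "ratio": [a.ratio_used for a in assessments],
            "sphere_um": [a.sphere_radius_um for a in assessments],
            "spacing_um": [a.mean_spacing_um for a in assessments],
            "interacting": [a.interacting for a in assessments],
        }
    )


@dataclass(frozen=True)
class ThresholdLine:
    """Critical density vs cell radius at a fixed concentration ratio."""

    ratio: float
    cell_radii_um: np.ndarray
    critical_densities_m3: np.ndarray
    convention: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ratio": self.ratio,
                "radius_um": self.cell_radii_um,
                "critical_density_m3": self.critical_densities_m3,
            }
        )


def threshold_line(
    ratio: float,
    cell_radii_um,
    *,
    convention: str = "centre",
    criterion: str = "full_spacing",
    correction_constant: float = POISSON_NN_CONSTANT,
) -> ThresholdLine:
    """Critical suspension density at which spheres of influence start to overlap.

    Per cell radius, the sphere radius at ``ratio`` is converted to the density
    whose mean spacing equals it (or twice it under ``half_spacing``).
    """
    radii = np.atleast_1d(np.asarray(cell_radii_um, dtype=float))
    if np.any(radii <= 0):
        raise ValidationError("cell radii must be positive")
    if criterion not in ("full_spacing", "half_spacing"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    densities = []
    for R in radii:
        sphere = sphere_of_influence_radius(float(R), ratio, convention)
        spacing = sphere if criterion == "full_spacing" else 2 * sphere
        densities.append(critical_density_for_spacing(spacing, correction_constant))
    return ThresholdLine(ratio, radii, np.asarray(densities), convention)


@dataclass
class Scene:
    """Renderable habitat scene: per-cell geometry plus overlap summary."""

    table: pd.DataFrame  # taxon, x/y/z_mm, cell_radius_um, sphere_radius_um, direction
    extent_mm: tuple[float, float, float]
    overlap_pairs: int
    overlap_fraction: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def overlay_habitat(
    community: Community,
    layout: CommunityLayout,
    assessments: list[InteractionAssessment],
) -> Scene:
    """Attach sphere-of-influence radii to layout positions and count overlaps.

    Two cells' spheres overlap when their centre separation is below the sum of
    their sphere radii. The layout and assessments must come from the same
    community (matched by taxon label).
    """
    sphere_by_taxon: dict[str, float] = {}
    direction_by_taxon: dict[str, str] = {}
    for a in assessments:
        sphere_by_taxon[a.record.taxon_name] = a.sphere_radius_um
        direction_by_taxon[a.record.taxon_name] = a.direction
    community_taxa = {r.taxon_name for r in community}
    layout_taxa = set(layout.taxon_labels)
    if not layout_taxa <= community_taxa or not layout_taxa <= set(sphere_by_taxon):
        raise ValidationError(
            "layout, community and assessments disagree on taxa: "
            f"{sorted(layout_taxa - (community_taxa & set(sphere_by_taxon)))}"
        )

    n = len(layout)
    spheres_um = np.array([sphere_by_taxon[t] for t in layout.taxon_labels], dtype=float)
    directions = [direction_by_taxon[t] for t in layout.taxon_labels]
    table = layout.to_frame().rename(columns={"radius_um": "cell_radius_um"})
    table["sphere_radius_um"] = spheres_um
    table["direction"] = directions

    overlap_pairs = 0
    touched = np.zeros(n, dtype=bool)
    if n >= 2:
        spheres_mm = spheres_um / 1000.0
        tree = cKDTree(layout.positions_mm)
        for i, j in tree.query_pairs(r=float(2 * spheres_mm.max())):
            d = float(np.linalg.norm(layout.positions_mm[i] - layout.positions_mm[j]))
            if d < spheres_mm[i] + spheres_mm[j]:
                overlap_pairs += 1
                touched[i] = touched[j] = True

    return Scene(
        table=table,
        extent_mm=layout.config.extent_mm,
        overlap_pairs=overlap_pairs,
        overlap_fraction=float(touched.mean()) if n else 0.0,
    )
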