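"""Matplotlib views over the exported tables.

All figures are pure renderings of values computed elsewhere: cell symbols are
circles whose data-space radius equals the cell radius (no marker-size
scaling, so apparent proximity is never exaggerated), and depth along z is
cued by opacity — fainter points sit farther back, alpha clipped to
[0.15, 1].
"""

from __future__ import annotations

import numpy as np
from matplotlib.axes import Axes
from matplotlib.collections import EllipseCollection
from matplotlib.figure import Figure

from .geometry import CommunityLayout
from .gradient import ConcentrationProfile
from .interactions import Scene, ThresholdLine
from .taxa import Community

__all__ = [
    "plot_community",
    "plot_profile",
    "plot_scene",
    "plot_threshold_lines",
]

_SOURCE_COLOR = "forestgreen"
_SINK_COLOR = "firebrick"
_SPHERE_COLOR = "lightblue"


def _depth_alpha(z_mm: np.ndarray, extent_z: float) -> np.ndarray:
    return np.clip(1.0 - z_mm / extent_z, 0.15, 1.0)


def _true_scale_circles(ax: Axes, xy_mm, radii_mm, colors, alphas) -> None:
    """Circles with data-space radii; EllipseCollection stays fast at 10⁵ cells."""
    if len(xy_mm) == 0:
        return
    diam = 2.0 * np.asarray(radii_mm)
    ec = EllipseCollection(
        diam, diam, np.zeros_like(diam), units="xy", offsets=xy_mm,
        offset_transform=ax.transData, facecolors=colors, edgecolors="none",
    )
    arr = ec.get_facecolor()
    alphas = np.broadcast_to(np.asarray(alphas, dtype=float), (len(diam),))
    if len(arr) == len(diam):
        arr = arr.copy()
        arr[:, 3] = alphas
        ec.set_facecolor(arr)
    ax.add_collection(ec)


def plot_community(layout: CommunityLayout, ax: Axes, color_by_taxon: dict | None = None) -> Axes:
    """True-scale scatter of a layout; z-depth shown by opacity."""
    ex, ey, ez = layout.config.extent_mm
    colors = (
        [color_by_taxon.get(t, _SOURCE_COLOR) for t in layout.taxon_labels]
        if color_by_taxon
        else [_SOURCE_COLOR] * len(layout)
    )
    alphas = _depth_alpha(layout.positions_mm[:, 2], ez) if len(layout) else np.empty(0)
    _true_scale_circles(
        ax, layout.positions_mm[:, :2], layout.radii_um / 1000.0, colors, alphas
    )
    ax.set_xlim(0, ex)
    ax.set_ylim(0, ey)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    return ax


def plot_profile(profile: ConcentrationProfile, ax: Axes) -> Axes:
    """Concentration vs distance with seawater and cytotoxic bands."""
    p = profile.params
    ax.axhspan(p.c_seawater, 1e-6, color=_SPHERE_COLOR, alpha=0.4, label="seawater range")
    ax.axhspan(p.cytotoxic_low, p.cytotoxic_high, color="orange", alpha=0.35, label="cytotoxic")
    ax.plot(profile.radii_um, profile.conc_dilution_M, "k.", ms=3, label="dilution only")
    ax.plot(profile.radii_um, profile.conc_decay_M, "r.", ms=1.5, label="dilution + decay")
    ax.axvline(profile.cell_radius_um, color="green", lw=1.2, label="cell surface")
    # threshold radius: where the clamped series first reaches the background
    clamped = (
        profile.conc_decay_M <= p.c_seawater
        if profile.direction == "source"
        else profile.conc_decay_M >= p.c_seawater
    )
    if clamped.any():
        ax.axvline(profile.radii_um[int(np.argmax(clamped))], color="k", ls="--", lw=1)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("distance from cell centre (µm)")
    ax.set_ylabel("[H$_2$O$_2$] (M)")
    ax.legend(fontsize=7, loc="best")
    return ax


def plot_scene(scene: Scene, ax: Axes) -> Axes:
    """Cells plus their spheres of influence, both on the spatial scale."""
    ex, ey, ez = scene.extent_mm
    t = scene.table
    if len(t):
        alphas = _depth_alpha(t["z_mm"].to_numpy(), ez)
        sphere_colors = [
            _SPHERE_COLOR if d == "source" else "mistyrose" for d in t["direction"]
        ]
        xy = t[["x_mm", "y_mm"]].to_numpy()
        _true_scale_circles(ax, xy, t["sphere_radius_um"].to_numpy() / 1000.0,
                            sphere_colors, 0.5 * alphas)
        cell_colors = [_SOURCE_COLOR if d == "source" else _SINK_COLOR for d in t["direction"]]
        _true_scale_circles(ax, xy, t["cell_radius_um"].to_numpy() / 1000.0, cell_colors, alphas)
    ax.set_xlim(0, ex)
    ax.set_ylim(0, ey)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(f"{scene.overlap_pairs} overlapping sphere pairs", fontsize=8)
    return ax


def plot_threshold_lines(
    lines: list[ThresholdLine],
    ax: Axes,
    community: Community | None = None,
    habitat_markers: dict | None = None,
) -> Axes:
    """Critical-density threshold lines with optional habitat points.

    X: suspension density (cells m⁻³); Y: cell radius (µm). Above/left of a
    line, spheres of influence overlap at that intracellular:extracellular
    ratio.
    """
    styles = ["-", "--", ":", "-."]
    for line, ls in zip(lines, styles * (len(lines) // 4 + 1)):
        ax.plot(line.critical_densities_m3, line.cell_radii_um, ls, color="k",
                lw=1, label=f"ratio {line.ratio:g}")
    if community is not None:
        markers = habitat_markers or {
            "oligotrophic": "o", "mesotrophic": "s", "eutrophic": "^", "colony": "*"
        }
        for rec in community:
            ax.plot(rec.cells_per_m3, rec.cell_radius_um, markers.get(rec.habitat, "o"),
                    ms=6, mfc="none", mec="tab:blue")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("cell suspension density (cells m$^{-3}$)")
    ax.set_ylabel("cell radius (µm)")
    ax.legend(fontsize=7)
    return ax


def save(fig: Figure, path) -> None:
    fig.savefig(path, dpi=150, bbox_inches="tight")
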