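"""Interaction classification, threshold lines and habitat scenes."""

import numpy as np
import pytest

from rosphere import (
    Community,
    LayoutConfig,
    TaxonRecord,
    ValidationError,
    assess_community,
    assessments_to_frame,
    critical_density_for_spacing,
    generate_layout,
    mean_cell_spacing,
    overlay_habitat,
    sphere_of_influence_radius,
    threshold_line,
)
from rosphere.taxa import with_density


def _record(name="X", habitat="colony", metabolism="phototroph", radius=2.2, density=2.4e13):
    return TaxonRecord(name, habitat, metabolism, radius, density)


class TestAssessCommunity:
    def test_phaeocystis_colony_interacts(self, builtin_community):
        phae = builtin_community.filter(habitat="colony", taxon="Phaeocystis")
        (a,) = assess_community(phae, source_ratio=1000.0)
        assert a.sphere_radius_um == pytest.approx(22.0)
        assert a.mean_spacing_um == pytest.approx(19.2, abs=0.05)
        assert a.interacting is True

    def test_oligotrophic_prochlorococcus_does_not(self, builtin_community):
        recs = [
            r
            for r in builtin_community.filter(habitat="oligotrophic", taxon="Prochlorococcus")
            if r.cells_per_m3 == 3.8e10
        ]
        (a,) = assess_community(Community(recs), source_ratio=1000.0)
        assert a.sphere_radius_um == pytest.approx(3.0)
        assert a.mean_spacing_um == pytest.approx(164.8, abs=0.1)
        assert a.interacting is False

    def test_empty_community(self):
        assert assess_community(Community([])) == []

    def test_heterotrophs_use_sink_threshold(self):
        (a,) = assess_community(
            Community([_record(metabolism="heterotroph", radius=0.5, density=4.6e11)]),
            sink_ratio=0.1,
        )
        assert a.direction == "sink"
        assert a.sphere_radius_um == pytest.approx(0.5 * np.cbrt(10.0))

    @pytest.mark.parametrize("kwargs", [{"source_ratio": 0.5}, {"sink_ratio": 2.0}])
    def test_ratio_on_wrong_side_of_one_rejected(self, builtin_community, kwargs):
        with pytest.raises(ValidationError):
            assess_community(builtin_community, **kwargs)

    def test_half_spacing_criterion_is_more_permissive(self, builtin_community):
        full = assessments_to_frame(assess_community(builtin_community))
        half = assessments_to_frame(assess_community(builtin_community, criterion="half_spacing"))
        assert (half["interacting"] >= full["interacting"]).all()

    def test_interacting_flag_matches_definition(self, builtin_community):
        for a in assess_community(builtin_community):
            assert a.interacting == (a.sphere_radius_um >= a.mean_spacing_um)


class TestThresholdLine:
    def test_large_cell_critical_density(self):
        line = threshold_line(1000.0, [40.0])
        assert line.critical_densities_m3[0] == pytest.approx(2.66e9, rel=0.002)

    def test_small_cell_conventions(self):
        centre = threshold_line(1000.0, [0.5], convention="centre")
        surface = threshold_line(1000.0, [0.5], convention="surface")
        assert centre.critical_densities_m3[0] == pytest.approx(1.36e15, rel=0.005)
        assert surface.critical_densities_m3[0] == pytest.approx(1.87e15, rel=0.005)

    def test_identity_ratio_rejected(self):
        with pytest.raises(ValidationError):
            threshold_line(1.0, [1.0])

    def test_monotone_decreasing_in_radius_and_ratio(self):
        radii = np.logspace(-1, 2, 30)
        line_lo = threshold_line(100.0, radii)
        line_hi = threshold_line(1000.0, radii)
        assert np.all(np.diff(line_lo.critical_densities_m3) < 0)
        assert np.all(line_hi.critical_densities_m3 < line_lo.critical_densities_m3)

    def test_sink_lines_supported(self):
        line = threshold_line(0.1, [0.5])
        sphere = sphere_of_influence_radius(0.5, 0.1)
        assert line.critical_densities_m3[0] == pytest.approx(
            critical_density_for_spacing(sphere), rel=1e-12
        )

    @pytest.mark.parametrize("radius", [0.3, 1.0, 5.0, 40.0])
    def test_round_trip_sphere_equals_spacing_at_critical_density(self, radius):
        line = threshold_line(1000.0, [radius])
        rec = _record(radius=radius, density=float(line.critical_densities_m3[0]))
        (a,) = assess_community(Community([rec]), source_ratio=1000.0)
        assert a.sphere_radius_um == pytest.approx(a.mean_spacing_um, rel=1e-9)
        assert a.interacting is True


class TestOverlayHabitat:
    def test_single_cell_no_overlap(self):
        community = Community([_record(density=1e9)])
        layout = generate_layout(community, LayoutConfig(mode="uniform_random", seed=12))
        # force exactly one cell
        layout.positions_mm = np.array([[0.5, 0.5, 0.5]])
        layout.taxon_labels = ["X"]
        layout.radii_um = np.array([2.2])
        scene = overlay_habitat(community, layout, assess_community(community))
        assert scene.overlap_pairs == 0
        assert len(scene.table) == 1

    def test_two_spheres_intersect_when_closer_than_radius_sum(self):
        community = Community([_record(density=1e9)])
        layout = generate_layout(community, LayoutConfig(mode="uniform_random", seed=12))
        layout.positions_mm = np.array([[0.5, 0.5, 0.5], [0.53, 0.5, 0.5]])  # 30 µm apart
        layout.taxon_labels = ["X", "X"]
        layout.radii_um = np.array([2.2, 2.2])
        assessments = assess_community(community, source_ratio=1000.0)  # spheres 22 µm
        scene = overlay_habitat(community, layout, assessments)
        assert scene.overlap_pairs == 1
        assert scene.overlap_fraction == 1.0

    def test_colony_mostly_overlapping(self, builtin_community):
        phae = builtin_community.filter(habitat="colony", taxon="Phaeocystis")
        fractions = []
        for seed in range(5):
            layout = generate_layout(phae, LayoutConfig(extent_mm=(0.1, 0.1, 0.1), seed=seed))
            scene = overlay_habitat(phae, layout, assess_community(phae, source_ratio=1000.0))
            fractions.append(scene.overlap_fraction)
        assert min(fractions) > 0.9

    def test_mismatched_community_rejected(self):
        community = Community([_record()])
        other = Community([_record(name="Y", density=1e9)])
        layout = generate_layout(
            other, LayoutConfig(extent_mm=(0.5, 0.5, 0.5), mode="uniform_random", seed=5)
        )
        if len(layout) == 0:  # ensure the check is actually exercised
            layout.positions_mm = np.array([[0.1, 0.1, 0.1]])
            layout.taxon_labels = ["Y"]
            layout.radii_um = np.array([1.0])
        with pytest.raises(ValidationError):
            overlay_habitat(community, layout, assess_community(community))


class TestDensityHelper:
    def test_with_density_round_trip(self):
        rec = _record()
        assert with_density(rec, 1e9).cells_per_m3 == 1e9
        assert with_density(rec, 1e9).taxon_name == rec.taxon_name


class TestSceneConsistency:
    def test_flag_reproduced_by_geometry(self, builtin_community):
        """Interacting taxa show mean nearest-neighbour distance ≤ sphere radius."""
        phae = builtin_community.filter(habitat="colony", taxon="Phaeocystis")
        (a,) = assess_community(phae, source_ratio=1000.0)
        from rosphere import nearest_neighbour_stats

        spacing_mm = mean_cell_spacing(phae[0].cells_per_m3).mean_spacing_mm
        extent = 10 * spacing_mm
        means = []
        for seed in range(3):
            layout = generate_layout(
                phae, LayoutConfig(extent_mm=(extent,) * 3, mode="uniform_random", seed=seed)
            )
            means.append(nearest_neighbour_stats(layout, boundary="periodic").mean_nn_mm)
        mean_nn_um = float(np.mean(means)) * 1000
        assert (mean_nn_um <= a.sphere_radius_um) == a.interacting
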