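import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from campimetry.errors import DomainError, InvalidConfigError
from campimetry.geometry import (
    FieldExtent,
    FieldLocation,
    ScreenSetup,
    default_blindspot,
    field_extension,
    generate_grid,
    grid_pixel_positions,
    location_to_pixels,
    mm_to_pixels,
    pixels_per_degree,
    sphericity_correct,
)


class TestFieldExtension:
    def test_validation_hardware_horizontal_extent(self):
        assert round(field_extension(535.0, 370.0), 2) == 71.73

    def test_vertical_extent_follows_the_formula(self):
        # 300 mm at 370 mm: the tangent formula gives ~44.14 degrees
        assert field_extension(300.0, 370.0) == pytest.approx(44.13, abs=0.01)

    def test_degenerate_and_symmetric_cases(self):
        assert field_extension(0.0, 370.0) == 0.0
        assert field_extension(2 * 370.0, 370.0) == pytest.approx(90.0)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(DomainError):
            field_extension(100.0, 0.0)

    @given(
        side=st.floats(1.0, 2000.0),
        distance=st.floats(50.0, 2000.0),
        factor=st.floats(1.01, 3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_size_and_distance(self, side, distance, factor):
        base = field_extension(side, distance)
        assert field_extension(side * factor, distance) > base
        assert field_extension(side, distance * factor) < base
        assert 0 < base < 180


class TestPixelsPerDegree:
    @pytest.mark.parametrize(
        "resolution, extent, expected",
        [(1920, 71.73, 26.77), (1080, 44.13, 24.47), (1000, 1000, 1.0)],
    )
    def test_density(self, resolution, extent, expected):
        assert pixels_per_degree(resolution, extent) == pytest.approx(expected, abs=5e-3)

    def test_zero_extent_rejected(self):
        with pytest.raises(DomainError):
            pixels_per_degree(1920, 0.0)


class TestSphericityCorrection:
    @pytest.mark.parametrize(
        "ecc, expected", [(0.0, 0.0), (45.0, 370.0), (15.0, 99.14)]
    )
    def test_tangent_mapping(self, ecc, expected):
        assert sphericity_correct(370.0, ecc) == pytest.approx(expected, abs=5e-3)

    def test_eccentricity_at_or_beyond_90_rejected(self):
        with pytest.raises(DomainError):
            sphericity_correct(370.0, 90.0)

    @given(ecc=st.floats(0.1, 89.0), d=st.floats(100.0, 1000.0))
    @settings(max_examples=100, deadline=None)
    def test_ratio_depends_only_on_eccentricity(self, ecc, d):
        assert sphericity_correct(d, ecc) / d == pytest.approx(
            sphericity_correct(370.0, ecc) / 370.0
        )

    def test_small_angle_agreement_with_linear_mapping(self):
        # when the whole screen subtends a small angle the tangent
        # correction and the linear pixels-per-degree placement agree to
        # well under one percent
        far = ScreenSetup(300.0, 300.0, 1920, 1920, 2000.0)
        extent = far.field_extent()
        for ecc in (0.5, 2.0, 4.0):
            corrected = mm_to_pixels(
                sphericity_correct(far.distance_mm, ecc),
                far.resolution_x,
                far.width_mm,
            )
            linear = ecc * extent.px_per_deg_x
            assert corrected == pytest.approx(linear, rel=0.01)


class TestMmToPixels:
    @pytest.mark.parametrize(
        "d, res, side, expected",
        [(0.0, 1920, 535.0, 0.0), (99.14, 1920, 535.0, 355.8), (535.0, 1920, 535.0, 1920.0)],
    )
    def test_linear_conversion(self, d, res, side, expected):
        assert mm_to_pixels(d, res, side) == pytest.approx(expected, abs=0.05)

    def test_linear_in_resolution(self):
        assert mm_to_pixels(10.0, 3840, 535.0) == pytest.approx(
            2 * mm_to_pixels(10.0, 1920, 535.0)
        )


class TestGrid:
    def extent(self):
        # the nominal study extent used with 5.98 x 5.52 degree spacing
        return FieldExtent(71.73, 44.41, 1920 / 71.73, 1080 / 44.41)

    def test_study_spacing_yields_96_locations(self):
        grid = generate_grid(self.extent(), 5.98, 5.52)
        assert len(grid) == 96

    def test_spacing_equal_to_extent_degenerates_to_fixation(self):
        grid = generate_grid(self.extent(), 71.73, 44.41)
        assert len(grid) == 1
        assert grid.locations[0] == FieldLocation(0.0, 0.0)

    def test_count_and_bounds_match_construction_oracle(self):
        extent = self.extent()
        for sx, sy in [(5.98, 5.52), (6.0, 6.0), (10.0, 10.0), (3.0, 4.0)]:
            grid = generate_grid(extent, sx, sy)
            n_x = int(math.floor(extent.horizontal_deg / sx + 0.5))
            n_y = int(math.floor(extent.vertical_deg / sy + 0.5))
            assert len(grid) == n_x * n_y
            assert max(abs(l.x_deg) for l in grid.locations) <= extent.horizontal_deg / 2
            assert max(abs(l.y_deg) for l in grid.locations) <= extent.vertical_deg / 2
            assert len(set(grid.locations)) == len(grid)

    def test_grid_symmetric_about_fixation(self):
        grid = generate_grid(self.extent(), 5.98, 5.52)
        locs = set(grid.locations)
        for loc in grid.locations:
            assert FieldLocation(-loc.x_deg, loc.y_deg) in locs
            assert FieldLocation(loc.x_deg, -loc.y_deg) in locs

    def test_mirrored_fixation_mirrors_the_grid(self):
        fix = FieldLocation(14.0, 0.0)
        a = generate_grid(self.extent(), 6.0, 6.0, fixation=fix)
        b = generate_grid(self.extent(), 6.0, 6.0, fixation=fix.mirrored())
        assert sorted((-l.x_deg, l.y_deg) for l in b.locations) == sorted(
            (l.x_deg, l.y_deg) for l in a.locations
        )

    def test_invalid_spacing_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_grid(self.extent(), 0.0, 5.0)
        with pytest.raises(InvalidConfigError):
            generate_grid(self.extent(), 100.0, 5.0)


class TestPixelPlacement:
    def test_fixation_maps_to_screen_centre(self, screen):
        x, y = location_to_pixels(FieldLocation(0.0, 0.0), screen)
        assert (x, y) == (960.0, 540.0)

    def test_superior_locations_have_smaller_pixel_y(self, screen):
        _, y_up = location_to_pixels(FieldLocation(0.0, 10.0), screen)
        _, y_down = location_to_pixels(FieldLocation(0.0, -10.0), screen)
        assert y_up < 540.0 < y_down

    def test_sphericity_places_interior_stimuli_inward_of_linear(self, screen):
        # tan is convex: the corrected offset sits inside the linear one
        # everywhere except the screen edge, where both must coincide
        loc = FieldLocation(30.0, 0.0)
        x_lin, _ = location_to_pixels(loc, screen, sphericity=False)
        x_sph, _ = location_to_pixels(loc, screen, sphericity=True)
        assert 960.0 < x_sph < x_lin
        half_extent = screen.field_extent().horizontal_deg / 2
        edge = FieldLocation(half_extent, 0.0)
        e_lin, _ = location_to_pixels(edge, screen, sphericity=False)
        e_sph, _ = location_to_pixels(edge, screen, sphericity=True)
        assert e_sph == pytest.approx(e_lin) == pytest.approx(1920.0)

    def test_grid_export_positions_cover_every_location(self, screen):
        grid = generate_grid(screen.field_extent(), 10.0, 10.0, sphericity=True)
        positions = grid_pixel_positions(grid, screen)
        assert len(positions) == len(grid)
        xs = [p[0] for p in positions]
        assert min(xs) >= 0 and max(xs) <= screen.resolution_x


class TestDefaultBlindspot:
    def test_temporal_and_inferior_to_fixation(self):
        assert default_blindspot("left") == FieldLocation(-15.0, -3.0)
        assert default_blindspot("right") == FieldLocation(15.0, -3.0)

    def test_left_right_mirror_property(self):
        left, right = default_blindspot("left"), default_blindspot("right")
        assert left.x_deg == -right.x_deg
        assert left.y_deg == right.y_deg

    def test_unknown_eye_rejected(self):
        with pytest.raises(DomainError):
            default_blindspot("both")
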