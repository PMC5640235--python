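"""Screen / visual-field geometry for flat-screen perimetry.

Coordinates follow the perimetric convention: degrees of visual angle
relative to the fixation point, x positive to the patient's right,
y positive superior.  Screen pixels have their origin at the top-left with
y increasing downward; the conversion between the two happens only here.

A flat screen at distance ``x`` mm subtends ``2θ = 2·arctan(y / 2x)``
degrees along a side of physical size ``y`` mm.  Equal steps of visual
angle map to unequal physical offsets on a flat surface; the *sphericity
correction* places an element at eccentricity β at the physical offset
``D = x·tan(β)`` mm from the fixation point (applied per axis), which is
then converted to pixels with ``P = D·R / y``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, InvalidConfigError


@dataclass(frozen=True)
class ScreenSetup:
    """Physical screen and viewing distance (all lengths in mm, pixels in px)."""

    width_mm: float
    height_mm: float
    resolution_x: int
    resolution_y: int
    distance_mm: float

    def __post_init__(self) -> None:
        for name in ("width_mm", "height_mm", "resolution_x", "resolution_y", "distance_mm"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")

    def field_extent(self) -> "FieldExtent":
        h = field_extension(self.width_mm, self.distance_mm)
        v = field_extension(self.height_mm, self.distance_mm)
        return FieldExtent(
            horizontal_deg=h,
            vertical_deg=v,
            px_per_deg_x=pixels_per_degree(self.resolution_x, h),
            px_per_deg_y=pixels_per_degree(self.resolution_y, v),
        )


@dataclass(frozen=True)
class FieldExtent:
    """Visual-field extension subtended by the screen, per axis."""

    horizontal_deg: float
    vertical_deg: float
    px_per_deg_x: float
    px_per_deg_y: float


@dataclass(frozen=True)
class FieldLocation:
    """A visual-field location in degrees relative to fixation
    (x > 0 right, y > 0 superior)."""

    x_deg: float
    y_deg: float

    def eccentricity_deg(self) -> float:
        return math.hypot(self.x_deg, self.y_deg)

    def mirrored(self) -> "FieldLocation":
        return FieldLocation(-self.x_deg, self.y_deg)


@dataclass(frozen=True)
class StimulusGrid:
    """Matrix-like arrangement of stimulus locations centred on fixation."""

    locations: tuple[FieldLocation, ...]
    spacing_x_deg: float
    spacing_y_deg: float
    fixation: FieldLocation
    sphericity_corrected: bool

    def __len__(self) -> int:
        return len(self.locations)


def field_extension(screen_side_mm: float, distance_mm: float) -> float:
    """Visual-field extension 2θ (degrees) subtended by a screen side:
    ``2·arctan(side / (2·distance))``."""
    if screen_side_mm < 0 or distance_mm <= 0:
        raise DomainError("screen side must be >= 0 and distance > 0")
    return math.degrees(2.0 * math.atan(screen_side_mm / (2.0 * distance_mm)))


def pixels_per_degree(resolution_px: float, extent_deg: float) -> float:
    """Screen pixels per degree of visual angle along one axis."""
    if resolution_px <= 0 or extent_deg <= 0:
        raise DomainError("resolution and extent must be > 0")
    return resolution_px / extent_deg


def sphericity_correct(distance_mm: float, eccentricity_deg: float) -> float:
    """Physical offset (mm) on a flat screen of a point at the given
    eccentricity: ``distance · tan(eccentricity)``.  Defined for |β| < 90°;
    the sign of the eccentricity is preserved."""
    if distance_mm <= 0:
        raise DomainError(f"distance must be > 0, got {distance_mm}")
    if abs(eccentricity_deg) >= 90.0:
        raise DomainError(f"eccentricity must satisfy |β| < 90°, got {eccentricity_deg}")
    return distance_mm * math.tan(math.radians(eccentricity_deg))


def mm_to_pixels(d_mm: float, resolution_px: float, screen_side_mm: float) -> float:
    """Convert a physical offset along one axis to pixels: ``d · R / side``."""
    if resolution_px <= 0 or screen_side_mm <= 0:
        raise DomainError("resolution and screen side must be > 0")
    return d_mm * resolution_px / screen_side_mm


def _grid_axis_count(extent_deg: float, spacing_deg: float) -> int:
    # round-half-up, so an extent of exactly k.5 spacings yields k+1 columns
    return int(math.floor(extent_deg / spacing_deg + 0.5))


def generate_grid(
    extent: FieldExtent,
    spacing_x_deg: float,
    spacing_y_deg: float,
    fixation: FieldLocation = FieldLocation(0.0, 0.0),
    sphericity: bool = False,
) -> StimulusGrid:
    """Build the matrix of stimulus locations.

    The per-axis count is ``round(extent / spacing)``; locations are spaced
    uniformly in degrees and centred on the fixation point.  The
    ``sphericity`` flag records how on-screen pixel positions will be
    computed (see :func:`grid_pixel_positions`); the degree coordinates
    themselves are identical either way.
    """
    if spacing_x_deg <= 0 or spacing_y_deg <= 0:
        raise InvalidConfigError("stimulus spacings must be > 0")
    if spacing_x_deg > extent.horizontal_deg or spacing_y_deg > extent.vertical_deg:
        raise InvalidConfigError("stimulus spacing exceeds the field extent")
    n_x = _grid_axis_count(extent.horizontal_deg, spacing_x_deg)
    n_y = _grid_axis_count(extent.vertical_deg, spacing_y_deg)
    if n_x < 1 or n_y < 1:
        raise InvalidConfigError("grid would be empty")
    locations = tuple(
        FieldLocation(
            fixation.x_deg + (i - (n_x - 1) / 2.0) * spacing_x_deg,
            fixation.y_deg + (j - (n_y - 1) / 2.0) * spacing_y_deg,
        )
        for j in range(n_y)
        for i in range(n_x)
    )
    return StimulusGrid(
        locations=locations,
        spacing_x_deg=spacing_x_deg,
        spacing_y_deg=spacing_y_deg,
        fixation=fixation,
        sphericity_corrected=sphericity,
    )


def location_to_pixels(
    location: FieldLocation,
    screen: ScreenSetup,
    fixation: FieldLocation = FieldLocation(0.0, 0.0),
    sphericity: bool = False,
) -> tuple[float, float]:
    """On-screen pixel position of a field location.

    The fixation point sits at the screen centre offset by its own degree
    coordinates (converted the same way).  With the sphericity correction,
    each axis offset is ``mm_to_pixels(sphericity_correct(distance, β))``;
    without it, offsets are linear in pixels per degree.  Screen y grows
    downward, so superior (positive y_deg) maps to smaller pixel y.
    """
    extent = screen.field_extent()

    def axis_px(delta_deg: float, resolution: int, side_mm: float, ppd: float) -> float:
        if sphericity:
            return mm_to_pixels(
                sphericity_correct(screen.distance_mm, delta_deg), resolution, side_mm
            )
        return delta_deg * ppd

    dx = axis_px(
        location.x_deg - fixation.x_deg, screen.resolution_x, screen.width_mm, extent.px_per_deg_x
    )
    dy = axis_px(
        location.y_deg - fixation.y_deg, screen.resolution_y, screen.height_mm, extent.px_per_deg_y
    )
    cx = screen.resolution_x / 2.0 + fixation.x_deg * extent.px_per_deg_x
    cy = screen.resolution_y / 2.0 - fixation.y_deg * extent.px_per_deg_y
    return cx + dx, cy - dy


def grid_pixel_positions(grid: StimulusGrid, screen: ScreenSetup) -> list[tuple[float, float]]:
    """Pixel positions of every grid location, honouring the grid's
    sphericity flag."""
    return [
        location_to_pixels(loc, screen, grid.fixation, grid.sphericity_corrected)
        for loc in grid.locations
    ]


def default_blindspot(eye: str) -> FieldLocation:
    """Assumed physiological blind-spot location: 15° temporal and 3°
    inferior to fixation — (−15, −3) for the left eye, (+15, −3) for the
    right eye."""
    if eye == "left":
        return FieldLocation(-15.0, -3.0)
    if eye == "right":
        return FieldLocation(15.0, -3.0)
    raise DomainError(f"eye must be 'left' or 'right', got {eye!r}")
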