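"""Sensitivity maps in dB: construction, aggregation, comparison, rendering.

Each examined location gets ``dB = 10·log10(L_max / L_threshold)`` where
``L_max`` is the fitted luminance at the scale's maximum stimulus
brightness.  A location that never responded — not even to the brightest
stimulus — is expressed as 0 dB, the floor of the scale.  Repeated tests
of the same eye under the same settings are aggregated per location
(sample mean, SD with n−1 denominator, variance, SEM = SD/√n) and two
single results may be compared by simple subtraction, which requires
identical settings (grid, brightness vector, dB reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import brightness_to_luminance, db_to_luminance, luminance_to_db
from .engine import ExamSession
from .errors import IncompatibleResultsError, InvalidInputError, StateError
from .geometry import FieldLocation


@dataclass
class VisualFieldMap:
    """Per-location sensitivity of one examination, in dB."""

    locations: tuple[FieldLocation, ...]
    db_values: np.ndarray
    l_max: float
    eye: str
    fixation: FieldLocation = FieldLocation(0.0, 0.0)
    control_location: FieldLocation | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.db_values = np.asarray(self.db_values, dtype=float)
        if len(self.locations) != self.db_values.size:
            raise InvalidInputError("db_values length must match locations")
        if np.any(self.db_values < 0):
            raise InvalidInputError("dB sensitivity cannot be negative")

    def settings_signature(self) -> tuple:
        vector = self.metadata.get("vector")
        return (self.locations, round(self.l_max, 9), vector)


@dataclass
class MapAggregate:
    """Per-location statistics over n repeated maps of one eye."""

    locations: tuple[FieldLocation, ...]
    n: int
    mean_map: np.ndarray
    sd_map: np.ndarray
    variance_map: np.ndarray
    sem_map: np.ndarray
    l_max: float
    eye: str


def build_map(session: ExamSession, scale=None) -> VisualFieldMap:
    """Sensitivity map of a finished session.

    ``scale`` defaults to the session's own luminance scale.  The dB
    reference is the fitted luminance at the configured maximum stimulus
    brightness; no-response locations map to 0 dB.
    """
    if session.cancelled:
        raise StateError("a cancelled session stores no results (data discarded)")
    scale = scale if scale is not None else session.scale
    l_max = brightness_to_luminance(scale, int(round(session.config.brightness.max_pct)))
    thresholds = session.thresholds()
    db = np.zeros(len(session.grid))
    for i in range(len(session.grid)):
        _, lum = thresholds[i]
        if lum is not None:
            db[i] = luminance_to_db(min(lum, l_max), l_max)
    control = session.control_location
    if control is None:
        control = session.config.fixation.blindspot_location
    return VisualFieldMap(
        locations=session.grid.locations,
        db_values=db,
        l_max=l_max,
        eye=session.eye,
        fixation=session.grid.fixation,
        control_location=control,
        metadata={
            "vector": session.vector.values,
            "scale_id": scale.id,
            "summary": session.summary(),
        },
    )


def _check_same_frame(maps) -> None:
    first = maps[0]
    for m in maps[1:]:
        if m.locations != first.locations:
            raise IncompatibleResultsError("maps cover different location grids")
        if not np.isclose(m.l_max, first.l_max, rtol=0, atol=1e-9):
            raise IncompatibleResultsError("maps use different dB references (l_max)")


def aggregate_maps(maps) -> MapAggregate:
    """Per-location mean, sample SD, variance and SEM over n ≥ 2 maps."""
    maps = list(maps)
    if len(maps) < 2:
        raise InvalidInputError("aggregation needs at least two maps")
    _check_same_frame(maps)
    stack = np.vstack([m.db_values for m in maps])
    sd = np.std(stack, axis=0, ddof=1)
    return MapAggregate(
        locations=maps[0].locations,
        n=len(maps),
        mean_map=np.mean(stack, axis=0),
        sd_map=sd,
        variance_map=sd**2,
        sem_map=sd / np.sqrt(len(maps)),
        l_max=maps[0].l_max,
        eye=maps[0].eye,
    )


def subtract_maps(map_a: VisualFieldMap, map_b: VisualFieldMap) -> np.ndarray:
    """Follow-up comparison ``a − b`` per location (positive = sensitivity
    gain of a over b).  Refuses maps taken with different settings."""
    if map_a.settings_signature() != map_b.settings_signature():
        raise IncompatibleResultsError(
            "subtraction requires identical settings (grid, vector, dB reference)"
        )
    return map_a.db_values - map_b.db_values


def rebase_db(db: float, l_max_from: float, l_max_to: float) -> float:
    """Re-express a dB value against another instrument's maximum luminance
    (e.g. a 318 cd/m² differential maximum), for cross-device comparison.

    The underlying threshold luminance is held fixed:
    ``rebase = 10·log10(l_max_to / (l_max_from / 10^(db/10)))``.  Luminances
    above the target maximum clip to 0 dB (the target scale cannot express
    them)."""
    luminance = db_to_luminance(db, l_max_from)
    if luminance >= l_max_to:
        return 0.0
    return luminance_to_db(luminance, l_max_to)


def render_map(
    map_or_values,
    *,
    palette: str = "grayscale",
    interpolation: str = "none",
    db_range: tuple[float, float] | None = None,
    title: str | None = None,
    ax=None,
    symmetric: bool = False,
):
    """Render a map (or per-location values) as a raster image.

    Axes cross at the fixation point with ticks every 10°; the blind-spot /
    control location is marked with a white "X"; a dB colour bar is added.
    ``palette`` is "grayscale" (larger dB → lighter) or "color";
    ``interpolation`` is "none" (one cell per location) or "bilinear".
    Pass ``symmetric=True`` for difference maps (diverging palette centred
    on zero).  Returns the matplotlib Axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if isinstance(map_or_values, VisualFieldMap):
        vf, values = map_or_values, map_or_values.db_values
    else:
        vf, values = map_or_values[0], np.asarray(map_or_values[1], dtype=float)

    xs = sorted({loc.x_deg for loc in vf.locations})
    ys = sorted({loc.y_deg for loc in vf.locations})
    img = np.full((len(ys), len(xs)), np.nan)
    xi = {x: i for i, x in enumerate(xs)}
    yi = {y: i for i, y in enumerate(ys)}
    for loc, v in zip(vf.locations, values):
        img[yi[loc.y_deg], xi[loc.x_deg]] = v

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    cmap = "gray" if palette == "grayscale" else ("RdBu_r" if symmetric else "viridis")
    if db_range is None:
        if symmetric:
            m = max(1e-9, float(np.nanmax(np.abs(img))))
            db_range = (-m, m)
        else:
            db_range = (0.0, max(1e-9, float(np.nanmax(img))))
    half_x = xs[1] - xs[0] if len(xs) > 1 else 1.0
    half_y = ys[1] - ys[0] if len(ys) > 1 else 1.0
    extent = (
        xs[0] - half_x / 2,
        xs[-1] + half_x / 2,
        ys[0] - half_y / 2,
        ys[-1] + half_y / 2,
    )
    im = ax.imshow(
        img,
        origin="lower",
        cmap=cmap,
        vmin=db_range[0],
        vmax=db_range[1],
        interpolation=interpolation if interpolation != "none" else "nearest",
        extent=extent,
        aspect="equal",
    )
    ax.axhline(vf.fixation.y_deg, color="0.5", lw=0.8)
    ax.axvline(vf.fixation.x_deg, color="0.5", lw=0.8)
    tick = lambda lo, hi: np.arange(np.ceil(lo / 10) * 10, hi + 1e-9, 10)
    ax.set_xticks(tick(extent[0], extent[1]))
    ax.set_yticks(tick(extent[2], extent[3]))
    if vf.control_location is not None:
        ax.plot(
            vf.control_location.x_deg,
            vf.control_location.y_deg,
            marker="x",
            color="white",
            markersize=10,
            markeredgewidth=2,
        )
    ax.set_xlabel("eccentricity (°)")
    ax.set_ylabel("eccentricity (°)")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, label="sensitivity (dB)")
    return ax
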