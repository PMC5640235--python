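"""Simulated observer: a configurable stand-in for the patient.

The observer owns a ground-truth sensitivity map (threshold luminance per
visual-field location, or blind) and three noise parameters:

* ``guess_rate`` γ — probability of responding to a stimulus that was not
  seen (and of a spurious key press in a gap with no stimulus);
* ``lapse_rate`` λ — probability of missing a stimulus that was seen;
* ``fixation_loss_prob`` q — probability that any given fixation check
  happens while fixation is lost (i.i.d. per check).

Detection defaults to a step function of luminance (the staircase model is
binary seen/not-seen); an optional logistic slope in dB softens the step
for studies of procedure robustness.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .errors import InvalidConfigError, InvalidInputError
from .geometry import FieldLocation, StimulusGrid

BLIND = None  # truth-map value for a location that never sees anything


@dataclass
class SimulatedObserver:
    """A deterministic-given-seed simulated patient."""

    truth_map: dict[FieldLocation, float | None]
    guess_rate: float = 0.0
    lapse_rate: float = 0.0
    fixation_loss_prob: float = 0.0
    seed: int = 0
    logistic_slope_per_db: float | None = None
    rng: random.Random = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("guess_rate", "lapse_rate", "fixation_loss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        if self.guess_rate + self.lapse_rate > 1.0:
            raise InvalidConfigError("guess_rate + lapse_rate must not exceed 1")
        for loc, thr in self.truth_map.items():
            if thr is not None and thr <= 0:
                raise InvalidConfigError(f"threshold at {loc} must be positive or blind")
        self.rng = random.Random(self.seed)

    # -- responses -------------------------------------------------------

    def detection_probability(self, location: FieldLocation, luminance: float) -> float:
        """Probability of a response to a stimulus of the given luminance."""
        if location not in self.truth_map:
            raise InvalidInputError(f"location {location} not in the observer's truth map")
        threshold = self.truth_map[location]
        if threshold is BLIND:
            p_seen = 0.0
        elif self.logistic_slope_per_db is None:
            p_seen = 1.0 if luminance >= threshold else 0.0
        else:
            if luminance <= 0:
                p_seen = 0.0
            else:
                d_db = 10.0 * math.log10(luminance / threshold)
                p_seen = 1.0 / (1.0 + math.exp(-self.logistic_slope_per_db * d_db))
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * p_seen

    def would_see(self, location: FieldLocation, luminance: float) -> bool:
        """Noise-free ground truth: is the stimulus at or above threshold?"""
        threshold = self.truth_map[location]
        return threshold is not BLIND and luminance >= threshold

    def respond_stimulus(self, location: FieldLocation, luminance: float) -> bool:
        """Seen stimuli are answered with probability 1−λ, unseen with γ."""
        if location not in self.truth_map:
            raise InvalidInputError(f"location {location} not in the observer's truth map")
        if self.logistic_slope_per_db is None:
            if self.would_see(location, luminance):
                return self.rng.random() < 1.0 - self.lapse_rate
            return self.rng.random() < self.guess_rate
        return self.rng.random() < self.detection_probability(location, luminance)

    def respond_fixation_check(self, kind: str) -> bool:
        """Response to a fixation check.

        With probability 1−q fixation is held: the blind-spot control falls
        on the optic disc (respond only by guess γ) and a point change is
        noticed (respond unless lapsing, 1−λ).  With probability q fixation
        is lost: the control stimulus lands on seeing retina (respond) and
        the point change goes unnoticed (silent).
        """
        from .fixation import BLINDSPOT, POINT_CHANGE  # cycle-free local import

        if kind not in (BLINDSPOT, POINT_CHANGE):
            raise InvalidInputError(f"unknown fixation check kind {kind!r}")
        lost = self.rng.random() < self.fixation_loss_prob
        if kind == BLINDSPOT:
            if lost:
                return True
            return self.rng.random() < self.guess_rate
        if lost:
            return False
        return self.rng.random() < 1.0 - self.lapse_rate

    def respond_no_stimulus(self) -> bool:
        """Spurious key press during a gap with no open response window."""
        return self.rng.random() < self.guess_rate


# -- truth-map presets ---------------------------------------------------


def uniform_truth(grid: StimulusGrid, threshold: float) -> dict[FieldLocation, float | None]:
    """Every location detects at the same threshold luminance."""
    return {loc: threshold for loc in grid.locations}


def hemianopia_truth(
    grid: StimulusGrid, threshold: float, blind_side: str = "right"
) -> dict[FieldLocation, float | None]:
    """One half-field blind (e.g. homonymous hemianopia after stroke):
    locations on the blind side never respond."""
    if blind_side not in ("left", "right"):
        raise InvalidConfigError(f"blind_side must be 'left' or 'right', got {blind_side!r}")
    sign = 1.0 if blind_side == "right" else -1.0
    return {
        loc: (BLIND if sign * loc.x_deg > 0 else threshold) for loc in grid.locations
    }


def tunnel_truth(
    grid: StimulusGrid, threshold: float, radius_deg: float = 10.0
) -> dict[FieldLocation, float | None]:
    """Tunnel vision (advanced retinitis pigmentosa): only locations within
    ``radius_deg`` of fixation respond."""
    fix = grid.fixation
    return {
        loc: (
            threshold
            if math.hypot(loc.x_deg - fix.x_deg, loc.y_deg - fix.y_deg) <= radius_deg
            else BLIND
        )
        for loc in grid.locations
    }


def scotoma_truth(
    grid: StimulusGrid,
    threshold: float,
    center: FieldLocation,
    radius_deg: float = 3.0,
) -> dict[FieldLocation, float | None]:
    """A blind patch (default use: the physiological blind spot) on an
    otherwise uniform field."""
    return {
        loc: (
            BLIND
            if math.hypot(loc.x_deg - center.x_deg, loc.y_deg - center.y_deg) <= radius_deg
            else threshold
        )
        for loc in grid.locations
    }


TRUTH_PRESETS = ("uniform", "hemianopia", "tunnel", "scotoma")


def make_observer(
    grid: StimulusGrid,
    truth,
    guess_rate: float = 0.0,
    lapse_rate: float = 0.0,
    fixation_loss_prob: float = 0.0,
    seed: int = 0,
    logistic_slope_per_db: float | None = None,
) -> SimulatedObserver:
    """Build an observer from a truth map or a preset spec.

    ``truth`` may be a ready ``{FieldLocation: threshold-or-None}`` dict or
    a spec dict such as ``{"preset": "hemianopia", "threshold_cd_m2": 10,
    "blind_side": "right"}`` (presets: uniform, hemianopia, tunnel,
    scotoma).
    """
    if isinstance(truth, dict) and "preset" in truth:
        truth_map = _truth_from_spec(grid, truth)
    elif isinstance(truth, dict):
        truth_map = dict(truth)
    else:
        raise InvalidConfigError("truth must be a truth map or a preset spec dict")
    return SimulatedObserver(
        truth_map=truth_map,
        guess_rate=guess_rate,
        lapse_rate=lapse_rate,
        fixation_loss_prob=fixation_loss_prob,
        seed=seed,
        logistic_slope_per_db=logistic_slope_per_db,
    )


def _truth_from_spec(grid: StimulusGrid, spec: dict) -> dict[FieldLocation, float | None]:
    preset = spec["preset"]
    threshold = float(spec.get("threshold_cd_m2", 10.0))
    if preset == "uniform":
        return uniform_truth(grid, threshold)
    if preset == "hemianopia":
        return hemianopia_truth(grid, threshold, spec.get("blind_side", "right"))
    if preset == "tunnel":
        return tunnel_truth(grid, threshold, float(spec.get("radius_deg", 10.0)))
    if preset == "scotoma":
        center = FieldLocation(
            float(spec.get("center_x_deg", 15.0)), float(spec.get("center_y_deg", -3.0))
        )
        return scotoma_truth(grid, threshold, center, float(spec.get("radius_deg", 3.0)))
    raise InvalidConfigError(f"unknown truth preset {preset!r}; choose from {TRUTH_PRESETS}")


def observer_from_spec(spec: dict, grid: StimulusGrid, seed: int | None = None) -> SimulatedObserver:
    """Observer from a parsed JSON spec (see the CLI).  ``seed`` overrides
    the spec's own seed when given."""
    return make_observer(
        grid,
        spec.get("truth", {"preset": "uniform"}),
        guess_rate=float(spec.get("guess_rate", 0.0)),
        lapse_rate=float(spec.get("lapse_rate", 0.0)),
        fixation_loss_prob=float(spec.get("fixation_loss_prob", 0.0)),
        seed=int(spec.get("seed", 0)) if seed is None else seed,
        logistic_slope_per_db=spec.get("logistic_slope_per_db"),
    )
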