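"""Fixation monitoring for flat-screen perimetry.

Three techniques are supported:

* **blindspot** (Heijl-Krakau): a *control* stimulus is shown at the
  assumed optic-disc location.  A patient holding fixation cannot see it,
  so a response means the eye has moved — responded → fixation *lost*.
* **fixation_point_change**: the fixation point briefly changes size or
  colour and the patient must respond; silence means the eye was not on
  the point — not responded → *lost*.
* **both**: checks alternate randomly between the two techniques, with
  accuracy counted separately per technique (the blind-spot technique is
  unreliable when the assumed optic-disc location misses the patient's
  actual blind spot, so its accuracy must remain inspectable on its own).

Fixation checks never feed a location's staircase; they only update the
session's reliability counters and, optionally, emit a feedback message.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DomainError, InvalidConfigError
from .geometry import FieldLocation

BLINDSPOT = "blindspot_check"
POINT_CHANGE = "fixation_point_change"
TECHNIQUES = ("blindspot", "fixation_point_change", "both")

#: Blind-spot accuracy below this fraction is flagged as unreliable in the
#: session summary — the assumed optic-disc location likely misses the
#: patient's true blind spot.  A tooling choice, not a clinical standard.
BLINDSPOT_RELIABILITY_FLOOR = 0.75


@dataclass(frozen=True)
class FeedbackSpec:
    """Appearance of the fixation-loss message shown to the patient."""

    enabled: bool = True
    text: str = "Please fixate on the central point"
    position: str = "center"
    color: str = "white"
    font_size_pt: int = 24


@dataclass(frozen=True)
class FixationConfig:
    technique: str = "both"
    blindspot_location: FieldLocation | None = None  # None → per-eye default
    control_brightness_pct: int = 100
    control_width_deg: float = 0.4
    control_height_deg: float = 0.4
    check_freq_min: int = 5
    check_freq_max: int = 10
    changed_point_size_deg: float = 0.5
    changed_point_color: str = "red"
    feedback: FeedbackSpec = field(default_factory=FeedbackSpec)

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise InvalidConfigError(
                f"technique must be one of {TECHNIQUES}, got {self.technique!r}"
            )
        if not 1 <= self.check_freq_min <= self.check_freq_max:
            raise InvalidConfigError(
                "check frequency interval must satisfy 1 <= min <= max, got "
                f"[{self.check_freq_min}, {self.check_freq_max}]"
            )
        if not 0 <= self.control_brightness_pct <= 100:
            raise InvalidConfigError("control stimulus brightness must be in [0, 100] %")


@dataclass(frozen=True)
class FixationEvent:
    kind: str  # BLINDSPOT | POINT_CHANGE
    responded: bool
    verdict: str  # "fixating" | "lost"


@dataclass(frozen=True)
class FeedbackMessage:
    time_ms: float
    text: str
    position: str
    color: str
    font_size_pt: int


def evaluate_check(kind: str, responded: bool) -> str:
    """Verdict of one fixation check.

    Blind-spot control: a response means the (invisible-when-fixating)
    stimulus was seen → lost.  Point change: a response is required →
    silence means lost.
    """
    if kind == BLINDSPOT:
        return "lost" if responded else "fixating"
    if kind == POINT_CHANGE:
        return "fixating" if responded else "lost"
    raise DomainError(f"unknown fixation check kind {kind!r}")


def next_check_kind(technique: str, rng) -> str:
    """Kind of the next inserted check.  Single-technique modes are
    constant; *both* draws uniformly at random so that each technique
    accumulates its own counts."""
    if technique == "blindspot":
        return BLINDSPOT
    if technique == "fixation_point_change":
        return POINT_CHANGE
    if technique == "both":
        return BLINDSPOT if rng.random() < 0.5 else POINT_CHANGE
    raise DomainError(f"unknown technique {technique!r}")


def emit_feedback(
    event: FixationEvent, config: FixationConfig, time_ms: float = 0.0
) -> FeedbackMessage | None:
    """Feedback message for a lost-fixation event, or None.

    Purely informational: never touches staircase or scheduling state.
    """
    if event.verdict != "lost" or not config.feedback.enabled:
        return None
    fb = config.feedback
    return FeedbackMessage(
        time_ms=time_ms,
        text=fb.text,
        position=fb.position,
        color=fb.color,
        font_size_pt=fb.font_size_pt,
    )
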