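"""The examination engine: scheduling, bookkeeping and reliability indices.

The engine runs the *Basic* staircase (see :mod:`campimetry.staircase`)
over every location of a stimulus grid.  At each step an unfinished
location is drawn uniformly at random and its current vector brightness is
presented; after every k ordinary stimuli (k drawn uniformly from the
configured integer interval) a fixation check is inserted.  Time is
virtual: the session clock advances by the stimulus display time plus an
inter-stimulus interval drawn uniformly from [isi_min, isi_max].

Response-window contract: the permission to respond opens with a
presentation and ends with the response or with the next presentation.
Any press inside an open window counts as a positive response P (the
engine cannot see ground truth); a press arriving in a gap whose window
has already closed counts as a false positive F.  The false-positive
response rate FPRR = F / (F + P) · 100 and the per-technique fixation
accuracy are the session's reliability indices; raw counts are always kept
so either convention found in the literature (F/(F+P) or F/P) can be
recomputed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .errors import InvalidConfigError, StateError
from .fixation import (
    BLINDSPOT,
    POINT_CHANGE,
    FeedbackMessage,
    FixationConfig,
    FixationEvent,
    emit_feedback,
    evaluate_check,
    next_check_kind,
)
from .calibration import LuminanceScale, brightness_to_luminance
from .geometry import (
    FieldLocation,
    ScreenSetup,
    StimulusGrid,
    default_blindspot,
    generate_grid,
)
from .observer import SimulatedObserver
from .staircase import (
    BrightnessVector,
    StaircaseState,
    make_brightness_vector,
    staircase_init,
    staircase_step,
    staircase_threshold,
)


@dataclass(frozen=True)
class StimulusSpec:
    """Shape, size and timing of the ordinary stimulus."""

    shape: str = "ellipse"  # "ellipse" | "polygon"
    width_deg: float = 0.4
    height_deg: float = 0.4
    inclination_deg: float = 0.0
    display_time_ms: float = 200.0
    isi_min_ms: float = 1200.0
    isi_max_ms: float = 1600.0

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "polygon"):
            raise InvalidConfigError(f"shape must be 'ellipse' or 'polygon', got {self.shape!r}")
        if self.display_time_ms <= 0:
            raise InvalidConfigError("display time must be > 0")
        if not 0 <= self.isi_min_ms <= self.isi_max_ms:
            raise InvalidConfigError("need 0 <= isi_min <= isi_max")


@dataclass(frozen=True)
class BrightnessSpec:
    """Parameters of the staircase brightness vector."""

    min_pct: float = 0.0
    max_pct: float = 100.0
    length: int = 9
    spread: str = "equal"

    def make_vector(self) -> BrightnessVector:
        return make_brightness_vector(self.min_pct, self.max_pct, self.length, self.spread)


@dataclass(frozen=True)
class KeyBindings:
    answer: str = "SPACE"
    pause: str = "P"
    cancel: str = "ESCAPE"


@dataclass(frozen=True)
class ExamConfig:
    """Everything needed to run (or re-run) one examination."""

    screen: ScreenSetup
    spacing_x_deg: float = 6.0
    spacing_y_deg: float = 6.0
    fixation_x_deg: float = 0.0
    fixation_y_deg: float = 0.0
    sphericity: bool = True
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    brightness: BrightnessSpec = field(default_factory=BrightnessSpec)
    stimulus_scale_id: str = ""
    background_scale_id: str = ""
    background_brightness_pct: int = 12
    fixation: FixationConfig = field(default_factory=FixationConfig)
    keys: KeyBindings = field(default_factory=KeyBindings)
    seed: int = 0

    def __post_init__(self) -> None:
        self.brightness.make_vector()  # validates length/range/spread
        if not 0 <= self.background_brightness_pct <= 100:
            raise InvalidConfigError("background brightness must be in [0, 100] %")

    def make_grid(self) -> StimulusGrid:
        return generate_grid(
            self.screen.field_extent(),
            self.spacing_x_deg,
            self.spacing_y_deg,
            FieldLocation(self.fixation_x_deg, self.fixation_y_deg),
            self.sphericity,
        )


@dataclass
class ResponseCounters:
    """Reliability counters; fixation checks are tallied per technique so
    the *both* mode remains separable."""

    positives: int = 0  # P
    false_positives: int = 0  # F
    blindspot_total: int = 0
    blindspot_correct: int = 0
    point_change_total: int = 0
    point_change_correct: int = 0

    @property
    def fixation_checks_total(self) -> int:
        return self.blindspot_total + self.point_change_total

    @property
    def fixation_checks_correct(self) -> int:
        return self.blindspot_correct + self.point_change_correct


@dataclass(frozen=True)
class PresentationRecord:
    """One row of the presentation log."""

    seq: int
    time_ms: float
    kind: str  # "stimulus" | "blindspot_check" | "fixation_change"
    loc_index: int | None
    brightness_pct: float | None
    luminance_cd_m2: float | None
    response: bool
    verdict: str | None = None


@dataclass
class ExamSession:
    """The complete record of one (simulated) examination."""

    config: ExamConfig
    eye: str
    grid: StimulusGrid
    vector: BrightnessVector
    scale: LuminanceScale
    states: dict[int, StaircaseState]
    records: list[PresentationRecord]
    counters: ResponseCounters
    feedback_messages: list[FeedbackMessage]
    duration_ms: float = 0.0
    paused_ms: float = 0.0
    cancelled: bool = False
    control_location: FieldLocation | None = None  # resolved blind-spot position

    @property
    def finished(self) -> bool:
        return all(s.finished for s in self.states.values())

    def record_pause(self, pause_ms: float) -> None:
        """A self-paced break: the duration counter keeps running."""
        if pause_ms < 0:
            raise InvalidConfigError("pause duration must be >= 0")
        self.paused_ms += pause_ms
        self.duration_ms += pause_ms

    def cancel(self) -> None:
        """Abort the test; a cancelled session stores no results."""
        self.cancelled = True
        self.states = {}
        self.records = []

    def thresholds(self) -> dict[int, tuple[float | None, float | None]]:
        """(brightness %, luminance) per location index of a finished,
        not-cancelled session."""
        if self.cancelled:
            raise StateError("a cancelled session stores no results")
        if not self.finished:
            raise StateError("session has unfinished locations")
        return {
            i: staircase_threshold(s, self.vector, self.scale) for i, s in self.states.items()
        }

    def summary(self) -> dict:
        c = self.counters
        out = {
            "eye": self.eye,
            "duration_ms": self.duration_ms,
            "paused_ms": self.paused_ms,
            "n_locations": len(self.grid),
            "positives": c.positives,
            "false_positives": c.false_positives,
            "fprr_pct": false_positive_rate(c),
            "blindspot_checks": f"{c.blindspot_correct}/{c.blindspot_total}",
            "blindspot_accuracy_pct": fixation_accuracy(c.blindspot_correct, c.blindspot_total),
            "point_change_checks": f"{c.point_change_correct}/{c.point_change_total}",
            "point_change_accuracy_pct": fixation_accuracy(
                c.point_change_correct, c.point_change_total
            ),
            "fixation_accuracy_pct": fixation_accuracy(
                c.fixation_checks_correct, c.fixation_checks_total
            ),
        }
        bs_acc = out["blindspot_accuracy_pct"]
        out["blindspot_unreliable"] = bool(bs_acc is not None and bs_acc < 75.0)
        return out


def false_positive_rate(counters: ResponseCounters) -> float | None:
    """FPRR = F / (F + P) · 100, or None when no responses were recorded."""
    total = counters.false_positives + counters.positives
    if total == 0:
        return None
    return 100.0 * counters.false_positives / total


def fixation_accuracy(correct: int, total: int) -> float | None:
    """Correct fixation checks as a percentage of all checks, or None."""
    if total == 0:
        return None
    if not 0 <= correct <= total:
        raise InvalidConfigError("need 0 <= correct <= total")
    return 100.0 * correct / total


class ExamScheduler:
    """Lazy presentation scheduler implementing the random-order policy.

    Drives the staircases to completion against any responder exposing the
    :class:`~campimetry.observer.SimulatedObserver` interface.  A real
    display/keyboard front-end can be plugged in by implementing the same
    three methods (``respond_stimulus``, ``respond_fixation_check``,
    ``respond_no_stimulus``).
    """

    def __init__(
        self,
        config: ExamConfig,
        scale: LuminanceScale,
        eye: str,
        rng: random.Random | None = None,
    ):
        self.config = config
        self.scale = scale
        self.eye = eye
        self.rng = rng if rng is not None else random.Random(config.seed)
        self.grid = config.make_grid()
        self.vector = config.brightness.make_vector()
        fx = config.fixation
        if fx.blindspot_location is None:
            fx = replace(fx, blindspot_location=default_blindspot(eye))
        self.fixation = fx

    def _draw_isi(self) -> float:
        s = self.config.stimulus
        return self.rng.uniform(s.isi_min_ms, s.isi_max_ms)

    def _draw_check_gap(self) -> int:
        return self.rng.randint(self.fixation.check_freq_min, self.fixation.check_freq_max)

    def run(self, observer: SimulatedObserver) -> ExamSession:
        cfg = self.config
        session = ExamSession(
            config=cfg,
            eye=self.eye,
            grid=self.grid,
            vector=self.vector,
            scale=self.scale,
            states={i: staircase_init(self.vector) for i in range(len(self.grid))},
            records=[],
            counters=ResponseCounters(),
            feedback_messages=[],
            control_location=self.fixation.blindspot_location,
        )
        unfinished = list(session.states)
        seq = 0
        since_check = 0
        next_check_after = self._draw_check_gap()
        display = cfg.stimulus.display_time_ms

        while unfinished:
            # ordinary stimulus at a random unfinished location
            pick = self.rng.randrange(len(unfinished))
            loc_index = unfinished[pick]
            state = session.states[loc_index]
            brightness = self.vector[state.current]
            luminance = brightness_to_luminance(self.scale, int(round(brightness)))
            location = self.grid.locations[loc_index]
            response = observer.respond_stimulus(location, luminance)
            session.states[loc_index] = staircase_step(state, response)
            if session.states[loc_index].finished:
                unfinished[pick] = unfinished[-1]
                unfinished.pop()
            session.records.append(
                PresentationRecord(
                    seq=seq,
                    time_ms=session.duration_ms,
                    kind="stimulus",
                    loc_index=loc_index,
                    brightness_pct=brightness,
                    luminance_cd_m2=luminance,
                    response=response,
                )
            )
            seq += 1
            session.duration_ms += display + self._draw_isi()
            self._tally_gap(session, response, observer)
            since_check += 1

            if since_check >= next_check_after:
                self._fixation_check(session, observer, seq)
                seq += 1
                since_check = 0
                next_check_after = self._draw_check_gap()

        return session

    def _tally_gap(self, session: ExamSession, responded: bool, observer) -> None:
        # Window closed by a response → any further press in the gap is F.
        # Window left open (no response) → a gap press would be attributed
        # to the stimulus, but that attribution is already folded into the
        # observer's guess response at presentation time.
        if responded:
            session.counters.positives += 1
            if observer.respond_no_stimulus():
                session.counters.false_positives += 1

    def _fixation_check(self, session: ExamSession, observer, seq: int) -> None:
        kind = next_check_kind(self.fixation.technique, self.rng)
        responded = observer.respond_fixation_check(kind)
        verdict = evaluate_check(kind, responded)
        event = FixationEvent(kind=kind, responded=responded, verdict=verdict)
        c = session.counters
        if kind == BLINDSPOT:
            c.blindspot_total += 1
            c.blindspot_correct += verdict == "fixating"
            brightness = float(self.fixation.control_brightness_pct)
            luminance = brightness_to_luminance(self.scale, self.fixation.control_brightness_pct)
        else:
            c.point_change_total += 1
            c.point_change_correct += verdict == "fixating"
            brightness = None
            luminance = None  # fixation point colour sits outside the scale
        session.records.append(
            PresentationRecord(
                seq=seq,
                time_ms=session.duration_ms,
                kind="blindspot_check" if kind == BLINDSPOT else "fixation_change",
                loc_index=None,
                brightness_pct=brightness,
                luminance_cd_m2=luminance,
                response=responded,
                verdict=verdict,
            )
        )
        session.duration_ms += self.config.stimulus.display_time_ms + self._draw_isi()
        self._tally_gap(session, responded, observer)
        message = emit_feedback(event, self.fixation, time_ms=session.duration_ms)
        if message is not None:
            session.feedback_messages.append(message)


def schedule_exam(
    config: ExamConfig,
    scale: LuminanceScale,
    eye: str,
    rng: random.Random | None = None,
) -> ExamScheduler:
    """Build the lazy scheduler for an exam (see :class:`ExamScheduler`)."""
    return ExamScheduler(config, scale, eye, rng)


def run_exam(
    config: ExamConfig,
    observer: SimulatedObserver,
    scale: LuminanceScale,
    eye: str = "left",
    rng: random.Random | None = None,
) -> ExamSession:
    """Run the full closed-loop simulated examination to completion."""
    return schedule_exam(config, scale, eye, rng).run(observer)
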