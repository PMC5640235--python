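"""The *Basic* adaptive staircase over a brightness vector.

Each visual-field location is searched over a fixed, ascending vector of
stimulus brightness percents.  Testing starts from the middle of the
vector and moves by one or two positions per response, maintaining a
bracket [lo, hi] of still-candidate indices:

* "not seen" at index i eliminates every index <= i (``lo = i + 1``) and
  jumps two up (clipped to ``hi``);
* "seen" at index i caps the bracket (``hi = i``) and steps one down.

The search terminates with the lowest index answered "seen" whose
predecessor was answered "not seen" or eliminated, or with no threshold at
all when even the brightest value went unseen.  The admissible vector
lengths are 5 + 4n (9, 13, 17, ...): these make the initial midpoint and
the two-up/one-down stepping land exactly on the endpoints.

Indices are 1-based throughout, matching the usual description of the
procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibration import LuminanceScale, brightness_to_luminance
from .errors import InvalidConfigError, StateError

ADMISSIBLE_LENGTHS_HINT = "length must be 5 + 4n for natural n, i.e. 9, 13, 17, 21, ..."


@dataclass(frozen=True)
class BrightnessVector:
    """Ascending stimulus brightness levels (%) searched by the staircase."""

    values: tuple[float, ...]
    spread: str  # "equal" | "logarithmic"

    @property
    def length(self) -> int:
        return len(self.values)

    def __getitem__(self, index_1based: int) -> float:
        if not 1 <= index_1based <= self.length:
            raise IndexError(f"staircase index {index_1based} outside 1..{self.length}")
        return self.values[index_1based - 1]


def make_brightness_vector(
    min_pct: float, max_pct: float, length: int, spread: str = "equal"
) -> BrightnessVector:
    """Build the brightness vector: an arithmetic ("equal") or geometric
    ("logarithmic") progression from ``min_pct`` to ``max_pct`` with an
    admissible length (9, 13, 17, ...)."""
    if length < 9 or (length - 5) % 4 != 0:
        raise InvalidConfigError(f"inadmissible vector length {length}; {ADMISSIBLE_LENGTHS_HINT}")
    if not (0 <= min_pct < max_pct <= 100):
        raise InvalidConfigError(
            f"need 0 <= min < max <= 100 %, got min={min_pct}, max={max_pct}"
        )
    if spread == "equal":
        values = np.linspace(min_pct, max_pct, length)
    elif spread == "logarithmic":
        if min_pct <= 0:
            raise InvalidConfigError("logarithmic spread requires min brightness > 0")
        values = np.geomspace(min_pct, max_pct, length)
    else:
        raise InvalidConfigError(f"spread must be 'equal' or 'logarithmic', got {spread!r}")
    return BrightnessVector(values=tuple(float(v) for v in values), spread=spread)


@dataclass(frozen=True)
class StaircaseState:
    """Immutable search state; :func:`staircase_step` returns the successor.

    ``lo``/``hi`` bound the still-candidate 1-based indices, ``current`` is
    the index being presented, ``history`` logs (index, seen) pairs.
    """

    length: int
    lo: int
    hi: int
    current: int
    history: tuple[tuple[int, bool], ...] = ()
    threshold_index: int | None = None
    finished: bool = False


def staircase_init(vector: BrightnessVector) -> StaircaseState:
    """Fresh state: full bracket, presentation starting mid-vector."""
    n = vector.length
    return StaircaseState(length=n, lo=1, hi=n, current=(n + 1) // 2)


def staircase_step(state: StaircaseState, seen: bool) -> StaircaseState:
    """Advance the search by one response at ``state.current``."""
    if state.finished:
        raise StateError("cannot step a finished staircase")
    history = state.history + ((state.current, seen),)
    if not seen:
        lo = state.current + 1
        if lo > state.hi:
            return replace(state, lo=lo, history=history, finished=True, threshold_index=None)
        return replace(state, lo=lo, history=history, current=min(state.current + 2, state.hi))
    hi = state.current
    if state.current - 1 >= state.lo:
        return replace(state, hi=hi, history=history, current=state.current - 1)
    return replace(state, hi=hi, history=history, finished=True, threshold_index=state.current)


def staircase_threshold(
    state: StaircaseState, vector: BrightnessVector, scale: LuminanceScale
) -> tuple[float | None, float | None]:
    """Map a finished staircase to (threshold brightness %, fitted luminance).

    A no-response search propagates ``(None, None)``; downstream the map
    builder renders that as 0 dB.
    """
    if not state.finished:
        raise StateError("staircase has not terminated")
    if state.threshold_index is None:
        return None, None
    brightness = vector[state.threshold_index]
    return brightness, brightness_to_luminance(scale, int(round(brightness)))


def presentation_indices(state: StaircaseState) -> list[int]:
    """The sequence of vector indices presented so far, in order."""
    return [i for i, _ in state.history]
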