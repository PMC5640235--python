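"""Luminance calibration of a display and decibel sensitivity arithmetic.

A flat-screen perimeter has no built-in knowledge of the physical luminance
its pixels emit.  The screen is therefore calibrated once with a photometer:
the luminance of a fixed hue/saturation patch is measured at HSB brightness
0, 20, 40, 60, 80 and 100 %, a second-degree polynomial is least-squares
fitted through the six points, and the fitted curve is tabulated at every
integer brightness percent (101 values).  That table *is* the luminance
scale used by the exam engine: stimulus intensity is always an integer HSB
brightness, and its physical meaning is the fitted luminance at that index.

Sensitivity is expressed in decibels of attenuation relative to the scale's
maximum stimulus luminance::

    dB = 10 * log10(L_max / L_T)

so 0 dB means the location needed the brightest stimulus the scale can
produce (or never responded), and larger dB means a dimmer stimulus was
detected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateScaleError, DomainError, InvalidInputError

#: The six HSB brightness levels (%) at which the photometer reads the screen.
CALIBRATION_BRIGHTNESS = (0, 20, 40, 60, 80, 100)


@dataclass(frozen=True)
class PhotometerMeasurement:
    """One photometer reading: luminance (cd/m²) of a patch at a given
    HSB brightness percent."""

    brightness_pct: int
    luminance: float

    def __post_init__(self) -> None:
        if self.brightness_pct not in CALIBRATION_BRIGHTNESS:
            raise InvalidInputError(
                f"calibration brightness must be one of {CALIBRATION_BRIGHTNESS}, "
                f"got {self.brightness_pct}"
            )
        if self.luminance < 0:
            raise InvalidInputError(f"luminance must be >= 0, got {self.luminance}")


@dataclass
class LuminanceScale:
    """Calibrated mapping from HSB brightness percent to luminance.

    ``coefficients`` are the fitted degree-2 polynomial coefficients in
    descending powers (as returned by :func:`numpy.polyfit`);
    ``fitted_vector`` tabulates the polynomial at brightness 0..100 %
    (negative fits clamped to zero).  ``chi2``/``p_value``/``residual_sd``
    summarise the goodness of fit at the six calibration points.
    """

    id: str
    name: str
    hue: float
    saturation: float
    coefficients: np.ndarray
    fitted_vector: np.ndarray
    chi2: float
    p_value: float
    residual_sd: float
    measurements: tuple[PhotometerMeasurement, ...] = ()
    notes: str = ""

    @property
    def l_max(self) -> float:
        """Luminance at 100 % brightness — the dB reference of this scale."""
        return float(self.fitted_vector[100])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LuminanceScale):
            return NotImplemented
        return (
            self.id == other.id
            and self.name == other.name
            and self.hue == other.hue
            and self.saturation == other.saturation
            and np.array_equal(self.coefficients, other.coefficients)
            and np.array_equal(self.fitted_vector, other.fitted_vector)
            and self.measurements == other.measurements
        )


@dataclass(frozen=True)
class DecibelValue:
    """A sensitivity value with the luminances it was derived from."""

    db: float
    l_max: float
    l_t: float


def fit_luminance_scale(
    measurements,
    *,
    id: str = "",
    name: str = "",
    hue: float = 0.0,
    saturation: float = 0.0,
    notes: str = "",
) -> LuminanceScale:
    """Least-squares fit a degree-2 polynomial through six photometer readings.

    Requires exactly one measurement at each of 0, 20, 40, 60, 80 and 100 %
    brightness.  Returns the scale with its 101-entry fitted vector and
    goodness-of-fit statistics (see :func:`goodness_of_fit`).
    """
    measurements = tuple(measurements)
    if len(measurements) != len(CALIBRATION_BRIGHTNESS):
        raise InvalidInputError(
            f"expected {len(CALIBRATION_BRIGHTNESS)} measurements, got {len(measurements)}"
        )
    by_level = {m.brightness_pct: m for m in measurements}
    if sorted(by_level) != sorted(CALIBRATION_BRIGHTNESS):
        raise InvalidInputError(
            "need exactly one measurement per brightness level "
            f"{CALIBRATION_BRIGHTNESS}, got levels {sorted(m.brightness_pct for m in measurements)}"
        )
    measurements = tuple(by_level[b] for b in CALIBRATION_BRIGHTNESS)

    b = np.asarray(CALIBRATION_BRIGHTNESS, dtype=float)
    lum = np.array([m.luminance for m in measurements], dtype=float)
    coefficients = np.polyfit(b, lum, deg=2)

    fitted_at_measured = np.polyval(coefficients, b)
    chi2, p_value, residual_sd = goodness_of_fit(lum, fitted_at_measured)

    fitted_vector = np.polyval(coefficients, np.arange(101, dtype=float))
    if np.any(fitted_vector < 0):
        warnings.warn(
            "fitted luminance is negative at low brightness; clamping to 0 cd/m²",
            stacklevel=2,
        )
        fitted_vector = np.clip(fitted_vector, 0.0, None)

    return LuminanceScale(
        id=id,
        name=name,
        hue=hue,
        saturation=saturation,
        coefficients=coefficients,
        fitted_vector=fitted_vector,
        chi2=chi2,
        p_value=p_value,
        residual_sd=residual_sd,
        measurements=measurements,
        notes=notes,
    )


def goodness_of_fit(observed, fitted) -> tuple[float, float, float]:
    """Pearson chi-square, its upper-tail p-value and the residual SD.

    ``chi2 = sum((obs - fit)**2 / fit)`` over the paired points; the p-value
    is the survival function of a chi-square distribution with ``n - 1``
    degrees of freedom (5 for the standard six-point calibration);
    ``residual_sd`` is the sample standard deviation of the residuals
    (``n - 1`` denominator), in cd/m².
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape or observed.ndim != 1 or observed.size < 2:
        raise InvalidInputError("observed and fitted must be equal-length 1-D vectors (n >= 2)")
    if np.any(fitted <= 0):
        raise DegenerateScaleError(
            "chi-square statistic undefined for non-positive fitted luminance"
        )
    chi2 = float(np.sum((observed - fitted) ** 2 / fitted))
    df = observed.size - 1
    p_value = chi_square_p_value(chi2, df)
    residual_sd = float(np.std(observed - fitted, ddof=1))
    return chi2, p_value, residual_sd


def chi_square_p_value(chi2: float, df: int = 5) -> float:
    """Upper-tail probability of a chi-square distribution at ``chi2``."""
    if chi2 < 0:
        raise DomainError(f"chi-square statistic must be >= 0, got {chi2}")
    return float(stats.chi2.sf(chi2, df))


def brightness_to_luminance(scale: LuminanceScale, brightness_pct: int) -> float:
    """Fitted luminance (cd/m²) at an integer brightness percent.

    This is a table lookup into the 101-entry fitted vector — the exam
    engine only ever uses integer brightness.  For a continuous evaluation
    of the fitted polynomial use :func:`evaluate_scale`.
    """
    idx = int(brightness_pct)
    if idx != brightness_pct or not 0 <= idx <= 100:
        raise DomainError(
            f"brightness must be an integer percent in [0, 100], got {brightness_pct!r}"
        )
    return float(scale.fitted_vector[idx])


def evaluate_scale(scale: LuminanceScale, brightness_pct: float) -> float:
    """Continuous evaluation of the fitted polynomial (convenience only;
    the engine uses the integer table via :func:`brightness_to_luminance`)."""
    if not 0 <= brightness_pct <= 100:
        raise DomainError(f"brightness must be in [0, 100], got {brightness_pct}")
    return float(np.polyval(scale.coefficients, float(brightness_pct)))


def luminance_to_db(l_t: float, l_max: float) -> float:
    """Attenuation of ``l_t`` relative to ``l_max`` in decibels:
    ``10 * log10(l_max / l_t)``.  Requires ``0 < l_t <= l_max``."""
    if l_max <= 0:
        raise DomainError(f"l_max must be > 0, got {l_max}")
    if l_t <= 0 or l_t > l_max:
        raise DomainError(f"l_t must satisfy 0 < l_t <= l_max ({l_max}), got {l_t}")
    return 10.0 * math.log10(l_max / l_t)


def db_to_luminance(db: float, l_max: float) -> float:
    """Exact inverse of :func:`luminance_to_db`: ``l_max / 10**(db / 10)``."""
    if db < 0:
        raise DomainError(f"db must be >= 0, got {db}")
    if l_max <= 0:
        raise DomainError(f"l_max must be > 0, got {l_max}")
    return l_max / 10.0 ** (db / 10.0)
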