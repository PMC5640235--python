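import random

import pytest

from campimetry.calibration import PhotometerMeasurement, fit_luminance_scale
from campimetry.engine import BrightnessSpec, ExamConfig, StimulusSpec
from campimetry.geometry import ScreenSetup


def quadratic_measurements(a=0.01, b=0.1, c=0.5):
    """Photometer readings lying exactly on a*x^2 + b*x + c."""
    return [
        PhotometerMeasurement(x, a * x * x + b * x + c) for x in (0, 20, 40, 60, 80, 100)
    ]


@pytest.fixture
def quad_scale():
    """Exact-quadratic luminance scale L(b) = 0.01 b^2 + 0.1 b + 0.5."""
    return fit_luminance_scale(quadratic_measurements(), id="S_quad", name="quad")


@pytest.fixture
def screen():
    """The validation hardware: 535 x 300 mm panel, 1920 x 1080 px, 370 mm
    viewing distance."""
    return ScreenSetup(
        width_mm=535.0, height_mm=300.0, resolution_x=1920, resolution_y=1080,
        distance_mm=370.0,
    )


@pytest.fixture
def study_config(screen):
    """The screening-test condition: ~6 degree spacing (96 locations),
    length-9 equally spread brightness vector, 1200-1600 ms ISI."""
    return ExamConfig(
        screen=screen,
        spacing_x_deg=5.98,
        spacing_y_deg=5.52,
        sphericity=True,
        stimulus=StimulusSpec(display_time_ms=200.0, isi_min_ms=1200.0, isi_max_ms=1600.0),
        brightness=BrightnessSpec(min_pct=0.0, max_pct=100.0, length=9, spread="equal"),
        seed=0,
    )


@pytest.fixture
def tiny_config(screen):
    """A 2 x 2 grid for fast closed-loop engine tests."""
    return ExamConfig(
        screen=screen,
        spacing_x_deg=36.0,
        spacing_y_deg=23.0,
        sphericity=False,
        brightness=BrightnessSpec(min_pct=0.0, max_pct=100.0, length=9),
        seed=0,
    )


@pytest.fixture
def rng():
    return random.Random(12345)
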