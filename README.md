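# campimetry

A headless engine for **flat-screen (campimetric) visual-field examination**
— the computational core of an automated-static-perimetry-style test that
runs on an ordinary monitor instead of a hemispherical perimeter bowl.
It is aimed at researchers and tool builders in visual psychophysics and
ophthalmic diagnostics who need the *testing machinery* — calibration,
geometry, adaptive thresholding, fixation monitoring, dB mapping, storage —
as an importable, fully testable library, exercised against a **simulated
observer** rather than a live patient and display.

## What it computes

**Luminance calibration.** A monitor's physical luminance is unknown to
software, so a fixed hue/saturation patch is measured with a photometer at
HSB brightness 0, 20, 40, 60, 80, 100 %. A degree-2 polynomial is
least-squares fitted and tabulated at every integer brightness (101
values); fit quality is summarised by the Pearson statistic
χ² = Σ(obs−fit)²/fit, its upper-tail p at 5 degrees of freedom, and the
sample SD of the residuals.

**Sensitivity in decibels.** As in clinical perimetry, sensitivity is the
attenuation of the detected stimulus relative to the instrument maximum,

    ΔL = 10 · log10(L_max / L_T)   [dB]

so 0 dB means no response even at maximum luminance and larger dB means a
dimmer stimulus was detected.

**Geometry.** A screen side of size *y* mm viewed from *x* mm subtends
2θ = 2·arctan(y/2x) degrees of visual angle; pixel density is R/2θ px/°.
The optional *sphericity correction* places a stimulus at eccentricity β at
the physical offset D = x·tan β mm (per axis), converted to pixels as
P = D·R/y, so that equal visual-angle steps land where they would on an
equidistant hemispherical surface.

**The *Basic* staircase.** Each grid location is searched over an
ascending brightness vector of admissible length 5+4n (9, 13, 17, …),
starting mid-vector and moving one or two steps per response while a
bracket of candidate indices shrinks; the result is the lowest brightness
answered "seen" whose predecessor was ruled out, or "no response" (0 dB).
Locations are tested in random order, a fixation check is inserted after
every 5–10 stimuli (configurable), and reliability is tracked via the
false-positive response rate FPRR = F/(F+P)·100 and per-technique fixation
accuracy (Heijl-Krakau blind-spot control and/or fixation-point change).

**Maps.** Per-location dB maps with mean / SD / variance / SEM aggregation
over repeated tests, subtraction comparison of two same-settings results,
matplotlib rendering, and re-expression of dB values against another
instrument's maximum luminance.

## Worked example

Calibrate a scale from a photometer CSV whose readings lie exactly on
L(b) = 0.01 b² + 0.1 b + 0.5, then examine a simulated stroke patient
(homonymous right hemianopia, 2 % guess rate) on a 535 × 300 mm screen at
370 mm — a 71.73° × 44.1° field with 96 stimulus locations:

```sh
$ campimetry calibrate scale.csv --name "green 534nm" --hue 100 --sat 100 --seed 1
scale S_20260924_iK2Z (green 534nm): registered in screenLuminanceScales.s
fit: chi2 = 3.277e-28, p = 1.000, SD = 1.314e-14 cd/m2
luminance range: 0.5 to 110.5 cd/m2

$ campimetry exam --config exam.sset --observer observer.json \
    --scale-csv scale.csv --patient P_20260924_demo --eye left --seed 5
result folder: Results/P_20260924_demo/R_20260924_u8jz
duration: 608.0 s
fixation accuracy (blindspot): 24/25 (96%)
fixation accuracy (point_change): 20/20 (100%)
FPRR: 4/172 (2.3%)
```

The exact-quadratic calibration fits perfectly (χ² ≈ 0, p = 1); the
simulated ten-minute exam holds fixation on nearly every check, and the
small FPRR reflects the observer's 2 % spurious-press rate. The result
folder contains the presentation log (`session.csv`), the dB map
(`map.csv`, 0 dB on the blind right half-field), a settings snapshot
(`settings.sset`), the calibration measurements (`scale.csv`) and
`summary.json` — enough to rebuild the map bit-for-bit.
`campimetry map`, `aggregate` and `compare` then render, average
(mean/SD/SD²/SEM) and subtract saved results.

The same loop is available as a library:

```python
from campimetry import ExamConfig, ScreenSetup, run_exam, build_map
from campimetry.observer import make_observer, hemianopia_truth

config = ExamConfig(screen=ScreenSetup(535, 300, 1920, 1080, 370),
                    spacing_x_deg=5.98, spacing_y_deg=5.52)
grid = config.make_grid()                      # 96 locations
observer = make_observer(grid, hemianopia_truth(grid, 10.0), seed=1)
session = run_exam(config, observer, scale, eye="left")
vf = build_map(session)                        # dB per location
```

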