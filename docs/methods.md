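# Methods

This note documents the models and procedures implemented by `campimetry`,
the parameters that matter, what the simulated observer does and does not
emulate, and the numerical/design choices made where the design was open.

## Luminance calibration

A display's HSB brightness channel (0–100 %) is calibrated against
photometer readings taken at 0, 20, 40, 60, 80 and 100 % for a fixed hue
and saturation. A degree-2 polynomial is fitted by ordinary least squares
(`numpy.polyfit`) and tabulated at all 101 integer brightness values; the
table *is* the scale — the exam engine only ever indexes it with integer
percents, and a continuous polynomial evaluation is exposed separately as
a convenience. A fit that dips below zero between calibration points
(possible for a concave fit at low brightness) is clamped to 0 cd/m² with
a warning; a fit that is non-positive *at* a calibration point is rejected
as degenerate, since the goodness-of-fit statistic is then undefined.

Goodness of fit is the Pearson chi-square over the six calibration points,
χ² = Σ(obs−fit)²/fit, with upper-tail p-value from a chi-square
distribution at **5 degrees of freedom** (six points minus one) and the
sample (n−1) standard deviation of the residuals in cd/m². The statistic's
exact form and the df are package choices: only the χ²→p mapping is
externally constrained, and df = 5 is the unique value consistent with
the reference (χ², p) pairs (1.63, 0.898) and (2.12, 0.832) that the test
suite pins.

Sensitivity arithmetic: ΔL = 10·log10(L_max/L_T) dB with exact inverse
L_T = L_max·10^(−ΔL/10). L_max is the fitted luminance at the scale's
maximum stimulus brightness. `rebase_db` re-expresses a dB value against a
different instrument's maximum (holding the threshold luminance fixed),
clipping to 0 dB when the luminance exceeds the target maximum.

## Geometry

Field extension per axis: 2θ = 2·arctan(y/2x) degrees for screen side
y mm at viewing distance x mm; pixel density R/2θ px/°. Coordinates are
degrees relative to fixation (x positive right, y positive superior);
screen pixels are top-left-origin with y downward, and the conversion
between the conventions lives in a single function.

The sphericity correction maps eccentricity β to the physical offset
D = x·tan β mm, applied independently per axis, then P = D·R/y pixels.
Because tan is convex, corrected positions sit *inside* the linear
(pixels-per-degree) placement everywhere except the screen edge, where the
two coincide; they agree to well under 1 % only when the whole screen
subtends a small angle. Eccentricities ≥ 90° are outside the model's
domain (a flat screen cannot display them).

Stimulus grids are matrix-like: per axis the count is round(extent /
spacing) (round-half-up), spaced uniformly in degrees and centred on the
fixation point. The default screening condition — 5.98° × 5.52° spacing on
a 71.73° × 44.41° nominal extent — yields a 12 × 8 = 96-location grid.
The assumed physiological blind spot is 15° temporal, 3° inferior:
(−15, −3) for the left eye, (+15, −3) for the right.

## The *Basic* staircase

Each location is searched over an ascending brightness vector from min to
max stimulus brightness, spread arithmetically ("equal") or geometrically
("logarithmic", requiring min > 0). Admissible lengths are 5+4n
(9, 13, 17, …); the default screening length is 9 and the bracketing rule
is:

* start at the middle index (length+1)/2 with candidate bracket [1, length];
* **not seen** at index i: eliminate indices ≤ i (lo := i+1); if the
  bracket empties, finish with *no response*; otherwise jump to
  min(i+2, hi);
* **seen** at index i: cap the bracket (hi := i) and step down to i−1; if
  i−1 is already eliminated, finish with threshold index i.

This reproduces the canonical trace (length 9, responses no/no/yes/yes →
presentations 5, 7, 9, 8, threshold index 8), terminates within `length`
presentations for every possible response sequence (verified exhaustively
for lengths 9 and 13), and for any observer whose "seen" set is
upward-closed returns exactly the minimum seen index — the
exhaustive-sweep answer. Non-monotone responses (seeing dim, missing
bright) are accepted as given; the procedure is deliberately unaware of
such errors, and reliability is judged downstream from FPRR and fixation
accuracy rather than corrected.

The threshold index maps through the vector to a brightness percent,
rounded to the nearest integer for the 101-entry luminance table lookup.
With the default length-9, 0–100 % vector the luminance quantisation step
is therefore one vector step (12.5 %), which bounds the estimation error
of a noiseless exam.

## Scheduling, timing and reliability indices

At every step an unfinished location is drawn uniformly at random; the
inter-stimulus interval is drawn uniformly from [isi_min, isi_max]
(default 1200–1600 ms, display time 200 ms). After every k ordinary
stimuli, with k redrawn uniformly from the configured integer interval
(default [5, 10]), one fixation check is inserted. Time is virtual — the
session clock sums display times and ISIs — so a full 96-location exam
spans a realistic ~9–10 simulated minutes while computing in milliseconds.
A presentation-layer seam (the responder interface: `respond_stimulus`,
`respond_fixation_check`, `respond_no_stimulus`) is where a real
display/keyboard front-end would plug in. Pauses add to the duration
counter (it never stops); cancelling a session discards all recorded data.

Response-window contract: permission to respond opens with a presentation
and ends with the response or the next presentation. Every press inside an
open window counts as a positive response P — the engine cannot see ground
truth, so a guess that lands in a window is indistinguishable from a
detection (and steps the staircase). A press arriving after the window has
closed counts as a false positive F. FPRR = F/(F+P)·100. The raw F and P
counts are always stored so the alternative convention F/P·100 found in
some reports can be recomputed. Fixation accuracy is correct/total checks
per technique; with technique *both*, each check draws its kind uniformly
at random and the two techniques keep separate counters, because blind-spot
checks are only meaningful when the assumed optic-disc location matches
the patient — sessions with blind-spot accuracy below 75 % are flagged
unreliable in the summary (a tooling heuristic, not a clinical standard).

## The simulated observer

The observer is the package's test harness for the whole closed loop. It
holds a ground-truth threshold luminance per location (or *blind*) and
three i.i.d. noise parameters:

* γ (`guess_rate`, default 0): probability of responding to an unseen
  stimulus, and of one spurious press in each closed-window gap;
* λ (`lapse_rate`, default 0): probability of missing a seen stimulus;
* q (`fixation_loss_prob`, default 0): probability a given fixation check
  occurs during lost fixation — the blind-spot control is then seen (the
  stimulus falls on seeing retina) and the point change is missed.

Detection is a step function of luminance (the staircase model is binary);
an optional logistic slope in dB is available but off by default. Truth
presets emulate the canonical clinical pictures: `uniform`, `hemianopia`
(one half-field blind), `tunnel` (periphery blind, as in advanced
retinitis pigmentosa) and `scotoma` (a blind patch, by default at the
physiological blind-spot location).

What the simulation does *not* emulate: temporal correlation in fixation
losses or attention, reaction times, perseverative key-holds, psychometric
slopes varying with eccentricity, refraction/media effects, and display
nonuniformity. Passing tests therefore demonstrate the correctness of the
procedure and its bookkeeping under the stated noise model, not clinical
performance on real patients.

Under this model the rate of responses to ground-truth-unseen
presentations is exactly Binomial(n, γ) — the property suite recovers
γ = 0.05 within the exact binomial 99 % acceptance region over 200 seeded
exams. The engine-level FPRR statistic has expectation γ/(1+γ) under the
spurious-press model (every false press needs a preceding closed window),
slightly below γ; both are reported.

## Maps and aggregation

A finished session maps each location to 10·log10(L_max/L_threshold) dB;
*no response* becomes 0 dB, the floor of the scale. Aggregation over n ≥ 2
repeated maps uses the sample mean, SD (n−1 denominator), variance = SD²
and SEM = SD/√n per location. Subtraction comparison of two results
requires identical settings — same location grid, brightness vector and
dB reference — and refuses anything weaker rather than rescaling silently.
Rendering draws one cell per location by default (bilinear interpolation
optional; the right smoothing for perimetric maps is a presentation
choice, not part of the model), with axes crossing at the fixation point,
ticks at 10° intervals, a white X at the blind-spot/control location and
a dB colour bar; the grayscale palette is monotone (brighter = more
sensitive).

## Storage

Registries (`patients.s`, `screenLuminanceScales.s`) are append-only
tab-delimited text databases with backslash escaping for tabs/newlines in
free text; appends write a temp file and atomically swap so prior lines
can never be corrupted. Identifiers follow `[PSR]_yyyyMMdd_xxxx` (prefix =
patient/scale/result, four random alphanumeric characters, regenerated on
collision); the date is injectable for tests. Settings templates
(`*.sset`) use a documented `key = value` format in sections (screen,
grid, stimulus, scales, procedure, fixation, keys); loading reproduces the
configuration exactly, unknown keys warn, missing sections fail.
A result folder `Results/<P-id>/<R-id>/` stores the presentation log, dB
map, settings snapshot, calibration measurements and a JSON summary;
`rebuild_map` replays the log through fresh staircases and a refitted
scale and must reproduce `map.csv` bit-for-bit.

## Problem sizes and defaults

The shipped defaults are the screening condition: 96 locations
(5.98°/5.52° spacing on the 535 × 300 mm / 370 mm geometry), length-9
equally spread 0–100 % brightness vector, 200 ms display, 1200–1600 ms
ISI, one fixation check per 5–10 stimuli, technique *both*. The
statistical properties in the test suite use 200 seeded exams at this full
size (~500 presentations each); the whole property suite completes in a
few seconds because each staircase needs at most `length` presentations.

## Known limitations

* Only the *Basic* staircase is implemented; QUEST/ZEST/full-threshold 4-2
  are extension points.
* No live display/keyboard front-end ships; the responder interface is the
  seam for one.
* The vertical extent of the validation geometry is reported as the
  tangent formula gives it (≈44.14° for 300 mm at 370 mm); grid
  construction accepts any nominal extent.
* No normative-database indices (MD, PSD, hemifield tests); comparison
  across visits is simple subtraction, and averages over repeated tests
  are the recommended basis for judging change.
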