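# goggleskit

Analysis toolkit for miniature VR headsets for head-fixed mice: the display
geometry and visual-field coverage of angle-linear eyepieces, stimulus
synthesis, video-oculography calibration and gaze estimation, V1
tuning-curve fits, hippocampal place-field analysis, and behavioral
readouts of place learning and looming-evoked defensive responses. It is
aimed at systems-neuroscience labs building or using headset-based mouse VR
who need the full computational path from display model to neural and
behavioral statistics, exercised end to end on ground-truth-labeled
synthetic data.

## What it computes

**Display geometry.** Each eyepiece presents an azimuthal-equidistant
image: viewing angle θ from the optical axis maps linearly to radial pixel
offset, px = ρ·θ with ρ = 1.57 px/deg over a 140° field of view, giving a
Nyquist limit of ρ/2 = 0.78 cycles/deg. Eyepiece footprints are spherical
caps; binocular coverage is the union/intersection of two caps along the
horizontal meridian, with Winkel tripel projections for plotting.

**Eye tracking.** The eye camera views the eye through a Fresnel lens from
a tilted angle. Eye-plane millimeters map to camera pixels through

    e' = e·(a·r² + b·r),   p = k·asin(e'/√(eₓ² + (e_y − c)² + d))

with radial-distortion terms *a, b*, tilt terms *c, d*, and an explicit
pixels-per-radian scale *k* fit from a millimeter grid. Gaze follows from
lateral pupil displacement: yaw = atan(pₓ/p_r), pitch = atan(p_y/p_r) with
p_r ≈ 1.3 mm from pupil to eyeball center.

**Neural tuning.** Stimulus-locked responses (mean inferred-spike rate in
the stimulus window minus a 2-s baseline) are fit with a rotated 2-D
Gaussian (receptive fields; RF size = mean half-width at half-maximum),
a log-Gaussian in log₂ spatial frequency, and a Naka–Rushton contrast
response R(c) = cⁿ/(cⁿ + c₅₀ⁿ), each with its goodness-of-fit gate.

**Place fields.** Spatial firing-rate maps on a 150-cm virtual track
(3-cm bins, 3-cm Gaussian smoothing, >5 cm/s speed filter), spatial
information SI = Σᵢ Pᵢ(λᵢ/λ)log₂(λᵢ/λ) in bits/spike, a 500-shuffle
circular-shift null, and 30%-of-peak field detection (widths 10–80 cm).

**Behavior.** Lick classification (post-reward bursts vs exploratory),
5-cm position bins with reward-zone preference against the 10/28 = 35.71%
chance level, probe-trial analysis, blinded startle scoring with an
exponential habituation fit, loom response metrics, and exact
Mann–Whitney U and Cuzick trend tests.

## Worked example

```sh
python examples/place_fields.py
```

```
session: 506 s, 39 laps
cell 3: PLACE SI=1.26 bits/spike (null 95th pct 0.16), peak 7.7 Hz, fields: 33-60 cm (27 wide) [true center: 47]
cell 4:   -   SI=0.03 bits/spike (null 95th pct 0.05), peak 1.1 Hz, fields: none [true center: none]
...
5/10 cells classified as place cells (5 planted). SI must beat the shuffle
95th percentile AND peak rate must reach 1 Hz.
```

Each line is one simulated CA1 cell: its spatial information score against
the 95th percentile of the circular-shift shuffle null, its rate-map peak,
and any detected fields (start–end in virtual cm) next to the planted field
center. Cells pass only if they beat the null *and* reach a 1-Hz peak, so
the five flat-firing cells are rejected while all five planted place cells
are recovered with fields covering their true centers.

Other capabilities have matching scripts in `examples/` (display coverage,
stimulus synthesis, eye-tracking calibration and gaze recovery, V1 tuning
fits, lick-based place learning, loom habituation). A thin CLI wraps the
same API, e.g.:

```sh
goggleskit fieldmap --pitch 15 --azimuth 45 --out coverage.json
goggleskit simulate place --seed 7 --out scratch/place/
goggleskit placecells --spikes scratch/place/spikes.csv --pos scratch/place/position.csv --seed 7 --out results.csv
```

## Layout

- `src/goggleskit/fieldmap.py` — display mapping, spherical footprints, coverage, projections
- `src/goggleskit/stimuli.py` — gratings, bar sweeps, loom schedule, viewport warp
- `src/goggleskit/eyetrack.py` — camera model, calibration, pupil/gaze pipeline
- `src/goggleskit/vistuning.py` — response quantification and tuning fits
- `src/goggleskit/placefield.py` — rate maps, spatial information, shuffle test, fields
- `src/goggleskit/behavior.py` — lick, startle and loom analyses; U and trend tests
- `src/goggleskit/synth.py` — seeded synthetic-data generators with ground truth
- `src/goggleskit/io.py`, `src/goggleskit/cli.py` — text formats and the CLI
- `docs/methods.md` — models, assumptions, parameters and limitations
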