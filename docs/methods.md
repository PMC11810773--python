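# Methods

This note records the models implemented in goggleskit, the assumptions
behind them, the parameters that matter, and what the synthetic-data tests
do and do not establish.

## Display geometry

The eyepiece is modeled as an ideal azimuthal-equidistant projector:
viewing angle θ (degrees from the optical axis) maps to radial pixel
offset ρ·θ, with angular resolution ρ = 1.57 px/deg and half field of view
70° by default. The display is treated as a continuous disc; pixel
quantization enters only when stimulus frames are rasterized. The Nyquist
limit is ρ/2 cycles/deg, reported with decimal round-half-even so the
default prints 0.78.

Angular coordinates are azimuth (positive to the animal's right) and
elevation (positive up), degrees at the API surface and radians
internally. An eyepiece footprint is the spherical cap of angular radius
equal to the half-FOV around the optical axis; boundaries are sampled at
1° of arc parameter by default. Cap area uses the closed form
2π(1 − cos r).

Binocular coverage is measured along the horizontal meridian at the
eyepieces' axis elevation — the small circle of constant elevation, on
which a cap of radius *h* centered at elevation *e* subtends an azimuthal
half-width acos((cos h − sin²e)/cos²e). With both axes on the equator at
±45° and h = 70°, the union spans 230° of azimuth and the caps share 50°.
The overlap along this meridian is a 1-D quantity; because published
overlap figures for such headsets depend on unstated conventions (eye
position, pupil offset), the full 2-D cap intersection in steradians is
exposed alongside it and neither is privileged. The monocular mouse field
of view is approximated as a 180°×140° ellipse in (azimuth, elevation)
coordinates centered at (±70°, 10°). Plots use the Winkel tripel
projection with standard parallel acos(2/π).

## Stimuli

Frames are 5-bit (0–31) integer images in display-pixel space; export
multiplies by 8 for 8-bit containers, optionally writing only the blue
channel (the display's spectral band that stays out of the red
eye-imaging channel). Square-wave gratings take integer pixel wavelengths
only, avoiding aliasing ambiguity; drift direction 0° is rightward motion
with angles counterclockwise, and phase advances TF·wavelength pixels per
second. Bright/dark bar pairs all average to the mid-gray 15, so mean
luminance is contrast-invariant. Michelson contrast is
100·(bright − dark)/(bright + dark), with 0/0 defined as 0%.

The receptive-field mapping stimulus is a 5×5 grid of 12-px (7.6°) cells
centered on the display; a 6×12-px bright bar sweeps each cell rightward,
downward, leftward and upward at 0.5 s per direction. The looming object
approaches at constant speed (defaults 20 m → 0.6 m at 25 m/s, ≈0.78 s);
its angular diameter is 2·atan(D/2d). The physical diameter D is not a
determined quantity and defaults to 0.5 m; all schedule invariants are
parameterized so nothing depends on D.

The reference viewport warp resamples a flat perspective rendering onto
the angle-linear display: a display pixel at angle θ samples the planar
image at radius f·tan θ, with bilinear interpolation; the inverse uses
atan. Perspective sources must have FOV < 180°, and round-trip error is
bounded by interpolation, not geometry.

## Eye tracking

The camera model takes eye-plane millimeters to camera pixels through a
radial distortion e′ = e·(a r² + b r) followed by a tilt-corrected arcsin
projection. As printed, the projection yields an angle in radians although
its output is named in pixels; since arcsin is bounded, no choice of a, b
can absorb a pixel scale, so an explicit pixels-per-radian factor k is
added and estimated during calibration. This is a deviation forced by
dimensional analysis and is the only departure from the stated form.

Calibration fits (a, b, c, d, k) to millimeter-grid correspondences by
trust-region least squares from a fixed initial point (a=0, b=1, c=0,
d=25, k=500), reporting the RMS pixel residual; collinear grids are
rejected as degenerate. Inversion (pixels to millimeters) runs a damped
Newton iteration from a radial bisection estimate, tolerance 1e-8 px,
at most 50 iterations. The forward map is quadratic — not linear — near
the origin (e′ is O(r²)), which the initializer accommodates by solving
the scalar radial problem first.

Pupil center and diameter come from the left/right pupil points only (top
and bottom are unreliable when eyelids droop); the eye center is the
eyelid left/right midpoint. Face motion is removed by subtracting
eye-center movement relative to its session median — the median was
chosen as the baseline for robustness to transients, since no reference
is otherwise determined. Frames whose required points fall below a 0.6
confidence threshold are flagged invalid rather than interpolated. Gaze
is yaw = atan(pₓ/p_r), pitch = atan(p_y/p_r) with p_r = 1.3 mm by default
(half the 3.2–3.4-mm axial length minus the 0.35–0.4-mm anterior chamber
depth); the in-plane rotation aligning x with the horizon has no stated
estimation procedure and is exposed as a calibration angle. Visual-field
mapping adds (±70°, 10°) for the eye's optical center.

## V1 tuning

Responses are mean inferred-spike rates in half-open stimulus windows
minus matched 2-s baselines, at a 3.41-Hz frame rate, averaged over
repetitions; repetitions extending past the trace are dropped. All three
fits act on max-normalized responses and are deterministic (fixed
initialization, no randomness):

- **Receptive field**: rotated 2-D Gaussian over the 5×5 grid, center
  initialized at the argmax bin, σ at one grid cell, rotation 0, center
  bounded within one grid-width of the stimulated region. The gate is
  resnorm (residual sum of squares on normalized data, dimensionless)
  < 0.25. RF size is the mean half-width at half-maximum, σ√(2 ln 2).
- **Spatial frequency**: R(SF) = exp(−(log₂SF − log₂SF_pref)²/(2σ²)),
  peak 1 at the preferred SF. The squared numerator is used: the
  unsquared form is neither symmetric in log-SF nor maximal at SF_pref.
  Gate: adjusted R² > 0.8 with 2 parameters.
- **Contrast**: R(c) = gain·cⁿ/(cⁿ + c₅₀ⁿ), c₅₀ ∈ (0, 100), n ∈ (0.1, 10),
  gain free. The gain is necessary because max-normalized data put the
  largest sample at exactly 1 while the saturating core always has
  R(100) < 1; pinning the asymptote biases recovered c₅₀ about 10% low
  on noiseless data. Gate: adjusted R² > 0.8 with 3 parameters;
  monotone-decreasing response sets are flagged unreliable.

Responses are averaged across repetitions first and normalized second.
Orientation/direction index summaries are deliberately not computed.

## Place fields

Rate maps bin position into 3-cm bins over the 150-cm track. Velocity is
computed by central differences, smoothed with a 0.25-s boxcar, and only
samples above 5 cm/s contribute to occupancy and spikes. Spike and
occupancy maps are smoothed separately with a 3-cm-s.d. Gaussian using
reflected boundaries — the track is traversed as a continuous loop with
teleportation, which breaks spatial adjacency, so no wraparound. Spatial
information uses the occupancy-weighted log₂ form with the x·log x → 0
convention; a flat map scores 0 and firing confined to one of N equal
bins scores log₂N.

The place-cell null shuffles by circular time-shift of the position
series, uniform offset ≥ 10 s, preserving position autocorrelation
(a full permutation is available behind a flag). 500 shuffles by default,
classification requires SI above the null 95th percentile and a 1-Hz peak.
Field detection takes each local maximum (strictly above both neighbors,
leftmost bin of plateaus) of at least 1 Hz, expands to the contiguous run
at ≥30% of that peak, merges runs sharing bins and keeps widths in
10–80 cm. The 1-Hz peak floor is a deliberate addition: without it,
sub-Hz background ripples seed near-zero thresholds whose runs span the
track, merge with genuine fields and are then discarded by the width cap;
reference field detectors expose the same parameter.

## Behavior

Post-reward lick bursts start at the first lick within 3 s of a reward
and extend while inter-lick intervals stay within 1 s (the operational
reading of "rate drops below 1 lick/s"); all other licks are exploratory.
Licks bin into 30 5-cm bins; the first and last are excluded because the
animal is held ≥4 cm from the walls (habitable length 1.42 m, 28 bins).
Zones span ±0.25 m (10 bins), so chance zone licking is 10/28 = 35.71%.
Probe trials are identified by the absence of any reward delivery within
the trial; note this definition is only reliable once animals lick in the
zone on rewarded trials — in an unlearned session it preferentially
selects trials without zone licks and biases zone preference downward.
The control zone defaults to the other cohort's reward location
(0.5 m ↔ 1.0 m), the only center for which both 10-bin zones are fully
habitable.

Startle scoring combines each rater's startle and tense-up confidences by
maximum, averages the two raters, and classifies scores ≥ 1.5 (boundary
inclusive) as startles; habituation is fit by
R(r) = R₁·exp(−λ(r−1)) + b with R₁, b ∈ [0, 1], λ ≥ 0. Loom response
metrics subtract a 2-s pre-onset baseline from the post-onset mean (2-s
window for velocity and eye pitch, 3 s for the slower pupil response) and
average within each consecutive set of three looms.

The Mann–Whitney U test enumerates all group assignments exactly for
combined n ≤ 20 (valid under ties) and otherwise uses the tie-corrected
normal approximation without continuity correction. Cuzick's trend test
ranks all observations jointly, weights group rank sums by ordinal scores
1..k, and uses the tie-corrected normal variance; all-identical data
return p = 0.5. Both are validated against enumeration/permutation
oracles and, for U, against an independent library implementation.

## Synthetic data

Each generator draws all randomness from `numpy.random.default_rng(seed)`
(the place-session generator uses spawned child streams so cell draws are
independent of the session build) and serializes its ground truth. Noise
models are Poisson for spikes and lick-like point processes, Gaussian for
continuous traces and landmark label noise. Defaults describe the study
conditions: the V1 protocol presents the 5×5 grid, 12 grating directions
and the 15-stimulus SF/TF/contrast battery at 5 repetitions each with 6-s
spacing; place sessions run 40 laps of the 150-cm track with a smoothed
random-walk speed profile including pauses below 5 cm/s; the lick
protocol implements the 5-day rules (days 1–2 automatic rewards, day 3+
reward-at-lick from trial 4, days 4–5 with 20% probes); loom sessions
present 15 looms in 5 sets of 3 with a pupil response decaying
exp(−rate·(set−1)) and non-habituating velocity/pitch responses.

Eye-session landmarks are placed symmetrically *in the camera image*
around the projected pupil/eye centers, as an image-space tracker would
label them. This matters: the camera model is nonlinear, so the pixel
midpoint of two millimeter-symmetric points is not the projected center;
emulating image-space labeling keeps the generator consistent with what
the pipeline estimates and lets noiseless recovery reach numerical
precision.

**What passing tests show — and what they do not.** Recovery tests show
the estimators are consistent with their own forward models at realistic
noise; null-calibration tests show the shuffle and trend tests hold their
nominal error rates. They do not certify performance on real recordings,
where tuning curves are not exactly Gaussian or Naka–Rushton, spiking is
non-Poisson, tracking errors are non-Gaussian and correlated, and
behavioral states drift. Problem sizes in the tests (tens of cells,
hundreds of shuffles, minutes-long sessions) were chosen as the smallest
that give stable statistics for the properties under test.

## Known limitations

- The linear angle-to-pixel mapping is taken as given; lens ray tracing,
  focal-depth variation and resolution falloff are out of scope.
- The binocular overlap along the meridian does not reproduce published
  "~25°" style figures whose measurement convention is unstated; both the
  1-D overlap and the 2-D intersection are reported instead.
- Pupil *diameter* through the inverse camera model carries a
  position-dependent bias of up to a few tenths of a millimeter (the
  symmetric-in-pixels edge points of an off-center pupil are not
  symmetric in millimeters); gaze angles are unaffected.
- The exact Mann–Whitney enumeration is O(C(n, n_x)) and is capped at
  combined n = 20.
- Spike sorting, calcium segmentation and pose-estimation inference are
  upstream tools whose outputs this package consumes.
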