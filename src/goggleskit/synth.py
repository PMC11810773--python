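"""Seeded synthetic-data generators with serialized ground truth.

Each generator emulates one recording modality of the headset system so
every analysis stage can be exercised end to end without real recordings:

* a V1 population presented with the full monocular stimulation protocol
  (5x5 receptive-field grid, 12 drifting-grating directions, and the
  SF/TF/contrast battery, 5 repetitions each) producing inferred-spike
  traces at the 3.41-Hz imaging frame rate;
* hippocampal place-cell spike trains over laps of the 150-virtual-cm
  linear track, with a realistic speed profile including sub-threshold
  pauses;
* lick/reward event logs following the 5-day place-learning protocol
  (days 1-2 automatic rewards, day 3+ reward-at-lick from trial 4, days
  4-5 with 20% unrewarded probe trials);
* eye-tracking point tables produced by pushing a known gaze trajectory
  through the eye geometry and the forward camera model, with common-mode
  face-motion drift and Gaussian label noise;
* loom-response time series (velocity, eye pitch, pupil) with a
  habituating pupil component.

All randomness flows from ``numpy.random.default_rng(seed)``; the same
seed reproduces the same data bit for bit, and every generator returns a
ground-truth record of the planted parameters.
"""

from __future__ import annotations

import numpy as np

from . import eyetrack
from .eyetrack import CalibrationParams, eye_to_camera
from .vistuning import FRAME_RATE_HZ

__all__ = [
    "synth_v1_population",
    "synth_place_session",
    "synth_lick_protocol",
    "synth_eye_session",
    "synth_loom_session",
    "V1_SF_WAVELENGTHS_PX",
    "V1_CONTRASTS_PERCENT",
]

# the monocular stimulation battery
V1_SF_WAVELENGTHS_PX = (4, 10, 20, 40, 80)
V1_SF_CPD = tuple(1.57 / w for w in V1_SF_WAVELENGTHS_PX)
V1_TF_HZ = (0.5, 1, 2, 4, 8, 12)
V1_CONTRASTS_PERCENT = (0, 20, 40, 60, 80, 100)
GRID_CELL_DEG = 7.6
N_REPS = 5
ITI_S = 6.0


def _protocol_schedule(rng: np.random.Generator) -> list:
    """Interleaved stimulus schedule: (stimulus_id, onset_s, duration_s).

    RF grid stimuli last 2 s, gratings 1 s, SF/TF/contrast stimuli 2 s,
    with 6 s between onsets of consecutive stimuli, repetitions in random
    order within each block.
    """
    sched = []
    t = 2.5  # leave room for the first baseline window
    for block, n_stim, dur in (
        ("rf", 25, 2.0),
        ("dir", 12, 1.0),
        ("sftc", len(V1_SF_CPD) + len(V1_TF_HZ) + len(V1_CONTRASTS_PERCENT) - 2, 2.0),
    ):
        ids = [f"{block}:{i}" for i in range(n_stim)]
        for _ in range(N_REPS):
            order = rng.permutation(len(ids))
            for j in order:
                sched.append((ids[j], t, dur))
                t += dur + ITI_S
    return sched


def synth_v1_population(
    n_cells: int = 20,
    noise_level: float = 1.0,
    seed: int = 0,
    untuned_fraction: float = 0.2,
    baseline_rate: float = 0.5,
    peak_rate: float = 12.0,
):
    """Simulate inferred-spike traces of a tuned V1 population.

    Each tuned cell has a planted 2-D Gaussian receptive field on the 5x5
    grid, a squared-log-Gaussian SF tuning curve, a Naka-Rushton contrast
    curve and a von Mises direction preference; a stated fraction of cells
    are untuned (flat response).  Spiking is Poisson per imaging frame at
    3.41 Hz, scaled by ``noise_level`` = 1 for plain Poisson counts
    (``noise_level`` = 0 returns the noiseless expected trace).

    Returns ``(traces, onsets, truth)``: traces (n_cells x n_frames),
    onsets mapping stimulus id -> onset times, and the ground truth.
    """
    rng = np.random.default_rng(seed)
    sched = _protocol_schedule(rng)
    t_end = sched[-1][1] + 8.0
    n_frames = int(np.ceil(t_end * FRAME_RATE_HZ))
    frame_t = np.arange(n_frames) / FRAME_RATE_HZ

    truth_cells = []
    rates = np.full((n_cells, n_frames), baseline_rate)
    n_sf = len(V1_SF_CPD)
    n_tf = len(V1_TF_HZ)
    for ci in range(n_cells):
        untuned = rng.random() < untuned_fraction
        # planted tuning parameters
        cx, cy = rng.uniform(-GRID_CELL_DEG, GRID_CELL_DEG, 2)
        sigma = rng.uniform(5.0, 10.0)
        sf_pref = float(np.exp(rng.uniform(np.log(0.02), np.log(0.09))))
        sf_sigma = rng.uniform(1.0, 2.5)
        c50 = rng.uniform(20.0, 45.0)
        n_exp = rng.uniform(1.5, 3.0)
        dir_pref = rng.uniform(0, 360)
        truth_cells.append(
            dict(
                cell=ci,
                untuned=bool(untuned),
                rf_center_deg=(float(cx), float(cy)),
                rf_sigma_deg=float(sigma),
                sf_pref_cpd=sf_pref,
                sf_sigma_log2=float(sf_sigma),
                c50_percent=float(c50),
                naka_n=float(n_exp),
                dir_pref_deg=float(dir_pref),
            )
        )
        for sid, onset, dur in sched:
            block, idx = sid.split(":")
            idx = int(idx)
            if untuned:
                gain = 0.0
            elif block == "rf":
                row, col = divmod(idx, 5)
                gx = (col - 2) * GRID_CELL_DEG
                gy = (2 - row) * GRID_CELL_DEG
                gain = np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sigma**2))
            elif block == "dir":
                ang = np.radians(idx * 30 - dir_pref)
                gain = np.exp(2.0 * (np.cos(ang) - 1))
            else:
                # SF/TF/contrast battery: 5 SFs at 100% contrast, 5
                # non-default TFs, 5 non-default contrasts at the default
                # 12.7-deg SF (100% contrast is the default grating itself)
                def sf_gain(cpd):
                    lr = np.log2(cpd) - np.log2(sf_pref)
                    return np.exp(-(lr**2) / (2 * sf_sigma**2))

                nr = lambda c: c**n_exp / (c**n_exp + c50**n_exp) if c > 0 else 0.0
                default_sf = 1.57 / 20
                if idx < n_sf:
                    gain = sf_gain(V1_SF_CPD[idx]) * nr(100)
                elif idx < n_sf + (n_tf - 1):
                    gain = sf_gain(default_sf) * nr(100)  # TF tuning flat
                else:
                    c = (0, 20, 40, 60, 80)[idx - n_sf - (n_tf - 1)]
                    gain = sf_gain(default_sf) * nr(c)
            win = (frame_t >= onset) & (frame_t < onset + dur)
            rates[ci, win] = baseline_rate + peak_rate * gain

    if noise_level == 0:
        traces = rates / FRAME_RATE_HZ
    else:
        traces = rng.poisson(noise_level * rates / FRAME_RATE_HZ) / max(noise_level, 1e-12)
    onsets: dict = {}
    durations: dict = {}
    for sid, onset, dur in sched:
        onsets.setdefault(sid, []).append(onset)
        durations[sid] = dur
    onsets = {k: np.array(v) for k, v in onsets.items()}
    truth = dict(seed=seed, noise_level=noise_level, cells=truth_cells,
                 baseline_rate=baseline_rate, peak_rate=peak_rate,
                 frame_rate_hz=FRAME_RATE_HZ, durations=durations)
    return traces.astype(float), onsets, truth


def v1_rf_grid_ids() -> list:
    """Stimulus ids of the 5x5 receptive-field grid, row-major."""
    return [f"rf:{i}" for i in range(25)]


def v1_sf_curve() -> tuple[list, tuple]:
    """(stimulus ids, spatial frequencies in c.p.d.) of the SF battery."""
    return [f"sftc:{i}" for i in range(5)], V1_SF_CPD


def v1_contrast_curve() -> tuple[list, tuple]:
    """(stimulus ids, contrast percents) of the contrast battery; the 100%
    point is the default grating, which is stimulus sftc:2 (12.7-deg SF)."""
    ids = [f"sftc:{10 + i}" for i in range(5)] + ["sftc:2"]
    return ids, (0, 20, 40, 60, 80, 100)


def _lap_speed_profile(rng, n_samples, mean_speed=15.0, pause_prob=0.004):
    """Smoothed random-walk speed with enforced pause epochs (< 5 cm/s)."""
    v = np.full(n_samples, mean_speed) + np.cumsum(rng.normal(0, 0.8, n_samples))
    v = np.clip(v, 6.0, 35.0)
    i = 0
    while i < n_samples:
        if rng.random() < pause_prob:
            pause_len = rng.integers(30, 120)
            v[i : i + pause_len] = rng.uniform(0.0, 3.0)
            i += pause_len
        i += 1
    return v


def synth_place_session(
    n_cells: int = 30,
    n_laps: int = 40,
    track_cm: float = 150.0,
    seed: int = 0,
    place_fraction: float = 0.4,
    dt_s: float = 0.02,
    peak_rate_hz: float = 8.0,
    background_rate_hz: float = 0.3,
):
    """Simulate a linear-track session: positions plus Poisson spike trains.

    A ``place_fraction`` of cells carry a Gaussian place field (centers
    uniform on the track, widths drawn so the 30%-of-peak field spans
    10-80 cm); the rest fire at a constant non-spatial rate.  The running
    profile includes pauses below the 5-cm/s analysis threshold.

    Returns ``(spike_times_by_cell, t_s, pos_cm, truth)``.
    """
    # independent streams: changing the session build never reshuffles cells
    rng, rng_cells = np.random.default_rng(seed).spawn(2)
    # build position series lap by lap
    pos_chunks = []
    while sum(len(c) for c in pos_chunks) * dt_s < n_laps * 16.0:
        n = 2000
        v = _lap_speed_profile(rng, n)
        pos_chunks.append(v)
        if len(pos_chunks) > 400:
            break
    speed = np.concatenate(pos_chunks)
    pos = np.mod(np.cumsum(speed) * dt_s, track_cm)
    # truncate at n_laps teleports
    wraps = np.where(np.diff(pos) < -track_cm / 2)[0]
    if len(wraps) >= n_laps:
        end = wraps[n_laps - 1] + 1
        pos = pos[:end]
        speed = speed[:end]
    t_s = np.arange(len(pos)) * dt_s

    spikes_by_cell = []
    truth_cells = []
    for ci in range(n_cells):
        rng = rng_cells.spawn(1)[0]  # per-cell stream
        is_place = rng.random() < place_fraction
        if is_place:
            center = rng.uniform(10, track_cm - 10)
            sigma = rng.uniform(3.0, 15.0)
            d = np.minimum(np.abs(pos - center), track_cm - np.abs(pos - center))
            rate = background_rate_hz + peak_rate_hz * np.exp(-(d**2) / (2 * sigma**2))
        else:
            center, sigma = np.nan, np.nan
            rate = np.full_like(pos, background_rate_hz + peak_rate_hz * 0.05)
        counts = rng.poisson(rate * dt_s)
        spike_times = np.repeat(t_s, counts) + rng.uniform(0, dt_s, counts.sum())
        spikes_by_cell.append(np.sort(spike_times))
        truth_cells.append(
            dict(cell=ci, is_place_cell=bool(is_place),
                 field_center_cm=float(center), field_sigma_cm=float(sigma))
        )
    truth = dict(seed=seed, n_laps=n_laps, track_cm=track_cm,
                 place_fraction=place_fraction, peak_rate_hz=peak_rate_hz,
                 background_rate_hz=background_rate_hz, cells=truth_cells)
    return spikes_by_cell, t_s, pos, truth


def synth_lick_protocol(
    cohort: str = "A",
    learning_rate: float = 0.5,
    seed: int = 0,
    n_trials: int = 40,
    dt_s: float = 0.05,
):
    """Simulate 5 days of place-learning event logs for one mouse.

    The reward zone center is 0.5 m (cohort A) or 1.0 m (cohort B).
    Days 1-2 deliver the reward automatically at the reward location; from
    day 3, trials 4+ require a lick inside the +/-0.25-m zone before the
    reward is delivered at the lick location; days 4-5 mark a random 20%
    of trials as unrewarded probes.  Exploratory licking concentrates in
    the reward zone with day as 'chance + (1 - chance) * (1 -
    exp(-learning_rate * (day - 1)))'; ``learning_rate`` = 0 keeps zone
    licking at the 10/28 chance level.

    Returns a list of 5 day-records with events (t_s, event, value),
    position series and trial bounds, plus the ground truth.
    """
    if cohort not in ("A", "B"):
        raise ValueError("cohort must be 'A' or 'B'")
    rng = np.random.default_rng(seed)
    zone_center = 0.5 if cohort == "A" else 1.0
    chance = 10 / 28
    days = []
    for day in range(1, 6):
        p_zone = chance + (1 - chance) * (1 - np.exp(-learning_rate * (day - 1)))
        events = []  # (t, name, value)
        t_list, pos_list, bounds = [], [], []
        probe_flags = []
        t = 0.0
        for trial in range(1, n_trials + 1):
            is_probe = day >= 4 and rng.random() < 0.2
            probe_flags.append(bool(is_probe))
            # constant-ish speed traversal 0.04 -> 1.46 m
            dur = rng.uniform(8.0, 20.0)
            n = int(dur / dt_s)
            tt = t + np.arange(n) * dt_s
            pp = 0.04 + (1.46 - 0.04) * np.arange(n) / (n - 1)
            t_list.append(tt)
            pos_list.append(pp)
            events.append((t, "trial_start", trial))
            rewarded = False
            # exploratory licking along the trial
            n_exp_licks = rng.poisson(6)
            for _ in range(n_exp_licks):
                if rng.random() < p_zone:
                    lick_pos = np.clip(rng.uniform(zone_center - 0.25, zone_center + 0.25), 0.05, 1.45)
                else:
                    lick_pos = rng.uniform(0.05, 1.45)
                    # outside-zone rejection keeps the zone fraction at p_zone
                    while abs(lick_pos - zone_center) <= 0.25:
                        lick_pos = rng.uniform(0.05, 1.45)
                lick_t = t + (lick_pos - 0.04) / (1.46 - 0.04) * dur
                events.append((lick_t, "lick", lick_pos))
                # reward-at-lick rule, day 3+, trials 4+
                if (
                    not rewarded
                    and not is_probe
                    and day >= 3
                    and trial >= 4
                    and abs(lick_pos - zone_center) <= 0.25
                ):
                    events.append((lick_t + 0.01, "reward", lick_pos))
                    rewarded = True
            # automatic reward when crossing the reward location
            if not is_probe and not rewarded and (day <= 2 or trial <= 3):
                t_rw = t + (zone_center - 0.04) / (1.46 - 0.04) * dur
                events.append((t_rw, "reward", zone_center))
                rewarded = True
            if rewarded:
                # post-reward lick burst: starts within 3 s, inter-lick < 1 s
                rt = [e[0] for e in events if e[1] == "reward" and e[0] >= t][-1]
                burst_t = rt + rng.uniform(0.2, 1.0)
                for _ in range(rng.integers(3, 8)):
                    events.append((burst_t, "lick", np.interp(burst_t, tt, pp)))
                    burst_t += rng.uniform(0.15, 0.5)
            events.append((t + dur, "trial_end", trial))
            bounds.append((t, t + dur))
            t += dur + 1.0
        events.sort(key=lambda e: e[0])
        days.append(
            dict(
                day=day,
                events=events,
                t_s=np.concatenate(t_list),
                pos_m=np.concatenate(pos_list),
                trial_bounds_s=bounds,
                probe_flags=probe_flags,
            )
        )
    truth = dict(seed=seed, cohort=cohort, zone_center_m=zone_center,
                 learning_rate=learning_rate, chance=chance)
    return days, truth


def synth_eye_session(
    calib: CalibrationParams | None = None,
    n_frames: int = 300,
    label_noise_px: float = 0.0,
    seed: int = 0,
    p_r_mm: float = eyetrack.PUPIL_RADIUS_MM,
    drift_amp_px: float = 0.0,
    fps: float = 30.0,
):
    """Simulate labeled eye-tracking point tables from a known gaze path.

    A smooth yaw/pitch trajectory is converted to pupil offsets via the
    eye geometry (p = p_r * tan(angle)), placed on the eye plane around a
    fixed eye center, pushed through the forward camera model, and offset
    by a shared sinusoidal face-motion drift (``drift_amp_px``) plus
    Gaussian label noise.  Returns ``(frames, truth)`` where frames is a
    list of :class:`~goggleskit.eyetrack.EyeFramePoints`.
    """
    rng = np.random.default_rng(seed)
    if calib is None:
        calib = CalibrationParams(a=0.02, b=0.9, c=0.4, d=20.0, k=420.0)
    t = np.arange(n_frames) / fps
    yaw = 8.0 * np.sin(2 * np.pi * 0.11 * t)
    pitch = 5.0 * np.sin(2 * np.pi * 0.07 * t + 1.0)
    diam_mm = 0.9 + 0.1 * np.sin(2 * np.pi * 0.03 * t)

    eye_center_mm = np.array([0.3, 0.2])
    drift = drift_amp_px * np.column_stack(
        [np.sin(2 * np.pi * 0.23 * t), np.cos(2 * np.pi * 0.19 * t)]
    )

    frames = []
    # eyelid landmarks sit symmetrically around the eye center in the
    # camera image, so their pixel midpoint is the projected eye center
    eye_center_px = eye_to_camera(eye_center_mm, calib)
    eyelid_offsets_px = {
        "eyelid_left": np.array([-160.0, 0.0]),
        "eyelid_right": np.array([160.0, 0.0]),
        "eyelid_top": np.array([0.0, 110.0]),
        "eyelid_bottom": np.array([0.0, -110.0]),
    }
    for i in range(n_frames):
        p_off = p_r_mm * np.tan(np.radians([yaw[i], pitch[i]]))
        center_mm = eye_center_mm + p_off
        # landmarks are labeled in the image: edge points sit symmetrically
        # in pixel space around the projected pupil center
        center_px = eye_to_camera(center_mm, calib)
        wx = np.linalg.norm(
            eye_to_camera(center_mm + [diam_mm[i] / 2, 0], calib)
            - eye_to_camera(center_mm - [diam_mm[i] / 2, 0], calib)
        )
        wy = np.linalg.norm(
            eye_to_camera(center_mm + [0, diam_mm[i] / 2], calib)
            - eye_to_camera(center_mm - [0, diam_mm[i] / 2], calib)
        )
        pts = {}
        for name, off_px in (
            ("pupil_left", np.array([-wx / 2, 0.0])),
            ("pupil_right", np.array([wx / 2, 0.0])),
            ("pupil_top", np.array([0.0, wy / 2])),
            ("pupil_bottom", np.array([0.0, -wy / 2])),
        ):
            pts[name] = tuple(
                center_px + off_px + drift[i] + rng.normal(0, label_noise_px, 2)
            )
        for name, off_px in eyelid_offsets_px.items():
            pts[name] = tuple(
                eye_center_px + off_px + drift[i] + rng.normal(0, label_noise_px, 2)
            )
        frames.append(
            eyetrack.EyeFramePoints(points=pts, confidence={n: 1.0 for n in pts})
        )
    truth = dict(
        seed=seed,
        yaw_deg=yaw,
        pitch_deg=pitch,
        diameter_mm=diam_mm,
        eye_center_mm=eye_center_mm.tolist(),
        label_noise_px=label_noise_px,
        drift_amp_px=drift_amp_px,
        p_r_mm=p_r_mm,
        calib=dict(a=calib.a, b=calib.b, c=calib.c, d=calib.d, k=calib.k),
        fps=fps,
    )
    return frames, truth


def synth_loom_session(
    habituation_rate: float = 0.4,
    seed: int = 0,
    n_sets: int = 5,
    set_size: int = 3,
    fps: float = 30.0,
    iti_s: float = 10.0,
    velocity_drop: float = -8.0,
    pitch_shift: float = 4.0,
    pupil_amp_mm: float = 0.15,
    noise: float = 0.15,
):
    """Simulate loom-response time series for one animal.

    15 looms in 5 sets of 3 (left/right/center).  Velocity shows a
    transient non-habituating drop, eye pitch a non-habituating upward
    shift, and pupil diameter a dilation whose amplitude decays by
    ``exp(-habituation_rate * (set - 1))`` across sets.  Gaussian noise is
    added to all three series.

    Returns ``(t_s, series, onsets_s, truth)`` with series keys
    'velocity', 'pitch', 'pupil'.
    """
    rng = np.random.default_rng(seed)
    n_looms = n_sets * set_size
    onsets = 5.0 + np.arange(n_looms) * iti_s
    t_end = onsets[-1] + 8.0
    t = np.arange(0, t_end, 1.0 / fps)

    vel = np.full_like(t, 12.0)
    pitch = np.zeros_like(t)
    pupil = np.full_like(t, 1.0)
    for i, onset in enumerate(onsets):
        s = i // set_size
        resp = (t >= onset) & (t < onset + 2.0)
        vel[resp] += velocity_drop
        pitch[resp] += pitch_shift
        decay = np.exp(-habituation_rate * s)
        pup_win = (t >= onset) & (t < onset + 3.0)
        # slow pupil transient: ramp up then hold over 3 s
        tau = (t[pup_win] - onset) / 3.0
        pupil[pup_win] += pupil_amp_mm * decay * np.minimum(1.0, 3 * tau)
    vel += rng.normal(0, noise * 8, len(t))
    pitch += rng.normal(0, noise * 4, len(t))
    pupil += rng.normal(0, noise * 0.1, len(t))
    series = {"velocity": vel, "pitch": pitch, "pupil": pupil}
    truth = dict(seed=seed, habituation_rate=habituation_rate,
                 velocity_drop=velocity_drop, pitch_shift=pitch_shift,
                 pupil_amp_mm=pupil_amp_mm, noise=noise,
                 n_sets=n_sets, set_size=set_size)
    return t, series, onsets, truth
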