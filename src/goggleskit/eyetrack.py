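"""Video-oculography: camera calibration, pupil extraction and gaze.

The eye camera views the eye through a Fresnel lens from a tilted angle, so
positions (e_x, e_y) in millimeters on the eye plane map to camera pixels
through a radial-distortion + tilt model:

    e'   = e * (a*r^2 + b*r),          r = sqrt(e_x^2 + e_y^2)
    p_x  = k * asin(e'_x / sqrt(e_x^2 + (e_y - c)^2 + d))
    p_y  = k * asin(e'_y / sqrt(e_x^2 + (e_y - c)^2 + d))

with a, b the radial distortion coefficients, c, d the tilt offsets, and k
an explicit pixels-per-radian output scale (the arcsin is an angle; a pixel
scale cannot be absorbed into a or b because arcsin is bounded).

Gaze is inferred from lateral pupil displacement: the pupil sits at radial
distance p_r from the eyeball center (default 1.3 mm, from a 3.2-3.4 mm
axial length minus 0.35-0.4 mm anterior chamber depth, halved), so a pupil
offset p gives yaw = atan(p_x / p_r) and pitch = atan(p_y / p_r).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CalibrationParams",
    "EyeFramePoints",
    "GazeSample",
    "eye_to_camera",
    "camera_to_eye",
    "fit_calibration",
    "pupil_state",
    "motion_correct",
    "pupil_to_gaze",
    "gaze_to_field",
    "gaze_pipeline",
    "PUPIL_RADIUS_MM",
]

PUPIL_RADIUS_MM = 1.3


def pupil_radius_from_geometry(
    axial_length_mm: float = 3.3, anterior_chamber_mm: float = 0.375
) -> float:
    """Pupil-to-eyeball-center distance from eye geometry.

    Half the axial length (eyeball center) minus the anterior chamber
    depth (pupil plane).  Mouse defaults: axial length 3.2-3.4 mm and
    anterior chamber 0.35-0.4 mm give ~1.3 mm.
    """
    return axial_length_mm / 2.0 - anterior_chamber_mm

POINT_NAMES = (
    "pupil_left",
    "pupil_right",
    "pupil_top",
    "pupil_bottom",
    "eyelid_left",
    "eyelid_right",
    "eyelid_top",
    "eyelid_bottom",
)


@dataclass(frozen=True)
class CalibrationParams:
    """Eye-plane-mm to camera-px model parameters.

    a, b: radial lens distortion; c, d: camera tilt offsets;
    k: output scale in pixels per radian; horizon_deg: in-plane rotation
    aligning the camera x axis with the visual horizon.
    """

    a: float
    b: float
    c: float
    d: float
    k: float
    horizon_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("scale k must be positive")
        if self.d <= 0:
            raise ValueError("tilt offset d must be positive (it sits under a sqrt)")


def eye_to_camera(e, params: CalibrationParams) -> np.ndarray:
    """Forward model: eye-plane (e_x, e_y) in mm to camera (p_x, p_y) px.

    Raises ``ValueError`` if the arcsin argument leaves [-1, 1] (point
    outside the model's valid domain).
    """
    e = np.asarray(e, dtype=float)
    single = e.ndim == 1
    e2 = np.atleast_2d(e)
    ex, ey = e2[:, 0], e2[:, 1]
    r2 = ex**2 + ey**2
    r = np.sqrt(r2)
    g = params.a * r2 + params.b * r
    denom = np.sqrt(ex**2 + (ey - params.c) ** 2 + params.d)
    args = np.column_stack([ex * g, ey * g]) / denom[:, None]
    bad = np.abs(args) > 1
    if np.any(bad):
        idx = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise ValueError(f"arcsin argument out of range for point index {idx}: {e2[idx]}")
    p = params.k * np.arcsin(args)
    return p[0] if single else p


def _radial_forward(rho: float, params: CalibrationParams) -> float:
    """|p| for a point at radius rho along +x with c-term ignored."""
    g = params.a * rho**2 + params.b * rho
    arg = rho * g / np.sqrt(rho**2 + params.d)
    if abs(arg) > 1:
        return np.inf  # outside the model's valid domain
    return params.k * np.arcsin(arg)


def camera_to_eye(
    p,
    params: CalibrationParams,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> np.ndarray:
    """Invert the forward model numerically: camera px to eye-plane mm.

    Deterministic damped Newton iteration started from a radial bisection
    estimate; converges to ||forward(e) - p|| below ``tol`` px or raises
    ``RuntimeError``.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim == 1:
        return _invert_one(p, params, tol, max_iter)
    return np.array([_invert_one(pi, params, tol, max_iter) for pi in p])


def _invert_one(p, params, tol, max_iter) -> np.ndarray:
    pn = float(np.hypot(p[0], p[1]))
    if pn < tol:
        return np.zeros(2)
    # radial initial guess: solve the c=0 scalar problem by bisection
    hi = 1.0
    while _radial_forward(hi, params) < pn and hi < 1e3:
        hi *= 2.0
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _radial_forward(mid, params) < pn:
            lo = mid
        else:
            hi = mid
    e = 0.5 * (lo + hi) * p / pn

    # damped Newton on the full 2-D model with numeric Jacobian
    h = 1e-7
    for _ in range(max_iter):
        f = eye_to_camera(e, params) - p
        if np.hypot(*f) < tol:
            return e
        jac = np.empty((2, 2))
        for j in range(2):
            de = np.zeros(2)
            de[j] = h
            jac[:, j] = (eye_to_camera(e + de, params) - eye_to_camera(e - de, params)) / (2 * h)
        try:
            step = np.linalg.solve(jac, f)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular Jacobian during inversion") from exc
        lam = 1.0
        base = np.hypot(*f)
        for _ in range(20):
            trial = e - lam * step
            try:
                ft = eye_to_camera(trial, params) - p
            except ValueError:
                lam *= 0.5
                continue
            if np.hypot(*ft) < base:
                e = trial
                break
            lam *= 0.5
        else:
            raise RuntimeError("inversion line search failed")
    f = eye_to_camera(e, params) - p
    if np.hypot(*f) < tol:
        return e
    raise RuntimeError(f"inversion did not converge for {p} (residual {np.hypot(*f):.2e})")


def fit_calibration(
    grid_mm: np.ndarray,
    observed_px: np.ndarray,
    x0: CalibrationParams | None = None,
) -> tuple[CalibrationParams, float]:
    """Least-squares fit of (a, b, c, d, k) from grid correspondences.

    ``grid_mm`` are known millimeter positions of gridline intersections on
    the eye plane, ``observed_px`` their camera pixel coordinates.  Returns
    the fitted parameters and the forward-model RMS residual in pixels.
    Deterministic: fixed initialization, no randomness.
    """
    grid_mm = np.asarray(grid_mm, dtype=float)
    observed_px = np.asarray(observed_px, dtype=float)
    if len(grid_mm) < 5:
        raise ValueError("need at least 5 correspondences")
    # collinear grids leave the 2-D tilt/distortion model unconstrained
    centered = grid_mm - grid_mm.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) calibration geometry")

    if x0 is None:
        x0 = CalibrationParams(a=0.0, b=1.0, c=0.0, d=25.0, k=500.0)

    def resid(theta):
        a, b, c, d, k = theta
        params = CalibrationParams(a=a, b=b, c=c, d=max(d, 1e-6), k=max(k, 1e-6))
        try:
            pred = eye_to_camera(grid_mm, params)
        except ValueError:
            return np.full(observed_px.size, 1e6)
        return (pred - observed_px).ravel()

    sol = least_squares(
        resid,
        x0=[x0.a, x0.b, x0.c, x0.d, x0.k],
        bounds=([-10, -10, -10, 1e-6, 1e-3], [10, 10, 10, 1e4, 1e5]),
        method="trf",
    )
    a, b, c, d, k = sol.x
    params = CalibrationParams(a=a, b=b, c=c, d=d, k=k)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return params, rms


@dataclass
class EyeFramePoints:
    """Tracked landmark coordinates of one video frame.

    ``points`` maps each of the eight landmark names (pupil/eyelid x
    left/right/top/bottom) to (x, y) pixel coordinates; ``confidence`` maps
    names to tracking likelihoods in [0, 1].
    """

    points: dict
    confidence: dict = field(default_factory=dict)

    def conf(self, name: str) -> float:
        return float(self.confidence.get(name, 1.0))


@dataclass(frozen=True)
class GazeSample:
    """Eye rotation and pupil size for one frame."""

    yaw_deg: float
    pitch_deg: float
    diameter_mm: float
    valid: bool = True


def extract_eye_roi(rgb_frame: np.ndarray, center_xy, size: int = 500) -> np.ndarray:
    """Crop a square region of interest around the eye and keep the red
    channel (the display emits blue/green, so red isolates the IR image)."""
    img = np.asarray(rgb_frame)
    red = img[..., 0] if img.ndim == 3 else img
    cx, cy = (int(round(v)) for v in center_xy)
    h = size // 2
    x0, y0 = max(cx - h, 0), max(cy - h, 0)
    return red[y0 : y0 + size, x0 : x0 + size]


REQUIRED_POINTS = ("pupil_left", "pupil_right", "eyelid_left", "eyelid_right")


def pupil_state(
    frame: EyeFramePoints, confidence_threshold: float = 0.6
) -> dict:
    """Pupil center, diameter, and eye center (all px) from labeled points.

    The pupil center is the midpoint of the pupil left/right points and the
    diameter their separation; top and bottom pupil points are ignored
    (they are unreliable when the eyelids partly close).  The eye center is
    the eyelid left/right midpoint.  Frames whose required points fall
    below the confidence threshold are flagged invalid, not dropped.
    """
    missing = [n for n in REQUIRED_POINTS if n not in frame.points]
    low_conf = [n for n in REQUIRED_POINTS if frame.conf(n) < confidence_threshold]
    if missing or low_conf:
        return {"valid": False, "missing": missing, "low_confidence": low_conf}
    pl = np.asarray(frame.points["pupil_left"], dtype=float)
    pr = np.asarray(frame.points["pupil_right"], dtype=float)
    el = np.asarray(frame.points["eyelid_left"], dtype=float)
    er = np.asarray(frame.points["eyelid_right"], dtype=float)
    return {
        "valid": True,
        "pupil_center_px": (pl + pr) / 2.0,
        "pupil_diameter_px": float(np.linalg.norm(pl - pr)),
        "eye_center_px": (el + er) / 2.0,
    }


def motion_correct(
    pupil_centers: np.ndarray,
    eye_centers: np.ndarray,
    baseline: np.ndarray | None = None,
) -> np.ndarray:
    """Remove common-mode face motion from the pupil track.

    corrected_t = pupil_t - (eyecenter_t - baseline); the baseline defaults
    to the session median of the eye center (robust to transients).
    """
    pupil_centers = np.asarray(pupil_centers, dtype=float)
    eye_centers = np.asarray(eye_centers, dtype=float)
    if pupil_centers.shape != eye_centers.shape:
        raise ValueError("pupil and eye center series must be aligned")
    if baseline is None:
        baseline = np.median(eye_centers, axis=0)
    return pupil_centers - (eye_centers - np.asarray(baseline, dtype=float))


def pupil_to_gaze(
    p_mm,
    p_r: float = PUPIL_RADIUS_MM,
    diameter_mm: float = 0.0,
    horizon_deg: float = 0.0,
) -> GazeSample:
    """Convert a lateral pupil offset (mm, relative to the eye center) to
    eye yaw and pitch.

    yaw = atan(p_x / p_r), pitch = atan(p_y / p_r) with p_r the pupil-to-
    eyeball-center distance; the offset is first rotated by ``horizon_deg``
    so x follows the visual horizon.
    """
    p = np.asarray(p_mm, dtype=float)
    if horizon_deg:
        th = np.radians(horizon_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        p = rot @ p
    yaw = np.degrees(np.arctan2(p[0], p_r))
    pitch = np.degrees(np.arctan2(p[1], p_r))
    return GazeSample(yaw_deg=float(yaw), pitch_deg=float(pitch), diameter_mm=float(diameter_mm))


def gaze_to_field(g: GazeSample, side: str) -> tuple[float, float]:
    """Map a gaze sample onto visual-field coordinates.

    The eyes' optical centers sit at +/-70 degrees azimuth and 10 degrees
    elevation; gaze adds to that pose (azimuth sign set by ``side``).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    sign = 1.0 if side == "right" else -1.0
    return (sign * 70.0 + g.yaw_deg, 10.0 + g.pitch_deg)


def gaze_pipeline(
    frames: list[EyeFramePoints],
    params: CalibrationParams,
    p_r: float = PUPIL_RADIUS_MM,
    confidence_threshold: float = 0.6,
) -> list[GazeSample]:
    """Full per-session gaze pipeline from labeled points.

    Extracts pupil/eye centers, motion-corrects the pupil track in pixels,
    converts to eye-plane millimeters through the inverse camera model
    (relative to the session-median eye center), and maps pupil offsets to
    yaw/pitch.  Invalid frames propagate as invalid samples.
    """
    states = [pupil_state(f, confidence_threshold) for f in frames]
    valid = np.array([s["valid"] for s in states])
    if not valid.any():
        return [GazeSample(np.nan, np.nan, np.nan, valid=False) for _ in states]
    pupils = np.array([s["pupil_center_px"] if s["valid"] else (np.nan, np.nan) for s in states])
    eyes = np.array([s["eye_center_px"] if s["valid"] else (np.nan, np.nan) for s in states])
    baseline = np.nanmedian(eyes, axis=0)
    corrected = pupils - (eyes - baseline)

    eye_center_mm = camera_to_eye(baseline, params)
    out = []
    for s, pc in zip(states, corrected):
        if not s["valid"]:
            out.append(GazeSample(np.nan, np.nan, np.nan, valid=False))
            continue
        p_mm = camera_to_eye(pc, params) - eye_center_mm
        # pupil diameter px -> mm via the local scale of the inverse map
        pl = camera_to_eye(pc + [s["pupil_diameter_px"] / 2, 0], params)
        pr_pt = camera_to_eye(pc - [s["pupil_diameter_px"] / 2, 0], params)
        diam_mm = float(np.linalg.norm(pl - pr_pt))
        out.append(pupil_to_gaze(p_mm, p_r=p_r, diameter_mm=diam_mm, horizon_deg=params.horizon_deg))
    return out
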