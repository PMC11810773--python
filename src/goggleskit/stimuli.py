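"""Visual stimulus synthesis and the reference viewport warp.

Stimuli are generated as stacks of 5-bit integer frames (pixel values
0..31) in the pixel space of the circular angle-linear display: drifting
square-wave gratings, a four-direction bar-sweep grid for receptive-field
mapping, and the distance/angular-size schedule of a looming object.  A CPU
reference warp converts between a flat perspective-rendered viewport and
the angle-linear display image (the job done by the rendering shaders in
the real headset).

5-bit frames export to 8-bit by multiplying by 8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .fieldmap import DisplayMapping

__all__ = [
    "GratingSpec",
    "LoomSpec",
    "michelson_contrast",
    "sf_px_to_cpd",
    "grating_frames",
    "bar_sweep_stimulus",
    "loom_schedule",
    "warp_viewport",
    "unwarp_viewport",
    "CONTRAST_PAIRS",
]

MID_GRAY = 15

#: the six 5-bit bright/dark bar pairs used for contrast tuning
CONTRAST_PAIRS = [(15, 15), (18, 12), (21, 9), (24, 6), (27, 3), (30, 0)]


@dataclass(frozen=True)
class GratingSpec:
    """Square-wave drifting grating in display-pixel space.

    ``wavelength_px`` is the spatial period (pixels per cycle; integer),
    ``direction_deg`` the drift direction (0 = rightward motion, counter-
    clockwise positive), ``contrast_pair`` the 5-bit (bright, dark) values,
    ``window`` a square region (center_x, center_y, width) in pixels
    relative to display center.
    """

    wavelength_px: int = 20
    tf_hz: float = 1.0
    direction_deg: float = 0.0
    contrast_pair: tuple[int, int] = (30, 0)
    window: tuple[float, float, float] = (0.0, 0.0, 80.0)
    duration_s: float = 1.0
    fps: float = 60.0

    def __post_init__(self) -> None:
        if int(self.wavelength_px) != self.wavelength_px or self.wavelength_px <= 0:
            raise ValueError("wavelength_px must be a positive integer")
        bright, dark = self.contrast_pair
        if not (0 <= dark <= bright <= 31):
            raise ValueError("contrast pair must satisfy 0 <= dark <= bright <= 31")


@dataclass(frozen=True)
class LoomSpec:
    """Constant-velocity approach of a dark circular object."""

    start_distance_m: float = 20.0
    speed_m_s: float = 25.0
    end_distance_m: float = 0.6
    object_diameter_m: float = 0.5
    placement: tuple[float, float] = (0.0, 45.0)
    fps: float = 60.0

    def __post_init__(self) -> None:
        if not (self.start_distance_m > self.end_distance_m > 0):
            raise ValueError("need start_distance > end_distance > 0")
        if self.speed_m_s <= 0:
            raise ValueError("speed must be positive")

    @property
    def duration_s(self) -> float:
        return (self.start_distance_m - self.end_distance_m) / self.speed_m_s


def michelson_contrast(pair: tuple[float, float]) -> float:
    """Michelson contrast, percent, of a 5-bit (bright, dark) bar pair.

    100 x (bright - dark) / (bright + dark); the all-black pair (0, 0) is
    defined as 0%.
    """
    bright, dark = pair
    if not (0 <= dark <= bright <= 31):
        raise ValueError("bar values must satisfy 0 <= dark <= bright <= 31")
    if bright + dark == 0:
        return 0.0
    return 100.0 * (bright - dark) / (bright + dark)


def sf_px_to_cpd(wavelength_px: float, mapping: DisplayMapping) -> float:
    """Spatial frequency (cycles/degree) of a grating of period
    ``wavelength_px`` on an angle-linear display: resolution / wavelength."""
    if wavelength_px <= 0:
        raise ValueError("wavelength must be positive")
    return mapping.resolution / wavelength_px


def display_size_px(mapping: DisplayMapping) -> int:
    """Square frame size (pixels) that contains the circular display."""
    return int(np.ceil(2 * mapping.radius_px))


def grating_frames(
    spec: GratingSpec, mapping: DisplayMapping = DisplayMapping()
) -> np.ndarray:
    """Render a drifting square-wave grating as a (frames, H, W) uint8
    stack of 5-bit values.

    Bright/dark bars alternate with period ``wavelength_px`` along the drift
    direction; the phase advances tf_hz x wavelength pixels per second.
    Pixels outside the square window are mid-gray (15).
    """
    size = display_size_px(mapping)
    cx, cy, width = spec.window
    if abs(cx) + width / 2 > mapping.radius_px + 1e-9 or abs(cy) + width / 2 > mapping.radius_px + 1e-9:
        raise ValueError("stimulus window exceeds the display")
    n_frames = int(round(spec.duration_s * spec.fps))
    bright, dark = spec.contrast_pair

    yy, xx = np.mgrid[0:size, 0:size]
    x = xx - (size - 1) / 2.0  # px right of center
    y = (size - 1) / 2.0 - yy  # px above center
    d = np.radians(spec.direction_deg)
    proj = x * np.cos(d) + y * np.sin(d)  # coordinate along drift direction
    in_win = (np.abs(x - cx) <= width / 2) & (np.abs(y - cy) <= width / 2)

    frames = np.empty((n_frames, size, size), dtype=np.uint8)
    for i in range(n_frames):
        t = i / spec.fps
        shift = spec.tf_hz * spec.wavelength_px * t  # drift along +direction
        phase = np.mod(proj - shift, spec.wavelength_px) / spec.wavelength_px
        img = np.where(phase < 0.5, bright, dark).astype(np.uint8)
        img[~in_win] = MID_GRAY
        frames[i] = img
    return frames


BAR_SWEEP_DIRECTIONS = ("right", "down", "left", "up")


def bar_sweep_stimulus(
    grid_index: int,
    mapping: DisplayMapping = DisplayMapping(),
    fps: float = 60.0,
    cell_px: int = 12,
    bar_value: int = 30,
) -> tuple[np.ndarray, dict]:
    """Four-direction bar sweep in one cell of the 5 x 5 receptive-field
    mapping grid centered on the display.

    A 6 x 12 px bright bar sweeps across the 12-px cell rightward, then
    down, left and up, 0.5 s per direction (2 s total).  Returns the frame
    stack and metadata with the cell center in pixels and degrees.
    """
    if not 0 <= grid_index <= 24:
        raise ValueError("grid_index must be in 0..24")
    row, col = divmod(grid_index, 5)
    # cell centers: 5x5 grid of cell_px squares centered on the display
    cx = (col - 2) * cell_px
    cy = (2 - row) * cell_px  # row 0 at top
    size = display_size_px(mapping)
    half = cell_px / 2
    n_per_dir = int(round(0.5 * fps))
    bar_l, bar_w = cell_px / 2, cell_px  # 6 x 12 px for the default cell

    yy, xx = np.mgrid[0:size, 0:size]
    x = xx - (size - 1) / 2.0
    y = (size - 1) / 2.0 - yy
    in_cell = (np.abs(x - cx) <= half) & (np.abs(y - cy) <= half)

    frames = np.full((4 * n_per_dir, size, size), MID_GRAY, dtype=np.uint8)
    for d_i, direction in enumerate(BAR_SWEEP_DIRECTIONS):
        for j in range(n_per_dir):
            frac = (j + 0.5) / n_per_dir  # sweep progress 0..1
            img = frames[d_i * n_per_dir + j]
            img[in_cell] = 0
            pos = -half + frac * cell_px  # leading coordinate within cell
            if direction == "right":
                bar = (np.abs(x - (cx + pos)) <= bar_l / 2) & (np.abs(y - cy) <= bar_w / 2)
            elif direction == "left":
                bar = (np.abs(x - (cx - pos)) <= bar_l / 2) & (np.abs(y - cy) <= bar_w / 2)
            elif direction == "down":
                bar = (np.abs(y - (cy - pos)) <= bar_l / 2) & (np.abs(x - cx) <= bar_w / 2)
            else:  # up
                bar = (np.abs(y - (cy + pos)) <= bar_l / 2) & (np.abs(x - cx) <= bar_w / 2)
            img[bar & in_cell] = bar_value
    meta = {
        "grid_index": grid_index,
        "cell_center_px": (cx, cy),
        "cell_center_deg": (cx / mapping.resolution, cy / mapping.resolution),
        "cell_width_px": cell_px,
        "cell_width_deg": cell_px / mapping.resolution,
        "directions": list(BAR_SWEEP_DIRECTIONS),
        "seconds_per_direction": 0.5,
    }
    return frames, meta


def loom_schedule(spec: LoomSpec) -> dict:
    """Time series of object distance and angular diameter for a loom.

    d(t) = start - speed*t until the end distance; the angular diameter is
    2*atan(D / 2d), strictly increasing as the object approaches.
    """
    n = int(np.floor(spec.duration_s * spec.fps)) + 1
    t = np.arange(n) / spec.fps
    d = spec.start_distance_m - spec.speed_m_s * t
    # include the exact end point
    if d[-1] > spec.end_distance_m + 1e-12:
        t = np.append(t, spec.duration_s)
        d = np.append(d, spec.end_distance_m)
    theta = np.degrees(2 * np.arctan(spec.object_diameter_m / (2 * d)))
    return {
        "t_s": t,
        "distance_m": d,
        "angular_diameter_deg": theta,
        "duration_s": spec.duration_s,
    }


def _focal_px(planar_size: int, planar_fov_deg: float) -> float:
    if planar_fov_deg >= 180:
        raise ValueError("perspective source FOV must be < 180 degrees")
    return (planar_size / 2.0) / np.tan(np.radians(planar_fov_deg) / 2.0)


def warp_viewport(
    planar_image: np.ndarray,
    planar_fov_deg: float,
    mapping: DisplayMapping = DisplayMapping(),
    out_size: int | None = None,
) -> np.ndarray:
    """Resample a flat perspective-rendered viewport onto the angle-linear
    circular display.

    A display pixel at radial offset rho represents viewing angle
    theta = rho / resolution; it samples the planar image at radius
    f*tan(theta) along the same azimuthal direction (f set by the planar
    FOV).  Bilinear interpolation; the center pixel is a fixed point.
    """
    img = np.asarray(planar_image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("planar image must be square and 2-D")
    if planar_fov_deg > 2 * mapping.half_fov:
        raise ValueError("planar FOV exceeds the viewable region")
    f = _focal_px(img.shape[0], planar_fov_deg)
    size = out_size or display_size_px(mapping)
    c_out = (size - 1) / 2.0
    c_in = (img.shape[0] - 1) / 2.0

    yy, xx = np.mgrid[0:size, 0:size]
    dx = xx - c_out
    dy = yy - c_out
    rho = np.hypot(dx, dy)
    theta = rho / mapping.resolution  # degrees
    theta = np.clip(theta, 0, 89.999)
    r_in = f * np.tan(np.radians(theta))
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(rho > 0, r_in / rho, 0.0)
    sx = c_in + dx * scale
    sy = c_in + dy * scale
    return map_coordinates(img, [sy, sx], order=1, mode="nearest")


def unwarp_viewport(
    display_image: np.ndarray,
    planar_fov_deg: float,
    mapping: DisplayMapping = DisplayMapping(),
    out_size: int | None = None,
) -> np.ndarray:
    """Inverse of :func:`warp_viewport`: resample a circular display image
    back to a flat perspective viewport (atan radial mapping)."""
    img = np.asarray(display_image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("display image must be square and 2-D")
    size = out_size or img.shape[0]
    f = _focal_px(size, planar_fov_deg)
    c_out = (size - 1) / 2.0
    c_in = (img.shape[0] - 1) / 2.0

    yy, xx = np.mgrid[0:size, 0:size]
    dx = xx - c_out
    dy = yy - c_out
    r = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(r, f))  # viewing angle of planar pixel
    rho = theta * mapping.resolution
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 0, rho / r, 0.0)
    sx = c_in + dx * scale
    sy = c_in + dy * scale
    return map_coordinates(img, [sy, sx], order=1, mode="nearest")


def to_8bit(frames: np.ndarray) -> np.ndarray:
    """Scale 5-bit frame values to 8-bit for export (x8)."""
    return (np.asarray(frames, dtype=np.uint16) * 8).clip(0, 255).astype(np.uint8)


def to_blue_channel(frames: np.ndarray) -> np.ndarray:
    """Export frames into the blue channel of an RGB stack (red and green
    zero), matching the spectral separation from red-channel eye imaging."""
    f8 = to_8bit(frames)
    rgb = np.zeros(f8.shape + (3,), dtype=np.uint8)
    rgb[..., 2] = f8
    return rgb
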