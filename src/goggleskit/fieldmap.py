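"""Angle-linear display model and spherical visual-field coverage.

Each eyepiece presents an azimuthal-equidistant image: the viewing angle
theta from the optical axis maps linearly onto radial pixel offset on a
circular display.  This module models that mapping, computes the spherical
footprint each eyepiece covers, summarizes binocular coverage, and projects
footprints to the plane for plotting.

Conventions: azimuth is positive to the animal's right, elevation positive
up, both in degrees at the API surface; internal math is in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DisplayMapping",
    "SphericalFootprint",
    "angle_to_pixel",
    "pixel_to_angle",
    "nyquist_cpd",
    "eyepiece_footprint",
    "binocular_metrics",
    "mouse_fov_ellipse",
    "project_winkel_tripel",
]


@dataclass(frozen=True)
class DisplayMapping:
    """Linear angle-to-pixel model of one circular eyepiece display.

    Parameters
    ----------
    resolution : float
        Angular resolution in pixels per degree (default 1.57).
    half_fov : float
        Maximum viewing angle from the optical axis, degrees (default 70).
    axis_azimuth, axis_elevation : float
        Pose of the optical axis in the animal's visual field, degrees.
    """

    resolution: float = 1.57
    half_fov: float = 70.0
    axis_azimuth: float = 0.0
    axis_elevation: float = 0.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not (0 < self.half_fov <= 90):
            raise ValueError("half_fov must be in (0, 90] degrees")

    @property
    def radius_px(self) -> float:
        """Display radius in pixels (resolution x half_fov)."""
        return self.resolution * self.half_fov


@dataclass(frozen=True)
class SphericalFootprint:
    """Region of the visual sphere covered by a display or an eye.

    ``boundary`` holds ordered (azimuth, elevation) samples in degrees;
    ``kind`` is ``"circular-cap"`` or ``"ellipse"``.
    """

    center: tuple[float, float]
    boundary: np.ndarray
    kind: str = "circular-cap"
    angular_radius: float | None = None
    half_axes: tuple[float, float] | None = None

    def boundary_vectors(self) -> np.ndarray:
        """Unit direction vectors (x forward, y right, z up) of the boundary."""
        return _sph_to_vec(self.boundary[:, 0], self.boundary[:, 1])

    def area_sr(self) -> float:
        """Footprint area in steradians.

        Closed form for a circular cap; 1-degree-grid numerical integral for
        an ellipse footprint.
        """
        if self.kind == "circular-cap":
            r = np.radians(self.angular_radius)
            return float(2 * np.pi * (1 - np.cos(r)))
        return _ellipse_area_sr(self.center, self.half_axes)


def _sph_to_vec(az_deg, el_deg) -> np.ndarray:
    az = np.radians(np.asarray(az_deg, dtype=float))
    el = np.radians(np.asarray(el_deg, dtype=float))
    return np.stack(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)], axis=-1
    )


def _ellipse_area_sr(center, half_axes, step_deg: float = 0.05) -> float:
    # integrate cos(el) over the planar (az, el) ellipse
    el0 = center[1]
    a, b = half_axes
    els = np.arange(el0 - b + step_deg / 2, el0 + b, step_deg)
    frac = 1 - ((els - el0) / b) ** 2
    frac[frac < 0] = 0
    widths = 2 * a * np.sqrt(frac)  # azimuthal width, degrees
    return float(
        np.sum(np.radians(widths) * np.cos(np.radians(els))) * np.radians(step_deg)
    )


def angle_to_pixel(theta: float, mapping: DisplayMapping) -> float:
    """Radial pixel offset of viewing angle ``theta`` (degrees) from center.

    The display is angle-linear: offset = resolution x theta.  Raises
    ``ValueError`` for angles beyond the half field of view.
    """
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(np.abs(theta_arr) > mapping.half_fov + 1e-12):
        raise ValueError(
            f"viewing angle {theta} deg outside +/-{mapping.half_fov} deg FOV"
        )
    out = mapping.resolution * theta_arr
    return float(out) if np.isscalar(theta) or out.ndim == 0 else out


def pixel_to_angle(px: float, mapping: DisplayMapping) -> float:
    """Viewing angle (degrees) of a radial pixel offset; inverse of
    :func:`angle_to_pixel`."""
    px_arr = np.asarray(px, dtype=float)
    if np.any(np.abs(px_arr) > mapping.radius_px + 1e-9):
        raise ValueError(f"pixel offset {px} outside display radius {mapping.radius_px}")
    out = px_arr / mapping.resolution
    return float(out) if np.isscalar(px) or out.ndim == 0 else out


def nyquist_cpd(mapping: DisplayMapping) -> float:
    """Nyquist spatial frequency in cycles per degree, to two decimals.

    Half the angular sampling rate: resolution / 2.  Rounded half-even in
    decimal (1.57 px/deg reports 0.78, not 0.79 from binary-float carry).
    """
    from decimal import ROUND_HALF_EVEN, Decimal

    half = Decimal(repr(mapping.resolution)) / 2
    return float(half.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def eyepiece_footprint(mapping: DisplayMapping, step_deg: float = 1.0) -> SphericalFootprint:
    """Spherical cap covered by an eyepiece: angular radius ``half_fov``
    centered on the optical axis.

    The boundary is the circle of points at angular distance ``half_fov``
    from the axis, sampled every ``step_deg`` degrees of arc parameter.
    """
    az0 = np.radians(mapping.axis_azimuth)
    el0 = np.radians(mapping.axis_elevation)
    r = np.radians(mapping.half_fov)
    t = np.radians(np.arange(0.0, 360.0, step_deg))

    # circle of angular radius r around +x, then rotate +x onto the axis
    circ = np.stack(
        [np.full_like(t, np.cos(r)), np.sin(r) * np.cos(t), np.sin(r) * np.sin(t)],
        axis=-1,
    )
    ry = np.array(
        [
            [np.cos(el0), 0, -np.sin(el0)],
            [0, 1, 0],
            [np.sin(el0), 0, np.cos(el0)],
        ]
    )
    rz = np.array(
        [
            [np.cos(az0), -np.sin(az0), 0],
            [np.sin(az0), np.cos(az0), 0],
            [0, 0, 1],
        ]
    )
    vec = circ @ ry.T @ rz.T
    az = np.degrees(np.arctan2(vec[:, 1], vec[:, 0]))
    el = np.degrees(np.arcsin(np.clip(vec[:, 2], -1, 1)))
    return SphericalFootprint(
        center=(mapping.axis_azimuth, mapping.axis_elevation),
        boundary=np.column_stack([az, el]),
        kind="circular-cap",
        angular_radius=mapping.half_fov,
    )


def _cap_azimuth_halfwidth(cap: SphericalFootprint, elevation_deg: float) -> float:
    """Azimuthal half-width (degrees of azimuth) of a cap's intersection with
    the horizontal small circle at ``elevation_deg``; 0 if disjoint.

    From the spherical law of cosines, a point (az, e) lies inside a cap of
    radius h centered at (az0, e0) iff
    sin(e) sin(e0) + cos(e) cos(e0) cos(az - az0) >= cos(h).
    """
    h = np.radians(cap.angular_radius)
    e0 = np.radians(cap.center[1])
    e = np.radians(elevation_deg)
    denom = np.cos(e) * np.cos(e0)
    if denom == 0:
        return 180.0 if np.sin(e) * np.sin(e0) >= np.cos(h) else 0.0
    x = (np.cos(h) - np.sin(e) * np.sin(e0)) / denom
    if x > 1:
        return 0.0
    if x < -1:
        return 180.0
    return float(np.degrees(np.arccos(x)))


def _union_extent(intervals: list[tuple[float, float]]) -> float:
    """Total length of the union of 1-D intervals."""
    ivs = sorted((lo, hi) for lo, hi in intervals if hi > lo)
    total, cur_lo, cur_hi = 0.0, None, None
    for lo, hi in ivs:
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        total += cur_hi - cur_lo
    return total


def _caps_intersection_area_sr(
    left: SphericalFootprint, right: SphericalFootprint, step_deg: float = 0.1
) -> float:
    """Area (steradians) of the intersection of two circular caps, by
    integrating the overlap of their azimuth intervals over elevation."""
    els = np.arange(-90 + step_deg / 2, 90, step_deg)
    d_el = np.radians(step_deg)
    total = 0.0
    for e in els:
        w1 = _cap_azimuth_halfwidth(left, e)
        w2 = _cap_azimuth_halfwidth(right, e)
        if w1 == 0 or w2 == 0:
            continue
        lo = max(left.center[0] - w1, right.center[0] - w2)
        hi = min(left.center[0] + w1, right.center[0] + w2)
        if hi > lo:
            total += np.radians(hi - lo) * np.cos(np.radians(e)) * d_el
    return total


def binocular_metrics(left: SphericalFootprint, right: SphericalFootprint) -> dict:
    """Coverage summary of two eyepiece caps.

    Horizontal extent and overlap are measured along the horizontal meridian
    at the eyepieces' axis elevation (the small circle of constant
    elevation); the vertical extent along the vertical meridian through each
    axis.  The full 2-D intersection area (steradians) is also reported.
    Symmetric in argument order; disjoint caps give overlap 0.
    """
    if left.kind != "circular-cap" or right.kind != "circular-cap":
        raise ValueError("binocular_metrics expects two circular caps")
    # measure along the horizontal line at the mean axis elevation
    el_ref = 0.5 * (left.center[1] + right.center[1])
    iv = []
    for cap in (left, right):
        w = _cap_azimuth_halfwidth(cap, el_ref)
        iv.append((cap.center[0] - w, cap.center[0] + w))
    horizontal = _union_extent(iv)
    olo, ohi = max(iv[0][0], iv[1][0]), min(iv[0][1], iv[1][1])
    overlap = max(0.0, ohi - olo)

    v_iv = [
        (cap.center[1] - cap.angular_radius, cap.center[1] + cap.angular_radius)
        for cap in (left, right)
    ]
    vertical = _union_extent(v_iv)
    return {
        "horizontal_extent_deg": horizontal,
        "vertical_extent_deg": vertical,
        "overlap_deg": overlap,
        "intersection_sr": _caps_intersection_area_sr(left, right),
        "meridian_elevation_deg": el_ref,
    }


def mouse_fov_ellipse(
    side: str = "right", step_deg: float = 1.0
) -> SphericalFootprint:
    """Approximate monocular mouse field of view: a 180 x 140 degree ellipse
    centered at 70 degrees azimuth (mirrored for the left eye) and 10
    degrees elevation, drawn in (azimuth, elevation) coordinates.
    """
    sign = 1.0 if side == "right" else -1.0
    az0, el0 = sign * 70.0, 10.0
    a, b = 90.0, 70.0
    t = np.radians(np.arange(0.0, 360.0, step_deg))
    az = az0 + a * np.cos(t)
    el = el0 + b * np.sin(t)
    return SphericalFootprint(
        center=(az0, el0),
        boundary=np.column_stack([az, el]),
        kind="ellipse",
        half_axes=(a, b),
    )


_WINKEL_PHI1 = np.arccos(2.0 / np.pi)


def project_winkel_tripel(points) -> np.ndarray:
    """Winkel tripel projection (standard parallel arccos(2/pi)) of
    (azimuth, elevation) points in degrees, for visual-field plots.

    Returns planar (x, y) in radians-scale units; (0, 0) maps to (0, 0).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    lam = np.radians(pts[:, 0])
    phi = np.radians(pts[:, 1])
    if np.any(np.abs(lam) > np.pi + 1e-9) or np.any(np.abs(phi) > np.pi / 2 + 1e-9):
        raise ValueError("azimuth must be in [-180, 180], elevation in [-90, 90]")
    alpha = np.arccos(np.clip(np.cos(phi) * np.cos(lam / 2.0), -1, 1))
    with np.errstate(invalid="ignore"):
        sinc = np.where(alpha == 0, 1.0, np.sin(alpha) / np.where(alpha == 0, 1.0, alpha))
    x = 0.5 * (lam * np.cos(_WINKEL_PHI1) + 2.0 * np.cos(phi) * np.sin(lam / 2.0) / sinc)
    y = 0.5 * (phi + np.sin(phi) / sinc)
    return np.column_stack([x, y])
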