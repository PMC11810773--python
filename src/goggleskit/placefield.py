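"""Hippocampal place-field analysis on a virtual linear track.

Spatial tuning curves are built from spike times and the animal's virtual
position: spikes and occupancy are speed-filtered (> 5 cm/s), binned into
3-cm bins along the 150-virtual-cm track, and each map is smoothed with a
3-cm-s.d. Gaussian before forming the rate.  Spatial selectivity is scored
by the information content

    SI = sum_i P_i * (lambda_i / lambda) * log2(lambda_i / lambda)

in bits per spike, where P_i is the occupancy probability of bin i,
lambda_i its mean firing rate, and lambda the overall mean rate.  A cell
is a place cell when its SI exceeds the 95th percentile of 500 shuffles
(circular time shifts of the position series) and its peak rate is at
least 1 Hz.  Fields are contiguous regions holding at least 30% of a local
ratemap peak, with widths restricted to 10-80 virtual cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "RateMap",
    "Field",
    "PlaceCellResult",
    "compute_speed",
    "rate_map",
    "spatial_information",
    "place_cell_test",
    "detect_fields",
    "TRACK_LENGTH_CM",
]

TRACK_LENGTH_CM = 150.0
BIN_CM = 3.0
SMOOTH_SD_CM = 3.0
SPEED_MIN_CM_S = 5.0


@dataclass
class RateMap:
    """Binned, smoothed spatial firing-rate map with occupancy."""

    bin_centers_cm: np.ndarray
    rate_hz: np.ndarray          # lambda_i
    occupancy: np.ndarray        # P_i, sums to 1 over occupied bins
    overall_rate_hz: float       # lambda
    occupied: np.ndarray         # bool mask of occupied bins
    bin_cm: float = BIN_CM

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers_cm)

    @property
    def peak_rate_hz(self) -> float:
        return float(np.nanmax(self.rate_hz[self.occupied]))


@dataclass(frozen=True)
class Field:
    start_cm: float
    end_cm: float
    peak_rate_hz: float

    @property
    def width_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass
class PlaceCellResult:
    si_bits_per_spike: float
    null_si: np.ndarray
    percentile_95: float
    peak_rate_hz: float
    is_place_cell: bool
    fields: list = field(default_factory=list)


def compute_speed(t_s: np.ndarray, pos_cm: np.ndarray, boxcar_s: float = 0.25) -> np.ndarray:
    """Speed (cm/s) by central differences, smoothed with a 0.25-s boxcar.

    Teleports back to the track start produce one spurious large-speed
    sample; the magnitude is clipped at the track length per sample gap
    before smoothing to keep the boxcar local.
    """
    t_s = np.asarray(t_s, dtype=float)
    pos = np.asarray(pos_cm, dtype=float)
    v = np.gradient(pos, t_s)
    # suppress teleport spikes (lap reset): cap at half-track per sample
    dt = np.median(np.diff(t_s))
    v = np.clip(v, -0.5 * TRACK_LENGTH_CM / dt, 0.5 * TRACK_LENGTH_CM / dt)
    n = max(1, int(round(boxcar_s / dt)))
    kernel = np.ones(n) / n
    return np.convolve(np.abs(v), kernel, mode="same")


def rate_map(
    spike_times_s: np.ndarray,
    t_s: np.ndarray,
    pos_cm: np.ndarray,
    track_length_cm: float = TRACK_LENGTH_CM,
    bin_cm: float = BIN_CM,
    smooth_sd_cm: float = SMOOTH_SD_CM,
    speed_min_cm_s: float = SPEED_MIN_CM_S,
    speed: np.ndarray | None = None,
) -> RateMap:
    """Speed-filtered, Gaussian-smoothed spatial rate map.

    Spike and occupancy maps are each smoothed with a ``smooth_sd_cm``
    Gaussian kernel (reflected boundaries — teleportation breaks spatial
    adjacency, so the track is not wrapped) before the rate quotient.
    Raises ``ValueError`` if no occupancy survives the speed filter.
    """
    t_s = np.asarray(t_s, dtype=float)
    pos = np.asarray(pos_cm, dtype=float)
    spikes = np.asarray(spike_times_s, dtype=float)
    if speed is None:
        speed = compute_speed(t_s, pos)
    moving = speed > speed_min_cm_s

    n_bins = int(np.ceil(track_length_cm / bin_cm))
    edges = np.arange(n_bins + 1) * bin_cm
    dt = np.median(np.diff(t_s))

    occ_time, _ = np.histogram(pos[moving], bins=edges)
    occ_time = occ_time * dt
    if occ_time.sum() <= 0:
        raise ValueError("no occupancy above the speed threshold")

    # speed-filter spikes by the movement state at the nearest sample
    idx = np.clip(np.searchsorted(t_s, spikes), 0, len(t_s) - 1)
    sp_ok = moving[idx]
    spike_pos = np.interp(spikes[sp_ok], t_s, pos)
    spike_counts, _ = np.histogram(spike_pos, bins=edges)

    sigma_bins = smooth_sd_cm / bin_cm
    occ_s = gaussian_filter1d(occ_time.astype(float), sigma_bins, mode="reflect")
    spk_s = gaussian_filter1d(spike_counts.astype(float), sigma_bins, mode="reflect")

    occupied = occ_s > 0
    rate = np.zeros(n_bins)
    rate[occupied] = spk_s[occupied] / occ_s[occupied]
    p_i = np.zeros(n_bins)
    p_i[occupied] = occ_s[occupied] / occ_s[occupied].sum()
    overall = spike_counts.sum() / occ_time.sum()
    return RateMap(
        bin_centers_cm=(edges[:-1] + edges[1:]) / 2,
        rate_hz=rate,
        occupancy=p_i,
        overall_rate_hz=float(overall),
        occupied=occupied,
        bin_cm=bin_cm,
    )


def spatial_information(rmap: RateMap) -> float:
    """Spatial information content in bits per spike.

    Occupancy-weighted divergence of the positional rate from the overall
    mean rate; bins with zero rate contribute 0 (x log x -> 0 limit).
    Requires a positive overall rate.
    """
    lam = rmap.overall_rate_hz
    if lam <= 0:
        raise ValueError("spatial information undefined for a silent cell")
    p = rmap.occupancy[rmap.occupied]
    li = rmap.rate_hz[rmap.occupied]
    ratio = li / lam
    terms = np.where(ratio > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def place_cell_test(
    spike_times_s: np.ndarray,
    t_s: np.ndarray,
    pos_cm: np.ndarray,
    n_shuffles: int = 500,
    seed: int | np.random.Generator = 0,
    min_shift_s: float = 10.0,
    peak_min_hz: float = 1.0,
    shuffle: str = "circular",
    **map_kwargs,
) -> PlaceCellResult:
    """Shuffle test for place selectivity.

    The null distribution comes from ``n_shuffles`` spatial information
    scores computed after circularly time-shifting the position series by
    a uniform offset of at least ``min_shift_s`` (preserving position
    autocorrelation); ``shuffle='permute'`` uses a full random permutation
    instead.  A cell is a place cell when its observed SI exceeds the null
    95th percentile and its peak rate is at least 1 Hz.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_s = np.asarray(t_s, dtype=float)
    pos = np.asarray(pos_cm, dtype=float)
    speed = compute_speed(t_s, pos)

    obs_map = rate_map(spike_times_s, t_s, pos, speed=speed, **map_kwargs)
    si = spatial_information(obs_map)

    duration = t_s[-1] - t_s[0]
    if duration <= 2 * min_shift_s:
        raise ValueError("session too short for the circular shift null")
    dt = np.median(np.diff(t_s))
    n = len(pos)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        if shuffle == "circular":
            shift_s = rng.uniform(min_shift_s, duration - min_shift_s)
            k = int(round(shift_s / dt)) % n
            pos_sh = np.roll(pos, k)
        elif shuffle == "permute":
            pos_sh = rng.permutation(pos)
        else:
            raise ValueError("shuffle must be 'circular' or 'permute'")
        m = rate_map(spike_times_s, t_s, pos_sh, speed=speed, **map_kwargs)
        null[i] = spatial_information(m)

    p95 = float(np.percentile(null, 95))
    peak = obs_map.peak_rate_hz
    is_pc = bool(si > p95 and peak >= peak_min_hz)
    fields = detect_fields(obs_map) if is_pc else []
    return PlaceCellResult(
        si_bits_per_spike=si,
        null_si=null,
        percentile_95=p95,
        peak_rate_hz=peak,
        is_place_cell=is_pc,
        fields=fields,
    )


def detect_fields(
    rmap: RateMap,
    frac: float = 0.30,
    min_width_cm: float = 10.0,
    max_width_cm: float = 80.0,
    min_peak_hz: float = 1.0,
) -> list[Field]:
    """Detect place fields around local ratemap peaks.

    For each local maximum (strictly greater than both neighbors; plateaus
    take the leftmost bin) of at least ``min_peak_hz``, the field is the
    maximal contiguous run of bins with rate >= frac x peak containing it.
    Runs sharing bins are merged; widths outside [min_width_cm,
    max_width_cm] are discarded.  The peak-rate floor keeps background
    fluctuations from seeding near-zero thresholds that would swallow the
    whole track (it matches the 1-Hz peak criterion of the place-cell
    test).
    """
    r = rmap.rate_hz
    n = len(r)
    peaks = []
    for i in range(n):
        left = r[i - 1] if i > 0 else -np.inf
        right = r[i + 1] if i < n - 1 else -np.inf
        if r[i] > left and r[i] >= right and r[i] >= min_peak_hz:
            if i < n - 1 and r[i] == right:
                pass  # leftmost bin of a plateau counts as the peak
            peaks.append(i)

    runs: list[tuple[int, int, float]] = []
    for i in peaks:
        thr = frac * r[i]
        lo = i
        while lo > 0 and r[lo - 1] >= thr:
            lo -= 1
        hi = i
        while hi < n - 1 and r[hi + 1] >= thr:
            hi += 1
        runs.append((lo, hi, r[i]))

    # merge runs sharing bins
    runs.sort()
    merged: list[list] = []
    for lo, hi, pk in runs:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][2] = max(merged[-1][2], pk)
        else:
            merged.append([lo, hi, pk])

    fields = []
    for lo, hi, pk in merged:
        start = lo * rmap.bin_cm
        end = (hi + 1) * rmap.bin_cm
        width = end - start
        if min_width_cm <= width <= max_width_cm:
            fields.append(Field(start_cm=start, end_cm=end, peak_rate_hz=float(pk)))
    return fields


def population_matrix(rate_maps: list[RateMap]) -> np.ndarray:
    """Position-ordered, z-scored population matrix (cells x bins), rows
    sorted by each cell's peak location — the standard place-cell
    sequence heatmap."""
    mat = np.array([m.rate_hz for m in rate_maps])
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (mat - mu) / sd
    order = np.argsort(np.argmax(mat, axis=1))
    return z[order]
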