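"""Stimulus-locked response quantification and tuning-curve fits for V1.

Responses are mean inferred-spike rates in a stimulus window relative to a
2-s pre-stimulus baseline.  Three tuning models are fit to max-normalized
responses, each with a goodness-of-fit gate that mirrors standard practice:

* receptive field: rotated 2-D Gaussian over the 5x5 bar-sweep grid,
  accepted when the residual sum of squares (on normalized data) < 0.25;
  RF size is the mean half-width at half-maximum, hwhm = sigma*sqrt(2 ln 2)
* spatial frequency: log-Gaussian in log2-SF,
  R(SF) = exp(-(log2 SF - log2 SF_pref)^2 / (2 sigma^2)), accepted when
  adjusted R^2 > 0.8
* contrast: Naka-Rushton R(c) = c^n / (c^n + c50^n), accepted when
  adjusted R^2 > 0.8

All fits are deterministic (fixed initialization; no randomness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ResponseTable",
    "RFFit",
    "SFFit",
    "ContrastFit",
    "stimulus_response",
    "fit_rf",
    "fit_sf",
    "fit_contrast",
    "FRAME_RATE_HZ",
]

FRAME_RATE_HZ = 3.41

HWHM_FACTOR = np.sqrt(2 * np.log(2))


@dataclass
class ResponseTable:
    """Mean in-stimulus and baseline rates, cells x stimuli."""

    response: np.ndarray  # (n_cells, n_stimuli) mean rate during stimulus
    baseline: np.ndarray  # matched 2-s pre-stimulus means
    n_repetitions: int


@dataclass(frozen=True)
class RFFit:
    """Rotated 2-D Gaussian receptive-field fit."""

    center_deg: tuple[float, float]
    sigma_major_deg: float
    sigma_minor_deg: float
    rotation_deg: float
    amplitude: float
    offset: float
    resnorm: float
    accepted: bool

    @property
    def rf_size_hwhm_deg(self) -> float:
        """Mean of the two half-widths at half-maximum."""
        return 0.5 * (self.sigma_major_deg + self.sigma_minor_deg) * HWHM_FACTOR


@dataclass(frozen=True)
class SFFit:
    sf_pref_cpd: float
    sigma_log2: float
    adj_r2: float
    accepted: bool


@dataclass(frozen=True)
class ContrastFit:
    c50_percent: float
    n: float
    adj_r2: float
    accepted: bool
    monotone_decreasing: bool = False
    gain: float = 1.0


def _adjusted_r2(y: np.ndarray, yhat: np.ndarray, n_params: int) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    r2 = 1 - ss_res / ss_tot
    n = len(y)
    return 1 - (1 - r2) * (n - 1) / (n - n_params - 1)


def stimulus_response(
    trace: np.ndarray,
    onsets_s: np.ndarray,
    stim_dur_s: float,
    baseline_s: float = 2.0,
    frame_rate_hz: float = FRAME_RATE_HZ,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-repetition stimulus and baseline means for one cell and one
    stimulus, averaged across repetitions.

    Frames fall in half-open time windows [onset, onset+dur) for the
    stimulus and [onset-baseline, onset) for the baseline.  Repetitions
    whose windows extend past the trace are dropped with a warning count.
    Returns (mean_response, mean_baseline, n_used).
    """
    trace = np.asarray(trace, dtype=float)
    frame_t = np.arange(len(trace)) / frame_rate_hz
    resp, base = [], []
    for onset in np.atleast_1d(onsets_s):
        stim = (frame_t >= onset) & (frame_t < onset + stim_dur_s)
        pre = (frame_t >= onset - baseline_s) & (frame_t < onset)
        if onset - baseline_s < -1e-9 or onset + stim_dur_s > frame_t[-1] + 1.0 / frame_rate_hz:
            continue  # window extends past the trace; drop this repetition
        if stim.sum() == 0 or pre.sum() == 0:
            continue
        resp.append(trace[stim].mean())
        base.append(trace[pre].mean())
    if not resp:
        raise ValueError("no usable repetitions within the trace")
    return float(np.mean(resp)), float(np.mean(base)), len(resp)


def response_table(
    traces: np.ndarray,
    onsets_by_stimulus: dict,
    stim_dur_s: float,
    baseline_s: float = 2.0,
    frame_rate_hz: float = FRAME_RATE_HZ,
) -> ResponseTable:
    """Build a cells x stimuli :class:`ResponseTable` from per-cell traces
    and a mapping of stimulus id to onset times."""
    stim_ids = sorted(onsets_by_stimulus)
    n_cells = traces.shape[0]
    resp = np.zeros((n_cells, len(stim_ids)))
    base = np.zeros_like(resp)
    n_rep = 0
    for ci in range(n_cells):
        for si, sid in enumerate(stim_ids):
            r, b, n = stimulus_response(
                traces[ci], onsets_by_stimulus[sid], stim_dur_s, baseline_s, frame_rate_hz
            )
            resp[ci, si], base[ci, si] = r, b
            n_rep = max(n_rep, n)
    return ResponseTable(response=resp, baseline=base, n_repetitions=n_rep)


def _gauss2d_rot(xy, x0, y0, sx, sy, theta, amp, off):
    x, y = xy
    ct, st = np.cos(theta), np.sin(theta)
    xr = (x - x0) * ct + (y - y0) * st
    yr = -(x - x0) * st + (y - y0) * ct
    return off + amp * np.exp(-(xr**2 / (2 * sx**2) + yr**2 / (2 * sy**2)))


def fit_rf(
    grid_responses: np.ndarray,
    cell_size_deg: float = 7.6,
    resnorm_threshold: float = 0.25,
) -> RFFit:
    """Fit a rotated 2-D Gaussian to the 5x5 bar-sweep response grid.

    Responses are max-normalized before fitting; ``resnorm`` is the sum of
    squared residuals of the normalized data and fits with resnorm >= 0.25
    are flagged rejected.  Grid coordinates are degrees relative to the
    grid center (cells 7.6 degrees wide).  Row 0 is the top of the grid.
    """
    g = np.asarray(grid_responses, dtype=float)
    if g.shape != (5, 5):
        raise ValueError("expected a 5x5 response grid")
    peak = g.max()
    if peak <= 0:
        raise ValueError("all-zero response grid; cell excluded")
    gn = g / peak

    cols = (np.arange(5) - 2) * cell_size_deg
    rows = (2 - np.arange(5)) * cell_size_deg  # elevation decreases with row
    xg, yg = np.meshgrid(cols, rows)
    x, y = xg.ravel(), yg.ravel()
    z = gn.ravel()

    i0 = int(np.argmax(z))
    lim = 3 * cell_size_deg  # grid half-extent + one cell
    p0 = [x[i0], y[i0], cell_size_deg, cell_size_deg, 0.0, z.max() - z.min(), z.min()]
    lb = [-lim, -lim, 0.5, 0.5, -np.pi / 2, 0.0, 0.0]
    ub = [lim, lim, 5 * cell_size_deg, 5 * cell_size_deg, np.pi / 2, 2.0, 1.0]
    sol = least_squares(
        lambda p: _gauss2d_rot((x, y), *p) - z, x0=p0, bounds=(lb, ub), method="trf"
    )
    x0, y0, sx, sy, theta, amp, off = sol.x
    resnorm = float(np.sum(sol.fun**2))
    if sx < sy:  # report major axis first
        sx, sy = sy, sx
        theta += np.pi / 2
    return RFFit(
        center_deg=(float(x0), float(y0)),
        sigma_major_deg=float(sx),
        sigma_minor_deg=float(sy),
        rotation_deg=float(np.degrees((theta + np.pi / 2) % np.pi - np.pi / 2)),
        amplitude=float(amp),
        offset=float(off),
        resnorm=resnorm,
        accepted=resnorm < resnorm_threshold,
    )


def fit_sf(
    sf_cpd: np.ndarray,
    responses: np.ndarray,
    adj_r2_threshold: float = 0.8,
) -> SFFit:
    """Fit a log-Gaussian spatial-frequency tuning curve.

    The model peaks at 1 at the preferred SF and is symmetric in log2-SF
    (squared numerator in the exponent).  Responses are max-normalized;
    fits with adjusted R^2 <= 0.8 are rejected (2 free parameters).
    """
    sf = np.asarray(sf_cpd, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(sf) < 4:
        raise ValueError("need responses at >= 4 spatial frequencies")
    if not (np.all(np.isfinite(sf)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite spatial frequencies or responses")
    peak = y.max()
    if peak <= 0:
        raise ValueError("non-positive responses; cell excluded")
    yn = y / peak
    lsf = np.log2(sf)

    def model(p):
        lpref, sig = p
        return np.exp(-((lsf - lpref) ** 2) / (2 * sig**2))

    p0 = [lsf[int(np.argmax(yn))], 1.0]
    sol = least_squares(
        lambda p: model(p) - yn,
        x0=p0,
        bounds=([lsf.min() - 4, 0.05], [lsf.max() + 4, 20.0]),
        method="trf",
    )
    yhat = model(sol.x)
    adj = _adjusted_r2(yn, yhat, n_params=2)
    return SFFit(
        sf_pref_cpd=float(2 ** sol.x[0]),
        sigma_log2=float(sol.x[1]),
        adj_r2=float(adj),
        accepted=adj > adj_r2_threshold,
    )


def fit_contrast(
    contrast_percent: np.ndarray,
    responses: np.ndarray,
    adj_r2_threshold: float = 0.8,
) -> ContrastFit:
    """Fit a Naka-Rushton contrast-response function.

    R(c) = gain * c^n / (c^n + c50^n) on max-normalized responses, with
    c50 bounded in (0, 100)% and n in (0.1, 10).  The free gain is needed
    because max-normalized data place the highest sample at exactly 1
    while the saturating core always has R(100) < 1; pinning the asymptote
    would bias c50 downward by ~10%.  Fits with adjusted R^2 <= 0.8 are
    rejected (3 free parameters); monotone-decreasing response sets are
    flagged unreliable (the saturating model cannot describe them).
    """
    c = np.asarray(contrast_percent, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(c) < 4:
        raise ValueError("need responses at >= 4 contrast levels")
    order = np.argsort(c)
    monotone_dec = bool(np.all(np.diff(y[order]) <= 0) and y[order][0] > y[order][-1])
    peak = y.max()
    if peak <= 0:
        raise ValueError("non-positive responses; cell excluded")
    yn = y / peak

    def model(p):
        c50, n, gain = p
        with np.errstate(divide="ignore", invalid="ignore"):
            cn = np.where(c > 0, c, 0.0) ** n
            return gain * cn / (cn + c50**n)

    p0 = [30.0, 2.0, 1.0]
    sol = least_squares(
        lambda p: model(p) - yn,
        x0=p0,
        bounds=([1e-6, 0.1, 0.1], [100.0 - 1e-6, 10.0, 3.0]),
        method="trf",
    )
    yhat = model(sol.x)
    adj = _adjusted_r2(yn, yhat, n_params=3)
    return ContrastFit(
        c50_percent=float(sol.x[0]),
        n=float(sol.x[1]),
        adj_r2=float(adj),
        accepted=(adj > adj_r2_threshold) and not monotone_dec,
        monotone_decreasing=monotone_dec,
        gain=float(sol.x[2]),
    )
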