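"""Behavioral analyses: place learning, looming startle and habituation.

Place learning on the 1.5-m virtual linear track is read out from licking.
Licks split into post-reward bursts (starting within 3 s of a reward and
continuing while the instantaneous lick rate stays at or above 1 lick/s)
and exploratory licks.  Exploratory licks are binned into 5-cm position
bins; the first and last bin are excluded because the animal is
constrained at least 4 cm from the walls (habitable track 1.42 m, 28
bins).  Reward and control zones are 10 bins (+/-0.25 m) around their
centers, so chance-level zone licking is 10/28 = 35.71%.

Looming-stimulus responses are scored two ways: blinded human startle
scores (combined across two raters, threshold 1.5) with an exponential
habituation fit R(r) = R1*exp(-lambda*(r-1)) + b, and physiological
responses (treadmill velocity, eye pitch, pupil diameter) as baseline-
subtracted post-onset means averaged within each set of three looms.
Nonparametric tests: an exact-capable Mann-Whitney U and Cuzick's
rank-based trend test across ordered groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm, rankdata

__all__ = [
    "LickSession",
    "DecayFit",
    "classify_licks",
    "lick_position_map",
    "zone_preference",
    "probe_trial_split",
    "mann_whitney_u",
    "startle_classify",
    "fit_startle_decay",
    "loom_response_metrics",
    "cuzick_trend_test",
    "TRACK_LENGTH_M",
    "HABITABLE_LENGTH_M",
    "CHANCE_ZONE_FRACTION",
]

TRACK_LENGTH_M = 1.5
BIN_M = 0.05
N_BINS = 30                      # 1.5 m / 5 cm
N_HABITABLE_BINS = 28            # first and last bin excluded
WALL_MARGIN_M = 0.04
HABITABLE_LENGTH_M = TRACK_LENGTH_M - 2 * WALL_MARGIN_M  # 1.42 m
ZONE_BINS = 10                   # +/-0.25 m
CHANCE_ZONE_FRACTION = ZONE_BINS / N_HABITABLE_BINS      # 10/28


@dataclass
class LickSession:
    """One day's lick/reward/position record on the linear track."""

    lick_times_s: np.ndarray
    reward_times_s: np.ndarray
    t_s: np.ndarray
    pos_m: np.ndarray
    trial_bounds_s: list  # (start_s, end_s) per trial
    day: int = 1
    reward_zone_center_m: float = 0.5


def classify_licks(
    lick_times_s: np.ndarray,
    reward_times_s: np.ndarray,
    start_window_s: float = 3.0,
    max_interlick_s: float = 1.0,
) -> np.ndarray:
    """Label each lick ``post_reward`` or ``exploratory``.

    A post-reward burst starts at the first lick within ``start_window_s``
    of a reward delivery and extends while consecutive inter-lick intervals
    stay within ``max_interlick_s`` (rate >= 1 lick/s); every other lick is
    exploratory.  Each lick receives exactly one label.
    """
    licks = np.asarray(lick_times_s, dtype=float)
    rewards = np.asarray(reward_times_s, dtype=float)
    labels = np.array(["exploratory"] * len(licks), dtype=object)
    in_burst = np.zeros(len(licks), dtype=bool)
    for r in rewards:
        after = np.where((licks >= r) & (licks <= r + start_window_s) & ~in_burst)[0]
        if len(after) == 0:
            continue
        i = after[0]
        in_burst[i] = True
        while i + 1 < len(licks) and licks[i + 1] - licks[i] <= max_interlick_s:
            i += 1
            in_burst[i] = True
    labels[in_burst] = "post_reward"
    return labels


def lick_position_map(
    lick_times_s: np.ndarray,
    t_s: np.ndarray,
    pos_m: np.ndarray,
    bin_m: float = BIN_M,
    track_length_m: float = TRACK_LENGTH_M,
) -> dict:
    """Per-bin lick counts, dwell time, and lick rate over the track.

    30 bins of 5 cm; the first and last bin are excluded from the habitable
    set.  Rates are licks / dwell-time; interior bins with zero dwell are
    flagged undefined (NaN rate).
    """
    t_s = np.asarray(t_s, dtype=float)
    pos = np.asarray(pos_m, dtype=float)
    licks = np.asarray(lick_times_s, dtype=float)
    n_bins = int(round(track_length_m / bin_m))
    edges = np.arange(n_bins + 1) * bin_m
    dt = np.median(np.diff(t_s)) if len(t_s) > 1 else 0.0

    dwell, _ = np.histogram(pos, bins=edges)
    dwell = dwell * dt
    lick_pos = np.interp(licks, t_s, pos)
    counts, _ = np.histogram(lick_pos, bins=edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(dwell > 0, counts / np.where(dwell > 0, dwell, 1.0), np.nan)
    habitable = np.ones(n_bins, dtype=bool)
    habitable[0] = habitable[-1] = False
    return {
        "bin_edges_m": edges,
        "lick_counts": counts,
        "dwell_s": dwell,
        "lick_rate_hz": rate,
        "habitable": habitable,
    }


def zone_bins(zone_center_m: float, bin_m: float = BIN_M) -> np.ndarray:
    """Indices of the 10 position bins spanning +/-0.25 m of a zone center."""
    lo = zone_center_m - ZONE_BINS / 2 * bin_m
    first = int(round(lo / bin_m))
    return np.arange(first, first + ZONE_BINS)


def zone_preference(lick_map: dict, zone_center_m: float, bin_m: float = BIN_M) -> dict:
    """Fraction of (exploratory) licks falling in a 10-bin zone.

    The fraction is zone licks over all licks in the 28 habitable bins;
    chance level is 10/28 = 35.71%.  Raises if the zone is clipped by the
    track edge or leaves the habitable region.
    """
    bins = zone_bins(zone_center_m, bin_m)
    habitable = lick_map["habitable"]
    if bins.min() < 0 or bins.max() >= len(habitable) or not habitable[bins].all():
        raise ValueError("zone extends outside the habitable region")
    counts = lick_map["lick_counts"]
    total = counts[habitable].sum()
    in_zone = counts[bins].sum()
    frac = in_zone / total if total > 0 else np.nan
    return {
        "fraction": float(frac) if total > 0 else np.nan,
        "zone_licks": int(in_zone),
        "total_habitable_licks": int(total),
        "chance": CHANCE_ZONE_FRACTION,
    }


def probe_trial_split(
    trial_bounds_s: list,
    reward_times_s: np.ndarray,
) -> tuple[list, list]:
    """Partition trials into rewarded and (unrewarded) probe trials by the
    presence of any reward delivery inside the trial window."""
    rewards = np.asarray(reward_times_s, dtype=float)
    rewarded, probe = [], []
    for lo, hi in trial_bounds_s:
        if np.any((rewards >= lo) & (rewards < hi)):
            rewarded.append((lo, hi))
        else:
            probe.append((lo, hi))
    return rewarded, probe


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: number of (x_i, y_j) pairs with x_i > y_j (+0.5 for ties)."""
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return u


def mann_whitney_u(x, y, two_tailed: bool = True) -> tuple[float, float]:
    """Mann-Whitney U test.

    Exact p-value by full enumeration of group assignments when
    n_x + n_y <= 20 (valid with ties); otherwise the normal approximation
    with tie-corrected variance.  Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(x, y)
    n = nx + ny

    if n <= 20:
        pooled = np.concatenate([x, y])
        mu = nx * ny / 2.0
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if two_tailed:
                if abs(u - mu) >= dev_obs - 1e-12:
                    count += 1
            else:
                if u >= u_obs - 1e-12:
                    count += 1
        return u_obs, count / total

    ranks = rankdata(np.concatenate([x, y]))
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = nx * ny / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return u_obs, 1.0
    z = (u_obs - mu) / math.sqrt(var)
    if two_tailed:
        # continuity-free two-sided normal tail
        p = 2 * norm.sf(abs(z))
    else:
        p = norm.sf(z)
    return u_obs, float(min(p, 1.0))


REACTION_BEHAVIORS = ("startle", "tense_up")


def startle_classify(scores: dict, threshold: float = 1.5) -> dict:
    """Classify loom video clips as startle responses from rater scores.

    ``scores`` maps clip id -> {scorer -> {behavior -> confidence 0..3}}.
    Per scorer, the reaction score is max(startle, tense_up); the clip
    score is the mean over the two scorers, and clips scoring
    ``threshold`` or greater (ties included) are startles.  Clips missing
    a scorer are excluded and reported.
    """
    is_startle, clip_scores, excluded = {}, {}, []
    for clip, by_scorer in scores.items():
        if len(by_scorer) < 2:
            excluded.append(clip)
            continue
        reaction = []
        for scorer, beh in by_scorer.items():
            vals = [beh.get(b, 0) for b in REACTION_BEHAVIORS]
            if any(not (0 <= v <= 3 and float(v).is_integer()) for v in vals):
                raise ValueError(f"confidence scores must be integers 0..3 (clip {clip})")
            reaction.append(max(vals))
        score = float(np.mean(reaction))
        clip_scores[clip] = score
        is_startle[clip] = score >= threshold
    return {"is_startle": is_startle, "clip_scores": clip_scores, "excluded": excluded}


def startle_proportions(is_startle: dict, repetition_of: dict) -> dict:
    """Population startle proportion per stimulus repetition:
    startles / observations among clips at that repetition."""
    props: dict = {}
    for clip, flag in is_startle.items():
        r = repetition_of[clip]
        n, k = props.get(r, (0, 0))
        props[r] = (n + 1, k + int(flag))
    return {r: k / n for r, (n, k) in sorted(props.items())}


@dataclass(frozen=True)
class DecayFit:
    """Exponential habituation fit R(r) = R1*exp(-lambda*(r-1)) + b."""

    r1: float
    decay_rate: float
    offset: float
    degenerate: bool = False

    def predict(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return self.r1 * np.exp(-self.decay_rate * (r - 1)) + self.offset


def fit_startle_decay(repetitions, proportions) -> DecayFit:
    """Least-squares fit of the exponential habituation curve to startle
    proportions by repetition (R1 in [0,1], lambda >= 0, b in [0,1]).

    Constant data returns lambda = 0, flagged degenerate.
    """
    r = np.asarray(repetitions, dtype=float)
    y = np.asarray(proportions, dtype=float)
    if len(r) < 3:
        raise ValueError("need at least 3 repetitions")
    if np.allclose(y, y[0]):
        return DecayFit(r1=0.0, decay_rate=0.0, offset=float(y[0]), degenerate=True)

    def resid(p):
        r1, lam, b = p
        return r1 * np.exp(-lam * (r - 1)) + b - y

    p0 = [max(y[0] - y[-1], 0.1), 0.5, max(float(y[-1]), 0.0)]
    sol = least_squares(resid, x0=p0, bounds=([0, 0, 0], [1, 50, 1]), method="trf")
    return DecayFit(r1=float(sol.x[0]), decay_rate=float(sol.x[1]), offset=float(sol.x[2]))


def loom_response_metrics(
    t_s: np.ndarray,
    series: np.ndarray,
    onsets_s: np.ndarray,
    kind: str = "velocity",
    set_size: int = 3,
) -> dict:
    """Baseline-subtracted loom responses averaged within each set.

    Delta = mean over the post-onset window (2 s for velocity and eye
    pitch, 3 s for the slower pupil response) minus the 2-s pre-onset
    baseline mean, then averaged within consecutive sets of ``set_size``
    looms (left/right/center).  Onsets too close to the series edge are
    dropped.
    """
    windows = {"velocity": 2.0, "pitch": 2.0, "pupil": 3.0}
    if kind not in windows:
        raise ValueError("kind must be velocity|pitch|pupil")
    post_w = windows[kind]
    t_s = np.asarray(t_s, dtype=float)
    y = np.asarray(series, dtype=float)
    deltas, reps = [], []
    for i, onset in enumerate(np.atleast_1d(onsets_s)):
        if onset - 2.0 < t_s[0] or onset + post_w > t_s[-1]:
            continue
        pre = (t_s >= onset - 2.0) & (t_s < onset)
        post = (t_s >= onset) & (t_s < onset + post_w)
        deltas.append(y[post].mean() - y[pre].mean())
        reps.append(i)
    deltas = np.asarray(deltas)
    reps = np.asarray(reps)
    set_means = {}
    for s in np.unique(reps // set_size):
        set_means[int(s) + 1] = float(deltas[reps // set_size == s].mean())
    return {"delta": deltas, "repetition_index": reps, "set_means": set_means, "kind": kind}


def cuzick_trend_test(groups: list, one_sided: str = "decreasing") -> tuple[float, float]:
    """Cuzick's nonparametric test for trend across ordered groups.

    Observations are ranked jointly; the statistic T = sum_i l_i * W_i
    weights each group's rank sum W_i by its order score l_i = 1..k.  Under
    the null E[T] = L(N+1)/2 and Var[T] = (N+1)/12 * (N*sum n_i l_i^2 -
    L^2), shrunk by the standard tie-correction factor.  Returns (z, p)
    with a one-sided normal p in the stated direction ("increasing" or
    "decreasing"); identical data gives p = 0.5.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 ordered groups")
    if one_sided not in ("increasing", "decreasing"):
        raise ValueError("one_sided must be 'increasing' or 'decreasing'")
    gs = [np.asarray(g, dtype=float) for g in groups]
    all_vals = np.concatenate(gs)
    n_i = np.array([len(g) for g in gs])
    N = len(all_vals)
    ranks = rankdata(all_vals)
    scores = np.arange(1, len(gs) + 1, dtype=float)
    L = float(np.sum(n_i * scores))

    t_stat = 0.0
    start = 0
    for li, g in zip(scores, gs):
        t_stat += li * ranks[start : start + len(g)].sum()
        start += len(g)

    e_t = L * (N + 1) / 2.0
    var_t = (N + 1) / 12.0 * (N * float(np.sum(n_i * scores**2)) - L**2)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_factor = 1.0 - np.sum(tie_counts**3 - tie_counts) / (N**3 - N)
    var_t *= tie_factor
    if var_t <= 0:
        return 0.0, 0.5  # all values identical
    z = (t_stat - e_t) / math.sqrt(var_t)
    p = norm.sf(z) if one_sided == "increasing" else norm.cdf(z)
    return float(z), float(p)
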