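"""Small helpers shared across test modules."""

import numpy as np

from goggleskit.placefield import RateMap


def make_rate_map(rates, occupancy=None, bin_cm: float = 3.0) -> RateMap:
    """Build a RateMap directly from per-bin rates (uniform occupancy by
    default), for closed-form checks that bypass binning."""
    rates = np.asarray(rates, dtype=float)
    n = len(rates)
    p = (
        np.full(n, 1.0 / n)
        if occupancy is None
        else np.asarray(occupancy, dtype=float)
    )
    return RateMap(
        bin_centers_cm=(np.arange(n) + 0.5) * bin_cm,
        rate_hz=rates,
        occupancy=p,
        overall_rate_hz=float(np.sum(p * rates)),
        occupied=np.ones(n, dtype=bool),
        bin_cm=bin_cm,
    )
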