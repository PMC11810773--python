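"""Loom-evoked responses and pupil habituation across repetitions.

Simulates five mice through 15 looming stimuli (5 sets of 3), measures
baseline-relative changes in walking velocity, eye pitch and pupil
diameter per set, and tests for a declining trend with Cuzick's test.
Also fits the exponential habituation curve to startle-score proportions.
"""

import numpy as np

from goggleskit import behavior, synth

groups = {k: [[] for _ in range(5)] for k in ("velocity", "pitch", "pupil")}
for mouse in range(5):
    t, series, onsets, truth = synth.synth_loom_session(
        habituation_rate=0.5, seed=40 + mouse
    )
    for kind in groups:
        sm = behavior.loom_response_metrics(t, series[kind], onsets, kind=kind)
        for s, v in sm["set_means"].items():
            groups[kind][s - 1].append(v)

for kind, g in groups.items():
    z, p = behavior.cuzick_trend_test(g, one_sided="decreasing")
    means = ", ".join(f"{np.mean(x):+.2f}" for x in g)
    print(f"{kind:8s} set means [{means}]  Cuzick z={z:+.2f}, one-sided p={p:.3f}")
print("Only the pupil response habituates; velocity and pitch persist.\n")

# startle-proportion habituation across repetitions
reps = np.arange(1, 11)
props = 0.9 * np.exp(-0.6 * (reps - 1)) + 0.05
fit = behavior.fit_startle_decay(reps, props)
print(f"startle decay fit: R1={fit.r1:.2f}, lambda={fit.decay_rate:.2f}/rep, "
      f"offset={fit.offset:.2f} (first-loom proportion {fit.predict(1):.2f})")
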