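"""Lick-based readout of place learning over the 5-day protocol.

Simulates two mice (one that learns, one that does not), classifies licks
into post-reward bursts and exploratory licks, and measures reward-zone
lick preference on unrewarded probe trials against the 10/28 chance level.
"""

import numpy as np

from goggleskit import behavior, synth

for label, lr in (("learner", 1.0), ("non-learner", 0.0)):
    days, truth = synth.synth_lick_protocol("A", learning_rate=lr, seed=11)
    fracs = []
    for d in days:
        if d["day"] < 4:
            continue
        ev = d["events"]
        licks = np.array([e[0] for e in ev if e[1] == "lick"])
        lick_pos = np.array([e[2] for e in ev if e[1] == "lick"])
        rewards = np.array([e[0] for e in ev if e[1] == "reward"])
        labels = behavior.classify_licks(licks, rewards)
        probe = [b for b, f in zip(d["trial_bounds_s"], d["probe_flags"]) if f]
        sel = (labels == "exploratory") & np.any(
            [(licks >= lo) & (licks < hi) for lo, hi in probe], axis=0
        )
        counts, _ = np.histogram(lick_pos[sel], bins=np.arange(31) * 0.05)
        habitable = np.ones(30, dtype=bool)
        habitable[0] = habitable[-1] = False
        res = behavior.zone_preference(
            {"lick_counts": counts, "habitable": habitable},
            truth["zone_center_m"],
        )
        fracs.append(res["fraction"])
        print(f"{label}, day {d['day']}: {res['zone_licks']}/{res['total_habitable_licks']} "
              f"probe-trial exploratory licks in the reward zone "
              f"({100 * res['fraction']:.1f}%, chance {100 * res['chance']:.1f}%)")
    print(f"{label}: mean probe-zone preference {100 * np.mean(fracs):.1f}%\n")
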