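"""Saccade-latency quartile analysis.

For a good-preferring population with negative latency coupling on
contralateral good objects, splits each neuron's trials into latency
quartiles, correlates group order with window activity, and tests the
population median correlation against zero.
"""

import pandas as pd

from seqchoice import latency as lat
from seqchoice import spikes as spk
from seqchoice.synth import simulate_choice_session
from seqchoice.task import BehaviorPolicy, TaskConfig, default_archetypes

task = TaskConfig()
rows = []
for i in range(24):
    mk = "C" if i % 2 == 0 else "S"
    s = simulate_choice_session(
        task, BehaviorPolicy.from_reference(mk),
        default_archetypes()["cluster1_good"], n_trials=160, seed=900 + i,
        monkey_id=mk, neuron_id=f"n{i:03d}", with_eye=False)
    labeled = spk.per_trial_activity(s, trial_mask=s.trials["rt_ms"].notna())
    rows.append(labeled.assign(Neuron_ID=s.neuron_id)[
        ["Neuron_ID", "value", "direction", "rt_ms", "z"]])

table = lat.latency_correlation_table(pd.concat(rows, ignore_index=True),
                                      activity_col="z")
print("median latency-quartile correlation per condition:")
for (value, direction), sub in table.groupby(["value", "direction"]):
    res = lat.median_r_test(sub["r"].dropna())
    print(f"  {value:>4} {direction:>6}: median r = {res.median:+.3f}, "
          f"Wilcoxon p = {res.p:.4f} (n = {res.n})")
print("\nOnly the contra-good condition carries the latency coupling: its median")
print("correlation should be strongly negative (more activity -> faster saccade),")
print("the other conditions centered on zero.")
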