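"""Detect saccades and classify actions from the 1-kHz eye trace.

Simulates a session with fixational noise, runs the 40 deg/s velocity
detector and the geometric action classifier on every trial, and compares
the result with the commanded behavior.
"""

import numpy as np

from seqchoice.behavior import classify_action, detect_saccade
from seqchoice.synth import simulate_choice_session
from seqchoice.task import BehaviorPolicy, TaskConfig, default_archetypes

task = TaskConfig()
session = simulate_choice_session(
    task, BehaviorPolicy.from_reference("C"),
    default_archetypes()["cluster1_good"], n_trials=150, seed=3, noise_sd=0.3,
)

agree = 0
rt_errors = []
for row in session.trials.itertuples(index=False):
    target = (task.target_eccentricity * np.cos(np.radians(row.angle_deg)),
              task.target_eccentricity * np.sin(np.radians(row.angle_deg)))
    action = classify_action(session.eye, target, row.t_target_ms,
                             t_fp=row.t_fp_ms)
    agree += action == row.action
    if row.action in ("Accept", "Return"):
        onset = detect_saccade(session.eye, row.t_target_ms, search_window=600)
        if onset is not None:
            rt_errors.append(onset - row.t_saccade_go_ms)

print(f"classifier agreement with commanded actions: {agree}/{len(session.trials)}")
print(f"saccade onset error vs commanded RT: mean {np.mean(rt_errors):+.2f} ms, "
      f"max |err| {np.max(np.abs(rt_errors)):.2f} ms over {len(rt_errors)} saccades")
print("With 0.3 deg fixational noise, agreement should stay near 100% and the")
print("velocity-threshold onsets within ~2 ms of the commanded times.")
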