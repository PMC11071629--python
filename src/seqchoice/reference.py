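"""Published behavioral summary statistics used as generator defaults.

Two macaque subjects ("C" and "S") performed a sequential accept/reject
choice task in four scene conditions. The tables below are the printed
behavioral summaries of that dataset: per-scene saccade reaction-time
statistics toward good (rewarded) and bad (unrewarded) objects, and
per-scene counts of the action taken when a bad object was presented.
They parameterize the synthetic session generator and serve as inputs to
the behavioral summary computations.
"""

from __future__ import annotations

# Saccade reaction times (ms) per (monkey, scene, value): n, mean, sd.
# Good-object saccades are accept saccades; bad-object saccades are the
# outbound ("return go") saccades of return trials.
RT_REFERENCE: dict[tuple[str, int, str], tuple[int, float, float]] = {
    ("C", 1, "good"): (1428, 160.9, 21.6),
    ("C", 2, "good"): (1443, 162.6, 22.4),
    ("C", 3, "good"): (1452, 169.4, 22.1),
    ("C", 4, "good"): (1419, 165.5, 21.4),
    ("C", 1, "bad"): (1076, 234.3, 46.7),
    ("C", 2, "bad"): (1076, 240.0, 46.0),
    ("C", 3, "bad"): (1247, 215.0, 50.3),
    ("C", 4, "bad"): (1205, 221.3, 52.3),
    ("S", 1, "good"): (1466, 174.6, 20.8),
    ("S", 2, "good"): (1482, 179.1, 22.0),
    ("S", 3, "good"): (1490, 184.5, 21.4),
    ("S", 4, "good"): (1476, 186.9, 24.3),
    ("S", 1, "bad"): (1194, 302.1, 42.5),
    ("S", 2, "bad"): (1054, 311.9, 41.2),
    ("S", 3, "bad"): (1174, 291.2, 51.8),
    ("S", 4, "bad"): (1120, 299.9, 47.4),
}

ACTIONS = ("Accept", "Return", "Stay", "Other", "FixBreak")

# Counts of actions taken for bad objects per (monkey, scene):
# (total, accept, return, stay, other, fixbreak).
ACTION_COUNTS_REFERENCE: dict[tuple[str, int], tuple[int, int, int, int, int, int]] = {
    ("C", 1): (1479, 0, 1113, 314, 28, 24),
    ("C", 2): (1409, 1, 1100, 284, 15, 9),
    ("C", 3): (1396, 6, 1282, 94, 9, 5),
    ("C", 4): (1473, 6, 1253, 167, 13, 34),
    ("S", 1): (1602, 3, 1188, 376, 30, 5),
    ("S", 2): (1504, 2, 1063, 426, 6, 7),
    ("S", 3): (1475, 1, 1176, 287, 7, 4),
    ("S", 4): (1446, 5, 1130, 291, 15, 5),
}


def pooled_action_counts(monkey: str, scenes: tuple[int, ...]) -> tuple[int, ...]:
    """Pool action counts over scenes: (total, accept, return, stay, other, fixbreak)."""
    rows = [ACTION_COUNTS_REFERENCE[(monkey, s)] for s in scenes]
    return tuple(sum(col) for col in zip(*rows))
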