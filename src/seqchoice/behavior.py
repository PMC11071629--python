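"""Saccade detection, action classification, and behavioral statistics.

A saccade onset is the first sample whose two-dimensional eye speed —
central finite difference on the raw 1-kHz samples — exceeds 40 deg/s
within the search window after target onset. Each trial's action is then
classified geometrically:

* **Accept** — gaze enters the 8-deg-side target square and remains there
  for at least the 400-ms hold.
* **Return** — gaze enters the square, leaves it in under 400 ms, and
  comes back to within 4 deg of the central point.
* **Stay** — gaze never leaves a 4-deg-radius central zone during the
  decision window.
* **Other** — a saccade lands outside the target square and gaze does not
  return to center.
* **FixBreak** — gaze leaves the center before the object appears (choice
  task) or a saccade is made toward the presented object (fixation task).

Summary statistics mirror the published behavioral tables: per-scene
action counts/percentages for bad objects, Welch reaction-time contrasts
(good vs bad per scene, return-back saccades excluded), and the Fisher
exact test on stay proportions between stable (1, 2) and flexible (3, 4)
scenes.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .reference import ACTIONS, pooled_action_counts, ACTION_COUNTS_REFERENCE


class EyeDataError(ValueError):
    """Raised when the eye trace does not cover the requested window."""


def eye_speed(eye: pd.DataFrame) -> np.ndarray:
    """2D eye speed in deg/s via central differences on 1-ms samples.

    The first and last samples get one-sided differences.
    """
    x = eye["x_deg"].to_numpy(dtype=float)
    y = eye["y_deg"].to_numpy(dtype=float)
    vx = np.gradient(x)  # deg per ms
    vy = np.gradient(y)
    return np.hypot(vx, vy) * 1000.0


def detect_saccade(
    eye: pd.DataFrame,
    t_target: float,
    search_window: float = 400.0,
    threshold: float = 40.0,
) -> float | None:
    """First time in ``[t_target, t_target + search_window]`` at which eye
    speed strictly exceeds ``threshold`` (deg/s); ``None`` if it never does.
    """
    t = eye["t_ms"].to_numpy(dtype=float)
    i0 = int(np.searchsorted(t, t_target))
    i1 = int(np.searchsorted(t, t_target + search_window, side="right"))
    if i0 >= len(t) or t[i0] > t_target + 1.0 or i1 - i0 < 2:
        raise EyeDataError("eye trace does not cover the search window")
    seg = t[i0:i1]
    if np.any(np.diff(seg) > 1.5):
        raise EyeDataError("gap in eye trace inside the search window")
    # speed on a one-sample-padded slice so central differences match the
    # full-trace computation while staying O(window)
    j0, j1 = max(i0 - 1, 0), min(i1 + 1, len(t))
    sub = eye.iloc[j0:j1]
    speed = eye_speed(sub)[i0 - j0:i1 - j0]
    above = np.nonzero(speed > threshold)[0]
    if above.size == 0:
        return None
    return float(seg[above[0]])


def _inside_square(eye: pd.DataFrame, center: tuple[float, float], halfwidth: float) -> np.ndarray:
    return (
        (np.abs(eye["x_deg"].to_numpy() - center[0]) <= halfwidth)
        & (np.abs(eye["y_deg"].to_numpy() - center[1]) <= halfwidth)
    )


def classify_action(
    eye: pd.DataFrame,
    target_xy: tuple[float, float],
    t_target: float,
    accept_hold: float = 400.0,
    target_halfwidth: float = 4.0,
    t_fp: float | None = None,
    decision_window: float = 1000.0,
    center_radius: float = 4.0,
    threshold: float = 40.0,
) -> str:
    """Classify one trial's action from the gaze trace and target geometry."""
    if target_xy is None:
        raise ValueError("target geometry is required")
    # restrict to the trial's own span (keeps per-trial cost O(window) on
    # session-length traces)
    t_all = eye["t_ms"].to_numpy(dtype=float)
    anchors = [v for v in (t_fp, t_target) if v is not None and np.isfinite(v)]
    w0 = min(anchors) - 5.0 if anchors else t_all[0]
    w1 = (t_target if np.isfinite(t_target) else max(anchors, default=t_all[0]))
    w1 = w1 + decision_window + 900.0
    k0 = max(int(np.searchsorted(t_all, w0)) - 1, 0)
    k1 = min(int(np.searchsorted(t_all, w1, side="right")) + 1, len(t_all))
    eye = eye.iloc[k0:k1]
    t = eye["t_ms"].to_numpy(dtype=float)

    # fixation break: gaze leaves center between fixation and object onset
    if t_fp is not None:
        pre_end = t_target if np.isfinite(t_target) else t_fp + 1400.0
        pre_end = min(pre_end, t[-1] - 1)
        if pre_end - t_fp > 2:
            onset = detect_saccade(eye, t_fp, search_window=pre_end - t_fp - 1,
                                   threshold=threshold)
            if onset is not None:
                return "FixBreak"
    if not np.isfinite(t_target):
        return "Stay"

    onset = detect_saccade(eye, t_target, search_window=decision_window,
                           threshold=threshold)
    if onset is None:
        dist = np.hypot(eye["x_deg"].to_numpy(), eye["y_deg"].to_numpy())
        i0 = int(np.searchsorted(t, t_target))
        i1 = int(np.searchsorted(t, t_target + decision_window, side="right"))
        return "Stay" if np.all(dist[i0:i1] <= center_radius) else "Other"

    inside = _inside_square(eye, target_xy, target_halfwidth)
    i_on = int(np.searchsorted(t, onset))
    horizon = int(np.searchsorted(t, onset + 300.0, side="right"))
    entries = np.nonzero(inside[i_on:horizon])[0]
    if entries.size == 0:
        return "Other"
    i_enter = i_on + entries[0]
    exits = np.nonzero(~inside[i_enter:])[0]
    if exits.size == 0:
        dwell = t[-1] - t[i_enter]
        return "Accept" if dwell >= accept_hold else "Other"
    i_exit = i_enter + exits[0]
    dwell = t[i_exit] - t[i_enter]
    if dwell >= accept_hold:
        return "Accept"
    # exited early: did gaze come back to center?
    back_end = int(np.searchsorted(t, t[i_exit] + 400.0, side="right"))
    dist = np.hypot(eye["x_deg"].to_numpy(), eye["y_deg"].to_numpy())
    if np.any(dist[i_exit:back_end] <= center_radius):
        return "Return"
    return "Other"


@dataclass
class BehaviorSummary:
    """Per-scene and pooled action counts/percentages for bad-object trials,
    plus reaction-time statistics per (scene, value)."""

    counts: pd.DataFrame  # index: scene label; columns: Total + actions
    percentages: pd.DataFrame  # same layout, percent of scene total
    rt_stats: pd.DataFrame  # scene, value, n, mean, sd, ci_lo, ci_hi


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (the convention behind the printed percentages)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _count_table(trials: pd.DataFrame) -> pd.DataFrame:
    bad = trials[trials["value"] == "bad"]
    rows = {}
    scenes = sorted(bad["scene"].unique())
    for scene in scenes:
        sub = bad[bad["scene"] == scene]
        rows[f"Scene {scene}"] = [len(sub)] + [int((sub["action"] == a).sum()) for a in ACTIONS]
    for label, group in (("Non-switch (Scenes 1, 2)", (1, 2)), ("Switch (Scenes 3, 4)", (3, 4))):
        sub = bad[bad["scene"].isin(group)]
        if len(sub):
            rows[label] = [len(sub)] + [int((sub["action"] == a).sum()) for a in ACTIONS]
    return pd.DataFrame.from_dict(rows, orient="index", columns=["Total", *ACTIONS])


def summarize_actions(trials: pd.DataFrame) -> BehaviorSummary:
    """Build the behavioral summary from a labeled trial table.

    Percentages use all bad-object trials of the scene (fixation breaks
    included) as the denominator and are rounded half-up to one decimal.
    """
    counts = _count_table(trials)
    pct = counts[list(ACTIONS)].astype(float)
    for label in counts.index:
        total = counts.loc[label, "Total"]
        for a in ACTIONS:
            pct.loc[label, a] = round_half_up(100.0 * counts.loc[label, a] / total) if total else np.nan

    rt_rows = []
    for (scene, value), sub in trials.groupby(["scene", "value"]):
        rts = sub["rt_ms"].dropna().to_numpy(dtype=float)
        if value == "bad":  # only outbound return-go saccades carry an RT
            rts = sub.loc[sub["action"] == "Return", "rt_ms"].dropna().to_numpy(dtype=float)
        if rts.size == 0:
            continue
        mean = rts.mean()
        sd = rts.std(ddof=1) if rts.size > 1 else np.nan
        if rts.size > 1:
            half = stats.t.ppf(0.975, rts.size - 1) * sd / np.sqrt(rts.size)
        else:
            half = np.nan
        rt_rows.append((scene, value, rts.size, mean, sd, mean - half, mean + half))
    rt_stats = pd.DataFrame(
        rt_rows, columns=["scene", "value", "n", "mean_ms", "sd_ms", "ci_lo", "ci_hi"]
    )
    return BehaviorSummary(counts=counts, percentages=pct, rt_stats=rt_stats)


def summarize_reference_counts(monkey: str = "C") -> BehaviorSummary:
    """Behavioral summary computed from the published per-scene action
    counts (expanded to one pseudo-trial per counted action)."""
    rows = []
    for scene in (1, 2, 3, 4):
        total, *counts = ACTION_COUNTS_REFERENCE[(monkey, scene)]
        for action, c in zip(ACTIONS, counts):
            for _ in range(c):
                rows.append((scene, "bad", action, np.nan))
    trials = pd.DataFrame(rows, columns=["scene", "value", "action", "rt_ms"])
    return summarize_actions(trials)


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_good: float
    mean_bad: float
    sd_good: float
    sd_bad: float
    ci_diff: tuple[float, float]


def compare_rt_welch(rt_good, rt_bad) -> WelchResult:
    """Welch's unequal-variance t-test of good vs bad reaction times.

    Callers must pass only outbound (return-go) saccade RTs for the bad
    objects; return-back saccades are excluded upstream.
    """
    a = np.asarray(rt_good, dtype=float)
    b = np.asarray(rt_bad, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch test requires at least two observations per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    se = np.sqrt(va + vb)
    diff = a.mean() - b.mean()
    half = stats.t.ppf(0.975, df) * se
    return WelchResult(
        t=float(res.statistic), df=float(df), p=float(res.pvalue),
        mean_good=float(a.mean()), mean_bad=float(b.mean()),
        sd_good=float(a.std(ddof=1)), sd_bad=float(b.std(ddof=1)),
        ci_diff=(float(diff - half), float(diff + half)),
    )


@dataclass
class StayProportionResult:
    p_fisher: float
    phi: float
    ci_phi: tuple[float, float]
    table: tuple[tuple[int, int], tuple[int, int]]


def phi_coefficient(a: int, b: int, c: int, d: int) -> float:
    """phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) for a 2x2 table."""
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("phi undefined: a table margin is zero")
    return (a * d - b * c) / np.sqrt(denom)


def stay_proportion_test(
    counts_nonswitch: tuple[int, int],
    counts_switch: tuple[int, int],
) -> StayProportionResult:
    """Fisher exact test and phi for stay frequency, stable vs flexible scenes.

    Each tuple is ``(stay, other)`` where "other" is the comparison count
    (returns, or all non-stay trials, depending on how the table was built
    — see :func:`reference_stay_table`).
    """
    a, b = (int(v) for v in counts_nonswitch)
    c, d = (int(v) for v in counts_switch)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    phi = phi_coefficient(a, b, c, d)
    n = a + b + c + d
    z = np.arctanh(np.clip(phi, -1 + 1e-12, 1 - 1e-12))
    half = 1.959963984540054 / np.sqrt(max(n - 3, 1))
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return StayProportionResult(p_fisher=float(p), phi=float(phi), ci_phi=ci,
                                table=((a, b), (c, d)))


def reference_stay_table(
    monkey: str, mode: str = "stay-vs-return"
) -> tuple[tuple[int, int], tuple[int, int]]:
    """2x2 stay table from the published counts, stable vs flexible scenes.

    ``stay-vs-return`` compares Stay against Return counts;
    ``stay-vs-all`` compares Stay against all non-stay trials. The printed
    effect sizes are consistent with different constructions per subject,
    so both are provided.
    """
    ns = pooled_action_counts(monkey, (1, 2))
    sw = pooled_action_counts(monkey, (3, 4))
    # (total, accept, return, stay, other, fixbreak)
    if mode == "stay-vs-return":
        return (ns[3], ns[2]), (sw[3], sw[2])
    if mode == "stay-vs-all":
        return (ns[3], ns[0] - ns[3]), (sw[3], sw[0] - sw[3])
    raise ValueError(f"unknown mode {mode!r}")
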