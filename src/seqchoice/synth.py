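"""Synthetic session generator for the sequential accept/reject choice task.

Generates complete sessions — trial event tables, 1-kHz eye traces, and
inhomogeneous-Poisson spike trains — with the statistical structure the
downstream analysis assumes: reaction times and action frequencies drawn
from per-monkey behavioral policies, saccades embedded in the eye trace at
the commanded reaction time with peak speed far above the 40 deg/s
detection criterion, and spiking driven by one of three response
archetypes.

Conventions
-----------
* All times are in ms from session start; the eye trace is sampled on a
  1-ms grid.
* "contra" means the target's horizontal position falls in the visual
  hemifield opposite the simulated recording hemisphere (stored in session
  metadata; default left hemisphere, so contra = x > 0).
* Saccades follow a minimum-jerk position profile with duration
  ``20 ms + 1.5 ms/deg``; the commanded onset time is the instant the
  profile's speed crosses 40 deg/s, so threshold-based detection recovers
  the commanded reaction time to within a sample or two.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .task import (
    ACTIONS,
    BehaviorPolicy,
    ConfigurationError,
    NeuronArchetype,
    TaskConfig,
)

SACCADE_SPEED_THRESHOLD = 40.0  # deg/s
KERNEL_SUPPORT_MS = 2000.0  # response kernels are treated as zero beyond this

TRIAL_COLUMNS = [
    "trial_id", "scene", "value", "direction", "angle_deg",
    "t_scene_ms", "t_fp_ms", "t_target_ms",
    "t_saccade_go_ms", "t_saccade_back_ms",
    "action", "rt_ms", "reward", "rt_z",
]


class EyeAssemblyError(RuntimeError):
    """Raised when commanded saccades overlap in time."""


@dataclass
class Session:
    """One simulated recording session for a single neuron."""

    monkey_id: str
    neuron_id: str
    region: str  # Cd | Put
    hemisphere: str  # left | right
    task: str  # choice | fixation
    trials: pd.DataFrame
    spikes: np.ndarray  # sorted spike times, ms
    eye: pd.DataFrame | None  # columns t_ms, x_deg, y_deg
    seed: int
    archetype_label: str = ""
    config_hash: str = ""

    def __post_init__(self) -> None:
        if len(self.spikes) > 1 and np.any(np.diff(self.spikes) <= 0):
            raise ValueError("spike times must be strictly increasing")


def _saccade_duration_ms(amplitude_deg: float) -> float:
    return 20.0 + 1.5 * amplitude_deg


def _threshold_crossing_ms(amplitude_deg: float) -> float:
    """Time after movement start at which min-jerk speed crosses 40 deg/s."""
    dur = _saccade_duration_ms(amplitude_deg)
    peak_speed = 1.875 * amplitude_deg / dur * 1000.0  # deg/s
    if peak_speed <= SACCADE_SPEED_THRESHOLD:
        raise ConfigurationError(
            f"saccade of {amplitude_deg} deg never exceeds {SACCADE_SPEED_THRESHOLD} deg/s"
        )

    def speed(tau: float) -> float:
        return 30.0 * tau**2 * (1 - tau) ** 2 * amplitude_deg / dur * 1000.0

    tau_c = brentq(lambda u: speed(u) - SACCADE_SPEED_THRESHOLD, 1e-9, 0.5)
    return tau_c * dur


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    return 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5


def synthesize_eye_trace(
    trials: pd.DataFrame,
    task: TaskConfig,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_end: float | None = None,
    noise_tau_ms: float = 40.0,
) -> pd.DataFrame:
    """Assemble the 1-kHz gaze trace implied by a trial table.

    Fixation epochs hold the commanded point with slow Gaussian jitter of
    standard deviation ``noise_sd`` (correlation time ``noise_tau_ms``,
    emulating fixational drift rather than white sensor noise); saccades
    are minimum-jerk displacements timed so that the 40 deg/s speed
    crossing occurs at the commanded onset.
    """
    commands = _eye_commands(trials, task)
    if t_end is None:
        last = max((c["t_on"] + c["dur"] for c in commands), default=0.0)
        ev_cols = ["t_scene_ms", "t_fp_ms", "t_target_ms", "t_saccade_go_ms", "t_saccade_back_ms"]
        ev_max = np.nanmax(trials[ev_cols].to_numpy(dtype=float)) if len(trials) else 0.0
        t_end = max(last, ev_max) + 1000.0
    n = int(math.ceil(t_end)) + 1
    t = np.arange(n, dtype=float)
    x = np.zeros(n)
    y = np.zeros(n)

    commands = sorted(commands, key=lambda c: c["t_on"])
    prev_end = -np.inf
    cur = np.array([0.0, 0.0])
    pos = 0.0
    for cmd in commands:
        start = cmd["t_on"] - cmd["shift"]
        if start < prev_end - 1e-9:
            raise EyeAssemblyError(
                f"saccade commanded at {cmd['t_on']:.1f} ms overlaps the previous movement"
            )
        i0 = int(math.floor(start))
        i1 = min(int(math.ceil(start + cmd["dur"])), n - 1)
        x[int(pos):i0 + 1] = cur[0]
        y[int(pos):i0 + 1] = cur[1]
        tau = np.clip((t[i0:i1 + 1] - start) / cmd["dur"], 0.0, 1.0)
        s = _minimum_jerk(tau)
        target = np.asarray(cmd["to"], dtype=float)
        x[i0:i1 + 1] = cur[0] + (target[0] - cur[0]) * s
        y[i0:i1 + 1] = cur[1] + (target[1] - cur[1]) * s
        cur = target
        pos = i1
        prev_end = start + cmd["dur"]
    x[int(pos):] = cur[0]
    y[int(pos):] = cur[1]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + _smooth_jitter(rng, n, noise_sd, noise_tau_ms)
        y = y + _smooth_jitter(rng, n, noise_sd, noise_tau_ms)
    return pd.DataFrame({"t_ms": t, "x_deg": x, "y_deg": y})


def _smooth_jitter(rng: np.random.Generator, n: int, sd: float, tau_ms: float) -> np.ndarray:
    """Temporally correlated jitter: white noise low-passed with a Gaussian
    kernel of width ``tau_ms`` and rescaled to standard deviation ``sd``."""
    raw = rng.standard_normal(n + int(8 * tau_ms))
    k = np.exp(-0.5 * (np.arange(-4 * tau_ms, 4 * tau_ms + 1) / tau_ms) ** 2)
    sm = np.convolve(raw, k / k.sum(), mode="same")[: n]
    s = sm.std()
    return sm * (sd / s) if s > 0 else sm


def _target_xy(task: TaskConfig, angle_deg: float) -> tuple[float, float]:
    a = math.radians(angle_deg)
    return (task.target_eccentricity * math.cos(a), task.target_eccentricity * math.sin(a))


def _make_command(t_on: float, to_xy: tuple[float, float], from_xy: tuple[float, float]) -> dict:
    amp = math.hypot(to_xy[0] - from_xy[0], to_xy[1] - from_xy[1])
    return {
        "t_on": t_on,
        "to": to_xy,
        "dur": _saccade_duration_ms(amp),
        "shift": _threshold_crossing_ms(amp),
    }


def _eye_commands(trials: pd.DataFrame, task: TaskConfig) -> list[dict]:
    """Translate a trial table into an ordered list of saccade commands.

    Gaze always starts and ends each trial at the central fixation point.
    """
    commands: list[dict] = []
    center = (0.0, 0.0)
    for row in trials.itertuples(index=False):
        action = row.action
        tgt = _target_xy(task, row.angle_deg)
        if action == "Accept":
            go = row.t_saccade_go_ms
            commands.append(_make_command(go, tgt, center))
            dur = commands[-1]["dur"]
            # gaze returns to center during the inter-trial interval
            commands.append(_make_command(go + dur + task.accept_hold + 150.0, center, tgt))
        elif action == "Return":
            commands.append(_make_command(row.t_saccade_go_ms, tgt, center))
            commands.append(_make_command(row.t_saccade_back_ms, center, tgt))
        elif action == "Other":
            # saccade lands well outside the target window, then drifts back
            away_angle = row.angle_deg + 180.0
            away = _target_xy(task, away_angle)
            go = row.t_saccade_go_ms
            commands.append(_make_command(go, away, center))
            dur = commands[-1]["dur"]
            commands.append(_make_command(go + dur + 600.0, center, away))
        elif action == "FixBreak":
            go = row.t_saccade_go_ms
            away = _target_xy(task, row.angle_deg + 180.0)
            commands.append(_make_command(go, away, center))
            dur = commands[-1]["dur"]
            commands.append(_make_command(go + dur + 500.0, center, away))
        # Stay: no saccade
    return commands


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, size=remaining.size)
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def simulate_choice_session(
    task: TaskConfig,
    policy: BehaviorPolicy,
    archetype: NeuronArchetype,
    n_trials: int,
    seed: int,
    monkey_id: str = "C",
    neuron_id: str = "n000",
    region: str = "Cd",
    hemisphere: str = "left",
    with_eye: bool = True,
    noise_sd: float = 0.3,
) -> Session:
    """Simulate a full choice-task session for one neuron.

    Condition labels (scene, value, target angle) are drawn uniformly;
    actions are drawn from ``policy``; reaction times from truncated
    normals; the eye trace and spike train are consistent with the drawn
    events. Identical arguments give an identical session.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0,))
    s_beh, s_eye, s_spk = (np.random.default_rng(c) for c in ss.spawn(3))

    trials = _draw_choice_trials(task, policy, n_trials, s_beh, hemisphere)
    eye = None
    if with_eye:
        eye = synthesize_eye_trace(trials, task, noise_sd=noise_sd,
                                   seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31))
    spikes = simulate_spike_train(
        trials, archetype,
        seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31),
        task_kind="choice",
        rng=s_spk,
    )
    return Session(
        monkey_id=monkey_id, neuron_id=neuron_id, region=region,
        hemisphere=hemisphere, task="choice", trials=trials, spikes=spikes,
        eye=eye, seed=seed, archetype_label=archetype.label,
        config_hash=config_hash(task),
    )


def _draw_choice_trials(
    task: TaskConfig,
    policy: BehaviorPolicy,
    n_trials: int,
    rng: np.random.Generator,
    hemisphere: str,
) -> pd.DataFrame:
    rows = []
    t_cursor = 500.0
    action_names = list(ACTIONS)
    for i in range(n_trials):
        prep = rng.uniform(*task.prep_interval)
        t_scene = t_cursor + prep
        t_fp = t_scene + task.scene_free_view
        t_target = t_fp + task.fp_hold
        scene = int(rng.integers(1, task.n_scenes + 1))
        value = "good" if rng.random() < 0.5 else "bad"
        angle = float(task.target_angles[rng.integers(len(task.target_angles))])
        xsign = math.cos(math.radians(angle))
        contra_sign = 1.0 if hemisphere == "left" else -1.0
        direction = "contra" if xsign * contra_sign > 0 else "ipsi"

        probs = policy.action_probs[(value, scene)]
        p = np.array([probs.get(a, 0.0) for a in action_names])
        action = action_names[rng.choice(len(action_names), p=p / p.sum())]

        mu, sd = policy.rt_mean[(value, scene)], policy.rt_sd[(value, scene)]
        lo, hi = policy.rt_bounds[value]
        rt = float(_truncated_normal(rng, mu, sd, lo, hi, 1)[0])
        rt_z = float(np.clip((rt - mu) / sd, -3.0, 3.0))

        t_go = t_back = np.nan
        rt_out = np.nan
        reward = False
        if action == "Accept":
            t_go = t_target + rt
            rt_out = rt
            reward = value == "good"
            t_last = t_go + task.accept_hold + 200.0
        elif action == "Return":
            t_go = t_target + rt
            rt_out = rt
            dwell = rng.uniform(120.0, 300.0)
            amp = task.target_eccentricity
            t_back = t_go + _saccade_duration_ms(amp) + dwell
            t_last = t_back + 400.0
        elif action == "Stay":
            rt_z = 0.0
            t_last = t_target + 1000.0
        elif action == "Other":
            t_go = t_target + rt  # saccade away from the target, rt not recorded
            rt_out = np.nan
            t_last = t_go + 800.0
        else:  # FixBreak: gaze leaves center during the fixation hold
            rt_z = 0.0
            t_go = t_fp + rng.uniform(100.0, task.fp_hold - 150.0)
            t_target = np.nan
            t_last = t_go + 700.0

        rows.append((i, scene, value, direction, angle, t_scene, t_fp, t_target,
                     t_go, t_back, action, rt_out, reward, rt_z))
        t_cursor = t_last
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def evaluate_rate(
    times_ms: np.ndarray,
    trials: pd.DataFrame,
    archetype: NeuronArchetype,
    task_kind: str = "choice",
) -> np.ndarray:
    """Instantaneous firing rate (spikes/s) at ``times_ms``.

    The rate is baseline plus the event-aligned response kernels of every
    target/object presentation within ``KERNEL_SUPPORT_MS`` of each time,
    rectified at zero. Used by both the thinning sampler and the analytic
    expected-count oracle.
    """
    times = np.asarray(times_ms, dtype=float)
    rate = np.full(times.shape, archetype.baseline_rate)
    atten = archetype.fixation_attenuation if task_kind == "fixation" else 1.0

    ev = trials.dropna(subset=["t_target_ms"])
    if len(ev) == 0:
        return np.maximum(rate, 0.0)
    order = np.argsort(ev["t_target_ms"].to_numpy())
    ev_t = ev["t_target_ms"].to_numpy(dtype=float)[order]
    ev_val = ev["value"].to_numpy()[order]
    ev_dir = ev["direction"].to_numpy()[order]
    ev_z = ev["rt_z"].to_numpy(dtype=float)[order] if "rt_z" in ev else np.zeros(len(ev))

    idx = np.searchsorted(ev_t, times, side="right")
    for lag in (1, 2, 3):
        j = idx - lag
        valid = j >= 0
        if not np.any(valid):
            break
        dt = np.where(valid, times - ev_t[np.clip(j, 0, None)], np.inf)
        in_support = valid & (dt > 0) & (dt < KERNEL_SUPPORT_MS)
        if not np.any(in_support):
            continue
        jj = j[in_support]
        dts = dt[in_support]
        contrib = np.zeros(dts.shape)
        for (value, direction), kernels in archetype.kernels.items():
            mask = (ev_val[jj] == value) & (ev_dir[jj] == direction)
            if not np.any(mask):
                continue
            gain = np.ones(mask.sum())
            if archetype.latency_coupling != 0.0 and value == "good" and direction == "contra":
                gain = 1.0 + archetype.latency_coupling * ev_z[jj][mask]
                gain = np.maximum(gain, 0.0)
            for k in kernels:
                contrib[mask] += gain * k.evaluate(dts[mask])
        out = np.zeros(times.shape)
        out[in_support] = contrib
        rate = rate + atten * out
    return np.maximum(rate, 0.0)


def simulate_spike_train(
    trials: pd.DataFrame,
    archetype: NeuronArchetype,
    seed: int | None = None,
    task_kind: str = "choice",
    t_end: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample spike times by Poisson thinning of the archetype's rate.

    Candidate events are drawn from a homogeneous Poisson process at the
    archetype's rate bound and accepted with probability rate/bound, with
    the rate evaluated at 1-ms bin centers (matching the 1-ms PSTH
    resolution downstream). Returns sorted spike times, unique at 0.1-ms
    resolution.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if t_end is None:
        ev_cols = ["t_scene_ms", "t_fp_ms", "t_target_ms", "t_saccade_go_ms", "t_saccade_back_ms"]
        vals = trials[ev_cols].to_numpy(dtype=float)
        t_end = (np.nanmax(vals) if len(trials) else 0.0) + 1000.0
    bound = archetype.max_rate_bound()
    if bound <= 0:
        import warnings

        warnings.warn("rate is zero everywhere; returning an empty spike train")
        return np.empty(0)
    n_cand = rng.poisson(bound * t_end / 1000.0)
    cand = np.sort(rng.uniform(0.0, t_end, size=n_cand))
    bin_centers = np.floor(cand) + 0.5
    rate = evaluate_rate(bin_centers, trials, archetype, task_kind=task_kind)
    keep = rng.uniform(0.0, bound, size=n_cand) < rate
    spikes = cand[keep]
    spikes = np.unique(np.round(spikes, 1))
    return spikes


def simulate_fixation_session(
    task: TaskConfig,
    archetype: NeuronArchetype,
    n_trials: int,
    seed: int,
    monkey_id: str = "C",
    neuron_id: str = "n000",
    region: str = "Cd",
    hemisphere: str = "left",
    fixbreak_prob: float = 0.0,
    with_eye: bool = False,
    noise_sd: float = 0.3,
) -> Session:
    """Simulate a fixation-task session.

    Each trial presents the scene-1 good and bad objects alternately 2-4
    times to one side of the fixation point (400-ms presentations, 400-ms
    interstimulus intervals); responses are attenuated by the archetype's
    ``fixation_attenuation``. Occasional fix-break trials (saccade to the
    object) can be injected via ``fixbreak_prob``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    rows = []
    t_cursor = 500.0
    contra_sign = 1.0 if hemisphere == "left" else -1.0
    tid = 0
    for tid in range(n_trials):
        prep = rng.uniform(*task.prep_interval)
        t_scene = t_cursor + prep  # fixation point onset epoch marker
        t_fp = t_scene + 500.0
        n_pres = int(rng.integers(2, 5))
        side = 1.0 if rng.random() < 0.5 else -1.0
        first_value = "good" if rng.random() < 0.5 else "bad"
        breaks = rng.random() < fixbreak_prob
        break_at = int(rng.integers(n_pres)) if breaks else -1
        t_obj = t_fp + task.fp_hold
        for p in range(n_pres):
            value = first_value if p % 2 == 0 else ("bad" if first_value == "good" else "good")
            angle = 0.0 if side > 0 else 180.0
            direction = "contra" if side * contra_sign > 0 else "ipsi"
            action = "Stay"
            t_go = np.nan
            if p == break_at:
                action = "FixBreak"
                t_go = t_obj + rng.uniform(150.0, 300.0)
            rows.append((tid, 1, value, direction, angle, t_scene, t_fp, t_obj,
                         t_go, np.nan, action, np.nan, False, 0.0))
            if p == break_at:
                break
            t_obj += task.fixation_task_object_duration + task.fixation_task_isi
        t_cursor = t_obj + task.reward_delay_fixation + 400.0
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    eye = None
    if with_eye:
        eye = synthesize_eye_trace(trials, task, noise_sd=noise_sd, seed=seed + 1)
    spikes = simulate_spike_train(trials, archetype, seed=seed + 2, task_kind="fixation")
    return Session(
        monkey_id=monkey_id, neuron_id=neuron_id, region=region,
        hemisphere=hemisphere, task="fixation", trials=trials, spikes=spikes,
        eye=eye, seed=seed, archetype_label=archetype.label,
        config_hash=config_hash(task),
    )


# ---------------------------------------------------------------------------
# Session bundle I/O (events.tsv, spikes.tsv, eye.tsv, meta.json)

def config_hash(task: TaskConfig) -> str:
    payload = json.dumps(task.__dict__, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_session(session: Session, out_dir: str | Path) -> Path:
    """Write a session bundle: events.tsv, spikes.tsv, eye.tsv, meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(out / "events.tsv", sep="\t", index=False, float_format="%.4f")
    pd.DataFrame({"neuron_id": session.neuron_id, "t_ms": session.spikes}).to_csv(
        out / "spikes.tsv", sep="\t", index=False, float_format="%.1f"
    )
    if session.eye is not None:
        session.eye.to_csv(out / "eye.tsv", sep="\t", index=False, float_format="%.5f")
    meta = {
        "monkey_id": session.monkey_id,
        "neuron_id": session.neuron_id,
        "region": session.region,
        "hemisphere": session.hemisphere,
        "task": session.task,
        "seed": session.seed,
        "archetype_label": session.archetype_label,
        "config_hash": session.config_hash,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def read_session(in_dir: str | Path) -> Session:
    """Read a session bundle written by :func:`write_session`."""
    p = Path(in_dir)
    meta = json.loads((p / "meta.json").read_text())
    trials = pd.read_csv(p / "events.tsv", sep="\t")
    trials["value"] = trials["value"].astype(str)
    spikes = pd.read_csv(p / "spikes.tsv", sep="\t")["t_ms"].to_numpy(dtype=float)
    eye = None
    if (p / "eye.tsv").exists():
        eye = pd.read_csv(p / "eye.tsv", sep="\t")
    return Session(
        monkey_id=meta["monkey_id"], neuron_id=meta["neuron_id"],
        region=meta["region"], hemisphere=meta["hemisphere"], task=meta["task"],
        trials=trials, spikes=spikes, eye=eye, seed=meta["seed"],
        archetype_label=meta.get("archetype_label", ""),
        config_hash=meta.get("config_hash", ""),
    )
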