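"""Event-aligned PSTHs, Gaussian spike-density functions, and baseline
Z-normalization.

The processing chain is the standard one for trial-aligned single-unit
data: spikes are binned at 1 ms relative to an alignment event (scene,
target, or saccade onset), averaged over trials, smoothed with a unit-area
Gaussian kernel (sigma = 20 ms, truncated at +-4 sigma and renormalized),
and expressed as a Z-score against the per-trial baseline rate (mean and
SD of the firing rate in a window preceding the event). Neurons are
included only if their baseline rate — 1000 ms ending 500 ms before scene
onset — is below 10 spikes/s, the operational criterion for medium spiny
neurons.

All windows are half-open ``[start, end)`` in ms relative to the event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import Session

# Named analysis windows (ms relative to the alignment event). The
# post-event 100-300 ms window is the default for scene/target/saccade
# epochs; the alternative presets cover the perisaccadic (-150..50) and
# early-target (50..200) readouts used for specific figures.
WINDOW_PRESETS: dict[str, tuple[float, float]] = {
    "scene": (100.0, 300.0),
    "target": (100.0, 300.0),
    "saccade": (100.0, 300.0),
    "perisaccade_pre": (-150.0, 50.0),
    "target_early": (50.0, 200.0),
}


@dataclass
class AlignedPSTH:
    """Trials x bins spike-count matrix on a 1-ms grid around an event."""

    counts: np.ndarray  # (n_trials, n_bins) nonnegative ints
    bin_left_edges: np.ndarray  # ms relative to event, step 1
    align_event: str

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]


@dataclass
class NormalizedSDF:
    """Trial-averaged, baseline-Z-scored spike-density trace."""

    rate_z: np.ndarray
    time_ms: np.ndarray
    baseline_mean: float  # spikes/s
    baseline_sd: float  # spikes/s
    sigma: float  # ms
    degenerate: bool = False


class DegenerateBaselineError(ValueError):
    """Raised when the baseline SD is zero and no degenerate handling is on."""


def align_and_bin(
    spikes: np.ndarray,
    event_times: np.ndarray,
    window: tuple[float, float],
    align_event: str = "target",
) -> AlignedPSTH:
    """Bin spikes in 1-ms half-open bins relative to each event time.

    ``counts[i, b]`` counts spikes in ``[event_i + pre + b, event_i + pre + b + 1)``.
    """
    events = np.asarray(event_times, dtype=float)
    events = events[np.isfinite(events)]
    if events.size == 0:
        raise ValueError("event list is empty")
    pre, post = window
    if pre >= post:
        raise ValueError("window must satisfy pre < post")
    edges = np.arange(np.floor(pre), np.floor(post) + 1, 1.0)
    spikes = np.asarray(spikes, dtype=float)
    counts = np.empty((events.size, edges.size - 1), dtype=np.int64)
    for i, ev in enumerate(events):
        counts[i] = np.histogram(spikes - ev, bins=edges)[0]
    return AlignedPSTH(counts=counts, bin_left_edges=edges[:-1], align_event=align_event)


def gaussian_kernel(sigma: float, dt: float = 1.0) -> np.ndarray:
    """Unit-area Gaussian kernel truncated at +-4 sigma and renormalized."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = int(np.ceil(4.0 * sigma / dt))
    x = np.arange(-half, half + 1) * dt
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_sdf(psth: AlignedPSTH, sigma: float = 20.0) -> np.ndarray:
    """Trial-averaged spike-density trace in spikes/s.

    The mean 1-ms counts are convolved with the truncated, renormalized
    Gaussian kernel and scaled by 1000 (counts/ms -> spikes/s). Total area
    is conserved up to edge truncation.
    """
    kern = gaussian_kernel(sigma)
    mean_counts = psth.counts.mean(axis=0)
    return np.convolve(mean_counts, kern, mode="same") * 1000.0


def smooth_trials(psth: AlignedPSTH, sigma: float = 20.0) -> np.ndarray:
    """Per-trial spike-density traces (trials x bins) in spikes/s."""
    kern = gaussian_kernel(sigma)
    from scipy.signal import fftconvolve

    out = fftconvolve(psth.counts.astype(float), kern[None, :], mode="same", axes=1)
    return out * 1000.0


def baseline_stats(
    spikes: np.ndarray,
    event_times: np.ndarray,
    mode: str = "pre_event_500",
) -> tuple[float, float, bool]:
    """Across-trial mean and SD of the per-trial baseline firing rate.

    ``pre_event_500`` uses the 500 ms immediately before each event;
    ``pre_scene_1000`` uses the 1000 ms between 1500 and 500 ms before it
    (the inclusion-filter convention). Returns ``(mean, sd, degenerate)``
    where ``degenerate`` flags an SD of exactly zero.
    """
    if mode == "pre_event_500":
        win = (-500.0, 0.0)
    elif mode == "pre_scene_1000":
        win = (-1500.0, -500.0)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    psth = align_and_bin(spikes, event_times, win, align_event="baseline")
    dur_s = (win[1] - win[0]) / 1000.0
    per_trial = psth.counts.sum(axis=1) / dur_s  # spikes/s
    mean = float(per_trial.mean())
    sd = float(per_trial.std(ddof=0))
    return mean, sd, sd == 0.0


def zscore_sdf(
    sdf: np.ndarray,
    baseline: tuple[float, float],
    time_ms: np.ndarray | None = None,
    sigma: float = 20.0,
    allow_degenerate: bool = False,
) -> NormalizedSDF:
    """Z-score a spike-density trace against a baseline (mean, sd)."""
    mean, sd = baseline
    if sd <= 0:
        if not allow_degenerate:
            raise DegenerateBaselineError("baseline SD is zero")
        return NormalizedSDF(
            rate_z=np.zeros_like(sdf),
            time_ms=time_ms if time_ms is not None else np.arange(len(sdf)),
            baseline_mean=mean, baseline_sd=0.0, sigma=sigma, degenerate=True,
        )
    return NormalizedSDF(
        rate_z=(np.asarray(sdf, dtype=float) - mean) / sd,
        time_ms=time_ms if time_ms is not None else np.arange(len(sdf)),
        baseline_mean=mean, baseline_sd=sd, sigma=sigma,
    )


def window_mean(
    trace: np.ndarray,
    window: tuple[float, float],
    time_ms: np.ndarray,
) -> float:
    """Arithmetic mean of ``trace`` over the half-open window ``[start, end)``."""
    start, end = window
    t = np.asarray(time_ms, dtype=float)
    mask = (t >= start) & (t < end)
    if not np.any(mask):
        raise ValueError("window contains no samples")
    return float(np.asarray(trace, dtype=float)[mask].mean())


def inclusion_filter(session: Session, threshold: float = 10.0) -> bool:
    """True iff the neuron's baseline rate (1000 ms ending 500 ms before
    scene onset) is strictly below ``threshold`` spikes/s."""
    events = session.trials["t_scene_ms"].to_numpy(dtype=float)
    mean, _, _ = baseline_stats(session.spikes, events, mode="pre_scene_1000")
    return mean < threshold


# ---------------------------------------------------------------------------
# Activity tables (long format, one row per neuron x condition cell)

_ALIGN_COLUMNS = {
    "scene_onset": "t_scene_ms",
    "target_onset": "t_target_ms",
    "saccade_onset": "t_saccade_go_ms",
    "saccade_back": "t_saccade_back_ms",
}


def per_trial_activity(
    session: Session,
    align: str = "target_onset",
    window: tuple[float, float] = (100.0, 300.0),
    sigma: float = 20.0,
    trial_mask: pd.Series | None = None,
) -> pd.DataFrame:
    """Baseline-Z-scored window activity per trial, with trial labels.

    Returns the trial table (rows with a defined alignment event) plus a
    ``z`` column; empty if the baseline is degenerate (SD = 0).
    """
    col = _ALIGN_COLUMNS[align]
    trials = session.trials
    if trial_mask is not None:
        trials = trials[trial_mask]
    trials = trials.dropna(subset=[col])
    if len(trials) == 0:
        return trials.assign(z=pd.Series(dtype=float))
    events = trials[col].to_numpy(dtype=float)

    pad = 4 * sigma
    lo = min(window[0], 0.0) - pad - 500.0
    hi = max(window[1], 0.0) + pad
    psth = align_and_bin(session.spikes, events, (lo, hi), align_event=align)
    traces = smooth_trials(psth, sigma=sigma)
    time_ms = psth.bin_left_edges + 0.5
    mask = (time_ms >= window[0]) & (time_ms < window[1])
    per_trial = traces[:, mask].mean(axis=1)

    b_mean, b_sd, degen = baseline_stats(session.spikes, events, mode="pre_event_500")
    if degen:
        return trials.iloc[0:0].assign(z=pd.Series(dtype=float))
    out = trials.copy()
    out["z"] = (per_trial - b_mean) / b_sd
    return out


def neuron_condition_activity(
    session: Session,
    align: str = "target_onset",
    window: tuple[float, float] = (100.0, 300.0),
    sigma: float = 20.0,
    by: tuple[str, ...] = ("scene", "value", "direction"),
    trial_mask: pd.Series | None = None,
    min_trials: int = 1,
) -> pd.DataFrame:
    """Mean baseline-Z-scored window activity per condition cell.

    Per-trial spike-density traces aligned at the event are averaged over
    the window; the per-trial values are Z-scored against the across-trial
    baseline statistics (500 ms pre-event) and averaged within each
    condition cell. Returns one row per cell.
    """
    labeled = per_trial_activity(
        session, align=align, window=window, sigma=sigma, trial_mask=trial_mask
    )
    if len(labeled) == 0:
        return pd.DataFrame(columns=[*by, "NeuronalActivity", "n_trials"])
    df = labeled[[*by, "z"]].copy()
    rows = []
    for keys, sub in df.groupby(list(by), observed=True):
        if len(sub) < min_trials:
            continue
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append((*keys, float(sub["z"].mean()), len(sub)))
    return pd.DataFrame(rows, columns=[*by, "NeuronalActivity", "n_trials"])


def build_activity_table(
    sessions: list[Session],
    align: str = "target_onset",
    window: tuple[float, float] = (100.0, 300.0),
    sigma: float = 20.0,
    epoch: str | None = None,
    by: tuple[str, ...] = ("scene", "value", "direction"),
    min_trials: int = 1,
    apply_inclusion: bool = False,
) -> pd.DataFrame:
    """Long-format activity table over sessions (the mixed model's input).

    Columns: the condition factors, NeuronalActivity, monkey_ID, Neuron_ID,
    epoch. One row per neuron x condition cell.
    """
    frames = []
    for s in sessions:
        if apply_inclusion and not inclusion_filter(s):
            continue
        cells = neuron_condition_activity(
            s, align=align, window=window, sigma=sigma, by=by, min_trials=min_trials
        )
        if len(cells) == 0:
            continue
        cells["monkey_ID"] = s.monkey_id
        cells["Neuron_ID"] = s.neuron_id
        cells["epoch"] = epoch or align
        frames.append(cells)
    if not frames:
        return pd.DataFrame(
            columns=[*by, "NeuronalActivity", "n_trials", "monkey_ID", "Neuron_ID", "epoch"]
        )
    return pd.concat(frames, ignore_index=True)
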