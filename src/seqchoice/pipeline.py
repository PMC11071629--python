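"""End-to-end orchestration: generate a synthetic population, run every
analysis stage, and write a reproducible artifact directory.

Stages, in order: session synthesis (choice + fixation per neuron, three
response archetypes across two subjects) -> behavioral summary and tests
-> activity tables -> silhouette/k-means response-type clustering ->
parametric-bootstrap mixed-model comparisons with Bonferroni post-hocs ->
latency-quartile correlation analysis -> the proactive/reactive contrast
(Return vs Stay during choice, good vs bad during fixation).

Everything is deterministic under the config seed; every written file's
SHA-256 is logged in ``hashes.json``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import cluster as clu
from . import latency as lat
from . import mixedstats as mx
from . import spikes as spk
from .synth import Session, simulate_choice_session, simulate_fixation_session
from .task import BehaviorPolicy, TaskConfig, default_archetypes

ARCHETYPE_ORDER = ("cluster1_good", "cluster2_bad", "cluster3_visual")


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-population run."""

    seed: int = 0
    n_neurons: tuple[int, int, int] = (19, 16, 26)  # per archetype
    n_choice_trials: int = 288
    n_fixation_trials: int = 40
    n_eye_sessions: int = 2  # sessions that get a full eye trace + classifier pass
    monkeys: tuple[str, ...] = ("C", "S")
    window: tuple[float, float] = (100.0, 300.0)
    sigma: float = 20.0
    n_boot: int = 199
    k_mode: str = "auto"  # 'auto' (silhouette scan) or an integer
    phi_mode: str = "stay-vs-return"
    separation: float = 1.0  # archetype effect-size multiplier
    noise_sd: float = 0.3

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class ContrastReport:
    """Reject-mode / task contrast per cluster and side."""

    cells: pd.DataFrame  # cluster, side, cell, mean
    posthoc: pd.DataFrame
    comparisons: list[dict]
    flags: dict = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def generate_population(
    config: PipelineConfig,
    with_fixation: bool = True,
) -> tuple[list[Session], list[Session], dict[str, str]]:
    """Simulate the choice (and optionally fixation) sessions of the
    population. Returns (choice_sessions, fixation_sessions, truth) where
    ``truth`` maps neuron_id -> generating archetype label."""
    task = TaskConfig()
    archetypes = default_archetypes()
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(42,))
    choice, fixation, truth = [], [], {}
    idx = 0
    for label, n_arch in zip(ARCHETYPE_ORDER, config.n_neurons):
        arch = archetypes[label]
        if config.separation != 1.0:
            arch = arch.scaled(config.separation)
        for j in range(n_arch):
            monkey = config.monkeys[idx % len(config.monkeys)]
            nid = f"n{idx:03d}"
            seed_c = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
            policy = BehaviorPolicy.from_reference(monkey)
            with_eye = idx < config.n_eye_sessions
            choice.append(simulate_choice_session(
                task, policy, arch, n_trials=config.n_choice_trials,
                seed=seed_c, monkey_id=monkey, neuron_id=nid,
                region="Cd" if j % 2 == 0 else "Put",
                with_eye=with_eye, noise_sd=config.noise_sd,
            ))
            if with_fixation:
                seed_f = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
                fixation.append(simulate_fixation_session(
                    task, arch, n_trials=config.n_fixation_trials,
                    seed=seed_f, monkey_id=monkey, neuron_id=nid,
                ))
            truth[nid] = label
            idx += 1
    return choice, fixation, truth


def run_behavior_stage(choice_sessions: list[Session], config: PipelineConfig) -> dict:
    """Behavioral summary on pooled trials; classifier validation on the
    sessions that carry an eye trace; Welch RT and stay-proportion tests."""
    task = TaskConfig()
    all_trials = pd.concat([s.trials for s in choice_sessions], ignore_index=True)
    summary = beh.summarize_actions(all_trials)

    n_checked = n_agree = 0
    for s in choice_sessions:
        if s.eye is None:
            continue
        for row in s.trials.itertuples(index=False):
            tgt = (
                task.target_eccentricity * np.cos(np.radians(row.angle_deg)),
                task.target_eccentricity * np.sin(np.radians(row.angle_deg)),
            )
            detected = beh.classify_action(
                s.eye, tgt, row.t_target_ms, t_fp=row.t_fp_ms,
                accept_hold=task.accept_hold,
                target_halfwidth=task.target_halfwidth,
            )
            n_checked += 1
            n_agree += detected == row.action

    welch = {}
    for scene in sorted(all_trials["scene"].unique()):
        sub = all_trials[all_trials["scene"] == scene]
        good = sub.loc[(sub["value"] == "good") & (sub["action"] == "Accept"), "rt_ms"].dropna()
        bad = sub.loc[(sub["value"] == "bad") & (sub["action"] == "Return"), "rt_ms"].dropna()
        if len(good) >= 2 and len(bad) >= 2:
            w = beh.compare_rt_welch(good, bad)
            welch[str(scene)] = {"t": w.t, "df": w.df, "p": w.p,
                                 "mean_good": w.mean_good, "mean_bad": w.mean_bad}

    bad = all_trials[all_trials["value"] == "bad"]
    ns = bad[bad["scene"].isin((1, 2))]
    sw = bad[bad["scene"].isin((3, 4))]
    if config.phi_mode == "stay-vs-return":
        tbl = ((int((ns["action"] == "Stay").sum()), int((ns["action"] == "Return").sum())),
               (int((sw["action"] == "Stay").sum()), int((sw["action"] == "Return").sum())))
    else:
        tbl = ((int((ns["action"] == "Stay").sum()), int((ns["action"] != "Stay").sum())),
               (int((sw["action"] == "Stay").sum()), int((sw["action"] != "Stay").sum())))
    fisher = beh.stay_proportion_test(*tbl)

    return {
        "summary": summary,
        "classifier_agreement": (n_agree / n_checked) if n_checked else None,
        "welch": welch,
        "fisher": {"p": fisher.p_fisher, "phi": fisher.phi, "table": fisher.table,
                   "mode": config.phi_mode},
    }


def reject_mode_contrast(
    choice_sessions: list[Session],
    fixation_sessions: list[Session],
    cluster_of: dict[str, int],
    window: tuple[float, float] = (100.0, 300.0),
    sigma: float = 20.0,
    n_boot: int = 199,
    seed: int = 0,
    min_trials_per_cell: int = 4,
    pool_sides: bool = False,
) -> ContrastReport:
    """Proactive vs reactive inhibition contrast.

    For each cluster and side, builds the four-cell activity table
    {Return-choice, Stay-choice, Good-fixation, Bad-fixation} restricted
    to scene-1 trials (where object values are constant) and runs the
    parametric-bootstrap model comparison plus the six pairwise post-hoc
    contrasts. Neurons enter a side's analysis only with at least
    ``min_trials_per_cell`` trials in every cell (cell means from very few
    trials have inflated sampling variance, which the homoscedastic cell-
    mean model would mistake for real modulation); ``pool_sides`` merges
    contra and ipsi trials, roughly doubling the trials behind the scarce
    Stay cells. Flags summarize the qualitative pattern: Return ~ Stay,
    and choice above fixation.
    """
    fix_by_id = {s.neuron_id: s for s in fixation_sessions}
    rows = []
    for s in choice_sessions:
        cl = cluster_of.get(s.neuron_id)
        if cl is None:
            continue
        mask = (s.trials["scene"] == 1) & (s.trials["value"] == "bad") \
            & s.trials["action"].isin(["Return", "Stay"])
        labeled = spk.per_trial_activity(s, align="target_onset", window=window,
                                         sigma=sigma, trial_mask=mask)
        for row in labeled.itertuples(index=False):
            rows.append((s.monkey_id, s.neuron_id, cl, row.direction,
                         f"{row.action}_choice", row.z))
        fx = fix_by_id.get(s.neuron_id)
        if fx is None:
            continue
        fl = spk.per_trial_activity(fx, align="target_onset", window=window, sigma=sigma)
        for row in fl.itertuples(index=False):
            rows.append((fx.monkey_id, fx.neuron_id, cl, row.direction,
                         f"{row.value.capitalize()}_fixation", row.z))
    per_trial = pd.DataFrame(
        rows, columns=["monkey_ID", "Neuron_ID", "cluster", "side", "cell", "z"]
    )
    if pool_sides and len(per_trial):
        per_trial["side"] = "both"
    if len(per_trial) == 0:
        return ContrastReport(cells=pd.DataFrame(), posthoc=pd.DataFrame(),
                              comparisons=[], flags={"empty": True})
    grouped = per_trial.groupby(
        ["monkey_ID", "Neuron_ID", "cluster", "side", "cell"], observed=True
    )["z"].agg(["mean", "size"]).reset_index()
    grouped = grouped[grouped["size"] >= min_trials_per_cell]
    cell_means = grouped.rename(columns={"mean": "NeuronalActivity"}).drop(columns="size")

    cell_names = ["Return_choice", "Stay_choice", "Good_fixation", "Bad_fixation"]
    contrast_spec = [
        (f"({a}) vs ({b})", [(a,)], [(b,)]) for a, b in combinations(cell_names, 2)
    ]
    posthoc_frames, comparisons, flags = [], [], {}
    for (cl, side), sub in cell_means.groupby(["cluster", "side"], observed=True):
        complete = sub.groupby("Neuron_ID")["cell"].nunique() == len(cell_names)
        keep = complete[complete].index
        sub = sub[sub["Neuron_ID"].isin(keep)]
        if sub["Neuron_ID"].nunique() < 3:
            comparisons.append({"cluster": int(cl), "side": side,
                                "skipped": "too few complete neurons"})
            continue
        cmp_res = mx.parametric_bootstrap_compare(
            sub, factors=("cell",), n_boot=n_boot,
            seed=seed + 1000 * int(cl) + (0 if side == "contra" else 1),
        )
        fit = mx.fit_cellmeans_lmm(sub, factors=("cell",))
        ph = mx.posthoc_pairwise(fit, contrast_spec, m=6)
        ph.insert(0, "cluster", int(cl))
        ph.insert(1, "side", side)
        posthoc_frames.append(ph)
        comparisons.append({"cluster": int(cl), "side": side,
                            "p_boot": cmp_res.p_boot,
                            "observed_diff": cmp_res.observed_diff})
        alpha = 0.05 / 6
        rs = ph.set_index("contrast")
        key = "(Return_choice) vs (Stay_choice)"
        if key in rs.index:
            flags[f"cluster{cl}_{side}_return_eq_stay"] = bool(
                rs.loc[key, "p_raw"] >= alpha
            )
        cvf = [
            "(Return_choice) vs (Good_fixation)", "(Return_choice) vs (Bad_fixation)",
            "(Stay_choice) vs (Good_fixation)", "(Stay_choice) vs (Bad_fixation)",
        ]
        present = [k for k in cvf if k in rs.index]
        if present:
            flags[f"cluster{cl}_{side}_choice_gt_fixation"] = bool(
                all(rs.loc[k, "p_raw"] < alpha and rs.loc[k, "t"] > 0 for k in present)
            )
    posthoc = pd.concat(posthoc_frames, ignore_index=True) if posthoc_frames else pd.DataFrame()
    return ContrastReport(cells=cell_means, posthoc=posthoc,
                          comparisons=comparisons, flags=flags)


def run_full(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage and write the artifact directory. Deterministic
    under ``config.seed``; aborts with a stage-tagged error on failure."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    try:
        choice, fixation, truth = generate_population(config)
    except Exception as e:  # noqa: BLE001
        raise StageError("synth", e)

    try:
        b = run_behavior_stage(choice, config)
        b["summary"].counts.to_csv(out / "behavior_summary.tsv", sep="\t")
        artifacts["behavior_summary"] = out / "behavior_summary.tsv"
        (out / "behavior_tests.json").write_text(json.dumps({
            "classifier_agreement": b["classifier_agreement"],
            "welch": b["welch"], "fisher": b["fisher"],
        }, indent=1, default=str))
        artifacts["behavior_tests"] = out / "behavior_tests.json"
    except Exception as e:  # noqa: BLE001
        raise StageError("behavior", e)

    try:
        activity = spk.build_activity_table(
            choice, align="target_onset", window=config.window,
            sigma=config.sigma, epoch="target_onset", apply_inclusion=True,
        )
        _require_columns(activity, ("scene", "value", "direction",
                                    "NeuronalActivity", "monkey_ID", "Neuron_ID"))
        activity.to_csv(out / "activity_table.tsv", sep="\t", index=False)
        artifacts["activity_table"] = out / "activity_table.tsv"
    except Exception as e:  # noqa: BLE001
        raise StageError("spikes", e)

    try:
        features = clu.build_features(activity)
        k = config.k_mode if config.k_mode == "auto" else int(config.k_mode)
        result = clu.cluster_neurons(features, k=k, seed=config.seed)
        clusters = pd.DataFrame({
            "neuron_id": result.neuron_ids,
            "cluster": result.labels,
            "z_good_contra": features["z_good_contra"],
            "z_bad_contra": features["z_bad_contra"],
            "archetype": [truth[n] for n in result.neuron_ids],
        })
        clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
        artifacts["clusters"] = out / "clusters.tsv"
        (out / "silhouette.json").write_text(json.dumps(
            {"k": result.k, "silhouette_by_k": result.silhouette_by_k}, indent=1))
        artifacts["silhouette"] = out / "silhouette.json"
    except Exception as e:  # noqa: BLE001
        raise StageError("cluster", e)

    try:
        cluster_of = dict(zip(clusters["neuron_id"], clusters["cluster"]))
        comparisons = {}
        posthoc_frames = []
        for cl in sorted(clusters["cluster"].unique()):
            ids = clusters.loc[clusters["cluster"] == cl, "neuron_id"]
            sub = activity[activity["Neuron_ID"].isin(ids)]
            if sub["Neuron_ID"].nunique() < 3:
                continue
            cmp_res = mx.parametric_bootstrap_compare(
                sub, factors=("scene", "value", "direction"),
                n_boot=config.n_boot, seed=config.seed + int(cl),
            )
            comparisons[f"cluster{cl}"] = {
                "p_boot": cmp_res.p_boot,
                "observed_diff": cmp_res.observed_diff,
                "deviance_full": cmp_res.deviance_full,
                "deviance_null": cmp_res.deviance_null,
                "n_boot": cmp_res.n_boot,
            }
            fit = mx.fit_cellmeans_lmm(sub, factors=("scene", "value", "direction"))
            fam = mx.value_direction_contrasts() + mx.scene_contrasts()
            ph = mx.posthoc_pairwise(fit, fam, m=12)
            ph.insert(0, "cluster", int(cl))
            posthoc_frames.append(ph)
        (out / "model_comparison.json").write_text(json.dumps(comparisons, indent=1))
        artifacts["model_comparison"] = out / "model_comparison.json"
        posthoc = pd.concat(posthoc_frames, ignore_index=True) if posthoc_frames else pd.DataFrame()
        posthoc.to_csv(out / "posthoc_table.tsv", sep="\t", index=False)
        artifacts["posthoc_table"] = out / "posthoc_table.tsv"
    except Exception as e:  # noqa: BLE001
        raise StageError("mixedstats", e)

    try:
        lat_rows = []
        for s in choice:
            mask = s.trials["rt_ms"].notna()
            labeled = spk.per_trial_activity(
                s, align="target_onset", window=config.window,
                sigma=config.sigma, trial_mask=mask,
            )
            labeled = labeled.assign(Neuron_ID=s.neuron_id)
            lat_rows.append(labeled[["Neuron_ID", "value", "direction", "rt_ms", "z"]])
        lat_input = pd.concat(lat_rows, ignore_index=True)
        lat_table = lat.latency_correlation_table(lat_input, activity_col="z")
        lat_table.to_csv(out / "latency_correlation.tsv", sep="\t", index=False)
        artifacts["latency_correlation"] = out / "latency_correlation.tsv"
        lat_tests = {}
        for (value, direction), sub in lat_table.groupby(["value", "direction"]):
            for cl in sorted(clusters["cluster"].unique()):
                ids = set(clusters.loc[clusters["cluster"] == cl, "neuron_id"])
                rs = sub.loc[sub["Neuron_ID"].isin(ids), "r"].dropna()
                if len(rs) >= 6:
                    res = lat.median_r_test(rs)
                    lat_tests[f"cluster{cl}_{value}_{direction}"] = {
                        "median_r": res.median, "p": res.p, "n": res.n,
                        "method": res.method,
                    }
        (out / "latency_test.json").write_text(json.dumps(lat_tests, indent=1))
        artifacts["latency_test"] = out / "latency_test.json"
    except Exception as e:  # noqa: BLE001
        raise StageError("latency", e)

    try:
        report = reject_mode_contrast(
            choice, fixation, cluster_of, window=config.window,
            sigma=config.sigma, n_boot=config.n_boot, seed=config.seed,
        )
        (out / "contrast_report.json").write_text(json.dumps({
            "comparisons": report.comparisons, "flags": report.flags,
        }, indent=1, default=float))
        artifacts["contrast_report"] = out / "contrast_report.json"
        if len(report.posthoc):
            report.posthoc.to_csv(out / "contrast_posthoc.tsv", sep="\t", index=False)
            artifacts["contrast_posthoc"] = out / "contrast_posthoc.tsv"
    except Exception as e:  # noqa: BLE001
        raise StageError("contrast", e)

    _write_report(out, config, b, clusters, comparisons, lat_tests, report)
    artifacts["report"] = out / "report.md"

    hashes = {name: hashlib.sha256(p.read_bytes()).hexdigest()
              for name, p in artifacts.items()}
    hashes["config"] = config.hash()
    (out / "hashes.json").write_text(json.dumps(hashes, indent=1, sort_keys=True))
    return out


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"stage output missing columns: {missing}")


def _write_report(out, config, b, clusters, comparisons, lat_tests, contrast):
    lines = [
        "# Synthetic population analysis report",
        "",
        f"- config hash: `{config.hash()}`, seed {config.seed}",
        f"- neurons per archetype: {config.n_neurons}",
        "",
        "## Behavior",
        f"- classifier agreement on eye-trace sessions: {b['classifier_agreement']}",
        f"- Fisher stay test ({b['fisher']['mode']}): p = {b['fisher']['p']:.3g}, "
        f"phi = {b['fisher']['phi']:.3f}",
        "",
        "## Clustering",
        f"- cluster sizes: {clusters['cluster'].value_counts().sort_index().to_dict()}",
        "",
        "## Model comparisons (target onset)",
    ]
    for name, c in comparisons.items():
        lines.append(f"- {name}: bootstrap p = {c['p_boot']:.4g} "
                     f"(deviance diff {c['observed_diff']:.1f}, {c['n_boot']} replicates)")
    lines += ["", "## Latency correlations (median r, Wilcoxon p)"]
    for name, c in lat_tests.items():
        lines.append(f"- {name}: median r = {c['median_r']:.3f}, p = {c['p']:.3g} (n={c['n']})")
    lines += ["", "## Reject-mode / task contrast flags"]
    for k, v in contrast.flags.items():
        lines.append(f"- {k}: {v}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
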