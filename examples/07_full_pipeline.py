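"""Run the full analysis pipeline on a small synthetic population.

Generates choice and fixation sessions for three archetype populations
across two subjects, then runs every stage — behavior, activity tables,
clustering, mixed-model comparisons, latency analysis, and the
proactive/reactive (Return/Stay vs fixation) contrast — into an artifact
directory with logged hashes.
"""

from seqchoice.pipeline import PipelineConfig, run_full

config = PipelineConfig(
    seed=42, n_neurons=(8, 8, 8), n_choice_trials=160,
    n_fixation_trials=24, n_boot=199, k_mode=3,
)
out = run_full(config, "scratch/pipeline_demo")
print((out / "report.md").read_text())
print(f"artifacts in {out}: behavior_summary.tsv, clusters.tsv, "
      "model_comparison.json, posthoc_table.tsv, latency_test.json, "
      "contrast_report.json, hashes.json")
print("Re-running with the same config reproduces identical hashes.")
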