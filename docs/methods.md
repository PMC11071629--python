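# Methods

This note documents the models, parameter choices, numerical details, and
limitations behind `seqchoice`. Empirical claims here are limited to what
the test suite and `scripts/acceptance.py` actually compute.

## Synthetic task and behavior

The generator emulates a sequential accept/reject choice task: scene
onset after a 1500–2000 ms preparatory interval, 1000 ms free viewing,
700 ms central fixation, then a single object (good or bad, drawn
uniformly) at 15° eccentricity in one of six directions (0°, 45°, 135°,
180°, 225°, 315° — no vertical positions, so the contralateral/
ipsilateral label is always defined). Each object presentation is one
trial record.

**Behavioral policy.** Reaction times are truncated normals with the
published per-subject, per-scene means and SDs (e.g. subject C, scene 1:
good 160.9 ± 21.6 ms, bad 234.3 ± 46.7 ms). Truncation bounds are
[80, 400] ms for good-object (accept) saccades — the detection window —
and [80, 600] ms for outbound return saccades, which may be slower;
80 ms is a physiological floor for visually guided saccades. Bad-object
action probabilities are the published per-scene action frequencies
(Return dominating at ~70–92%, then Stay); good objects are accepted
with probability 1, matching the near-ceiling observed acceptance.

**Eye traces.** Gaze is sampled at 1 kHz. Saccades follow a minimum-jerk
position profile `s(τ) = 10τ³ − 15τ⁴ + 6τ⁵` with duration
`20 ms + 1.5 ms/°·amplitude`, giving peak speeds of several hundred °/s —
far above the 40°/s detection criterion for any ≥ 5° movement without
fitting a main-sequence model. The waveform is shifted so that its
analytic 40°/s crossing falls exactly at the commanded onset; the
sample-level detector therefore recovers commanded reaction times within
±2 ms on noiseless traces (verified exhaustively over 1000 trials).
Fixational noise is white noise low-passed with a 40-ms Gaussian and
rescaled to the requested SD (default 0.3°). The correlation time
matters: truly white 0.3° noise at 1 kHz would produce apparent speeds
of hundreds of °/s and make the velocity criterion meaningless, whereas
slow drift is what fixating eyes actually do. Return-trial dwell times
are drawn from [120, 300] ms so the inside-window time stays below the
400-ms accept hold even after accounting for saccade flight time.
Fixation-break trials are modeled as a saccade away from the center
during the fixation hold; the classifier labels any pre-target saccade
`FixBreak` in both tasks.

**Spike trains.** Each neuron is an inhomogeneous Poisson process:
baseline rate plus event-aligned response kernels, rectified at zero.
Kernels are differences of exponentials (defaults: latency 90 ms, rise
20 ms, decay 80 ms), peaking ~127 ms after object onset so the 100–300 ms
analysis window brackets the peak. Sampling uses thinning against the
archetype's rate bound with the rate evaluated at 1-ms bin centers,
matching the 1-ms PSTH resolution downstream; expected window counts
agree with the analytic rate integral (3-SE envelope, tested). Spike
times are unique at 0.1-ms resolution.

**Archetypes.** Three response types, all with baseline < 10 spikes/s:

| archetype | good contra | good ipsi | bad contra | bad ipsi | baseline |
|---|---|---|---|---|---|
| cluster1_good | 30 | 18 | 14 | 12 | 5.0 |
| cluster2_bad | 6 | 6 | 28 | 27 | 4.0 |
| cluster3_visual | 32 | 30 | 32 (+5 sustained) | 30 (+5 sustained) | 5.0 |

(peak amplitudes in spikes/s). The orderings encode the in-vivo
taxonomy: good > bad and contra > ipsi for the good-preferring type;
bad > good with no laterality for the rejection type; equal early
transients plus a sustained bad-object component (rise 40 ms, decay
300 ms, latency 120 ms) for the visual type, whose good-object response
is cut short in vivo by the earlier accept saccade. Amplitudes and
baselines were chosen once so that the three types form clearly
separated clouds in the 2-D feature space (pairwise centroid distances
of ~4.5–5.5 Z against within-type spreads of ~0.4–0.8 Z) — the regime
the published scatter shows — while keeping single-trial responses at
realistic striatal magnitudes. `fixation_attenuation = 0.2` scales all
kernels during the fixation task, implementing the observed collapse of
task modulation under reactive-inhibition demands. The good-preferring
type carries `latency_coupling = −0.4` on contra-good trials: the
response amplitude is scaled by `1 − 0.4·z(RT)` (z truncated at ±3), so
high-activity trials have fast saccades — the mechanism behind the
negative latency-quartile correlation.

**Contra/ipsi convention.** "Contra" means the target's x-coordinate
sign is opposite the simulated recording hemisphere stored in session
metadata (default left hemisphere → contra = right hemifield). Any fixed
convention suffices for synthetic data; none is asserted as the
recording convention of any particular dataset.

## Behavioral analysis

Saccade onset = first sample whose central-difference 2-D speed exceeds
40°/s within 400 ms of target onset (no pre-smoothing; the estimator is
a parameter). Classification uses the 8°-side target window, the 400-ms
accept hold, a 4°-radius central zone for Stay, and a 1000-ms decision
window (the interval until the fixation point reappears). The central
radius and decision window are design choices — the verbal criterion
"kept looking around the center" specifies no radius.

Printed percentages use all bad-object trials of a scene (fixation
breaks included) as denominator and round half-up to one decimal, the
convention consistent with 13 of the 16 published Return/Stay
percentages; the other three are inconsistent with the published counts
under any rounding and are not reproduced. Welch's *t* uses the
Welch–Satterthwaite df; only outbound (return-go) saccades contribute
bad-object RTs. The stay-proportion test offers two 2×2 constructions —
Stay vs Return and Stay vs all-non-stay, pooled over stable vs flexible
scenes — because the published φ values are consistent with different
constructions for the two subjects (0.17 matches Stay-vs-Return for C;
0.07 matches Stay-vs-all for S); neither is asserted as *the* original
analysis. The φ confidence interval is a Fisher-z interval, provided as
a convenience.

## Spike-density chain

1-ms half-open bins `[t, t+1)` relative to the event (a spike exactly at
the event time falls in bin 0). The smoothing kernel is a unit-area
Gaussian truncated at ±4σ and renormalized (area conserved to < 0.1%).
Baselines: 500 ms immediately pre-event for Z-normalization; the
1000 ms ending 500 ms before scene onset for the < 10 spikes/s inclusion
filter (strictly less than). Neurons with zero baseline SD are excluded
and flagged rather than epsilon-padded — exclusion avoids infinities
without inventing a variance. Window means are arithmetic means over
half-open windows. Alternative window presets (perisaccadic −150…50 ms,
early-target 50…200 ms) are exposed because the narrative and figure
definitions of two analysis windows disagree; the 100–300 ms post-event
window is the default everywhere.

Condition-cell activity is computed per trial (window mean of the
per-trial SDF, Z-scored against the across-trial baseline mean/SD) and
averaged within cells; population summaries weight neurons equally.

## Clustering

Features are each neuron's mean Z in the 100–300 ms window for
contralateral good and bad objects, Z-scored against that neuron's own
baseline — consistent with the PSTH normalization; standardizing across
neurons instead is a plausible alternative reading and would only
rescale the feature axes. Silhouette is scanned over K = 2…8 even though
the design presumes three types: scanning turns the presumption into a
testable selection. k-means uses k-means++ with 50 restarts under a
fixed seed; ties in the silhouette resolve to the lowest K. Cluster
labels are canonicalized by centroid geometry (largest `z_good − z_bad`
→ cluster 1, smallest → cluster 2, remainder → cluster 3), since
k-means numbering is arbitrary but the response-type semantics are not.

## Mixed models and bootstrap

The response (mean normalized firing rate per neuron × condition cell)
is continuous, so the "generalized" mixed model is fitted as a Gaussian
LMM with identity link. Fitting is ML, not REML — deviances must be
comparable across fixed-effect structures. The likelihood is profiled
over the two variance ratios (monkey and monkey:neuron intercepts
relative to residual); the marginal covariance inverse and determinant
come from the Woodbury identity over the nested grouping, so one
evaluation is a handful of grouped sums, and the ratio box is
log-bounded at [−15, 10] (estimates at the lower bound are reported as
boundary zeros). For balanced cell-mean tables — every neuron
contributing every cell once, equal neuron counts per monkey — the
deviance depends on the data only through three stratum sums of squares
with known eigenvalues (1, `1+mλ_b`, `1+mλ_b+mgλ_a`), and the
constrained optimum is found by closed-form coordinate updates plus
boundary candidates, vectorized over bootstrap replicates. The two paths
agree to < 1e-3 on the deviance and are cross-checked against
statsmodels' MixedLM (ML) in the tests.

The bootstrap simulates from the fitted null (fixed effects plus fresh
monkey, neuron, and residual draws), refits both models per replicate,
and uses the add-one estimator `p = (1 + #{Δ* ≥ Δ}) / (B + 1)`, which
cannot return zero. Failed replicate refits are dropped and counted
(> 5% triggers a warning). Type-I error at α = 0.05 under null-generated
tables (2 monkeys × 60 neurons × 8 cells, 500 simulations × 199
replicates) falls inside the binomial band [0.032, 0.072] in the test
suite; the null deviance-difference distribution tracks χ² with the
fixed-effect df. Tests and the default pipeline use B = 199; B = 10 000
is a configuration choice for production runs.

A session-level random intercept is not in the default model: the
formula-level specification carries only monkey and monkey:neuron terms
(one synthetic session per neuron makes a session term unidentifiable
here anyway).

Post-hoc contrasts are differences of estimated marginal cell means with
model-based covariance; df is a Satterthwaite-style approximation
(finite-difference gradient of the contrast variance against the inverse
ML information of the variance components), with plain residual df as an
option. The m = 12 family at target onset comprises the six pairwise
(value × direction) contrasts averaged over scenes plus the six pairwise
scene contrasts averaged over cells; the saccade-onset and
choice-vs-fixation families use m = 6. The exact across-scene pairing is
an interpretation — the verbal description ("six pairwise tests … and
six across scenes") does not enumerate it. Effect size is the mean
difference divided by the residual SD. Bonferroni: `p_adj = min(1, m·p)`.

## Latency analysis

Trials with a measured RT are sorted (stable, ties by trial order) and
split into four contiguous groups; remainders go to the fastest groups —
an arbitrary but fixed rule that makes results deterministic. The
correlation is Pearson's r of group order (1–4) against group-mean
activity (with four equally spaced x-values this is also the natural
"group order" correlation; Spearman would be constant-shifted).
Correlations are computed per condition and pooled per condition for the
Wilcoxon test, matching the per-condition panel structure of the
analysis; pooling across conditions per neuron is the other defensible
reading. The signed-rank test is exact for n ≤ 25 without ties or zeros
(verified against full 2ⁿ enumeration for n ≤ 12) and a
continuity-corrected normal approximation otherwise. Degenerate cases:
zero-variance group means give a flagged NaN; conditions with fewer
trials than groups are skipped.

## Proactive/reactive contrast

Scene-1 bad-object trials (values constant there) are split by rejection
mode (Return/Stay) and compared with fixation-task object responses
(good/bad), per cluster and side, through the m = 6 post-hoc family. A
neuron enters a side's analysis only with ≥ 4 trials in every cell: cell
means from 2–3 trials have sampling variance far above the model's
homoscedastic residual and inflate false positives on the Return-vs-Stay
null contrast. A `pool_sides` option merges contra and ipsi trials,
roughly doubling the scarce Stay counts; the acceptance-level check of
the Return ≈ Stay null uses the pooled form for this reason. Flags in
the contrast report derive only from the post-hoc table.

## Problem sizes

Defaults were chosen as a realistic single-study scale: pipeline
populations of 19/16/26 neurons per archetype (the scale at which all
three types had fixation-task data), 288 object presentations per
choice session (the per-session presentation count implied by the
published totals), 40 fixation trials; clustering experiments use 150
neurons × 96 trials; the latency experiment 38 neurons × 160 trials;
calibration 500 simulations × 199 replicates. The full suite runs in a
few minutes on one core.

## Limitations

* Neurons within an archetype share identical parameters; real
  populations have heterogeneous amplitudes, latencies, and baselines,
  so clustering accuracy here is an upper bound on what identical
  pipelines achieve on real data.
* Oculomotor realism is minimal: no main-sequence variability,
  microsaccades, blinks, or measurement dropouts; the classifier's
  robustness is only demonstrated against slow Gaussian drift.
* Poisson spiking ignores refractoriness and burstiness; baseline SD is
  therefore tied to the mean, which real striatal units violate.
* The published neural effect tables depend on the original recordings
  and are reproduced structurally (sign/significance patterns on
  synthetic data), never numerically.
* Passing tests validate the pipeline's correctness and calibration on
  data satisfying its assumptions — not any scientific claim about real
  striatal recordings.
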