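"""Nested-intercept LMM fitting, bootstrap comparison, and post-hoc
contrasts, cross-checked against statsmodels (ML) and closed-form limits."""

import numpy as np
import pandas as pd
import pytest

from seqchoice import mixedstats as mx

SCENES = ["1", "2", "3", "4"]
VALUES = ["good", "bad"]


def simulate_table(
    rng,
    n_monkeys=2,
    n_neurons=12,
    sd_monkey=0.5,
    sd_neuron=1.0,
    sd_resid=1.0,
    value_effect=0.0,
    mu=1.0,
):
    rows = []
    for mi in range(n_monkeys):
        monkey = f"M{mi}"
        a = rng.normal(0, sd_monkey) if sd_monkey > 0 else 0.0
        for j in range(n_neurons):
            b = rng.normal(0, sd_neuron) if sd_neuron > 0 else 0.0
            for s in SCENES:
                for v in VALUES:
                    y = mu + (value_effect if v == "bad" else 0.0) + a + b
                    y += rng.normal(0, sd_resid)
                    rows.append((y, s, v, monkey, f"n{j}"))
    return pd.DataFrame(
        rows, columns=["NeuronalActivity", "Scene", "Value", "monkey_ID", "Neuron_ID"]
    )


class TestFitLMM:
    def test_deviance_matches_statsmodels_ml(self):
        import statsmodels.formula.api as smf

        tab = simulate_table(np.random.default_rng(1), value_effect=0.5)
        fit = mx.fit_lmm(tab, fixed="C(Scene)*C(Value)")
        md = smf.mixedlm(
            "NeuronalActivity ~ C(Scene)*C(Value)", tab, groups=tab["monkey_ID"],
            re_formula="1", vc_formula={"neuron": "0 + C(Neuron_ID)"},
        )
        mf = md.fit(reml=False, method="lbfgs", maxiter=300)
        assert fit.deviance <= -2 * mf.llf + 1e-4

    def test_ols_limit_recovers_mean(self):
        rng = np.random.default_rng(2)
        tab = simulate_table(rng, sd_monkey=0.0, sd_neuron=0.0, mu=2.5)
        fit = mx.fit_lmm(tab, fixed="1")
        se = tab["NeuronalActivity"].std(ddof=1) / np.sqrt(len(tab))
        assert abs(fit.beta[0] - 2.5) < 3 * se
        assert fit.sigma2_monkey < 0.05
        assert fit.sigma2_neuron < 0.05

    def test_null_deviance_never_below_full(self):
        for seed in range(8):
            tab = simulate_table(np.random.default_rng(seed),
                                 value_effect=0.3 * (seed % 3))
            full = mx.fit_lmm(tab, fixed="C(Scene)*C(Value)")
            null = mx.fit_lmm(tab, fixed="1")
            assert null.deviance >= full.deviance - 1e-6

    def test_variance_component_recovery(self):
        # generating values: monkey SD 0.5, neuron SD 1.0, residual 1.0
        rng = np.random.default_rng(42)
        tab = simulate_table(rng, n_monkeys=2, n_neurons=60)
        fit = mx.fit_lmm(tab, fixed="1")
        assert abs(np.sqrt(fit.sigma2_neuron) - 1.0) < 0.25
        assert abs(np.sqrt(fit.sigma2) - 1.0) < 0.25

    def test_missing_response_raises(self):
        tab = simulate_table(np.random.default_rng(3))
        tab.loc[0, "NeuronalActivity"] = np.nan
        with pytest.raises(mx.FitError):
            mx.fit_lmm(tab, fixed="1")


class TestBalancedPath:
    def test_agrees_with_general_path(self):
        for seed in range(5):
            tab = simulate_table(np.random.default_rng(100 + seed),
                                 value_effect=0.4 * (seed % 2))
            g = mx.parametric_bootstrap_compare(
                tab, factors=("Scene", "Value"), n_boot=1, seed=1, method="general")
            b = mx.parametric_bootstrap_compare(
                tab, factors=("Scene", "Value"), n_boot=1, seed=1, method="balanced")
            assert b.deviance_full == pytest.approx(g.deviance_full, abs=2e-4)
            assert b.deviance_null == pytest.approx(g.deviance_null, abs=2e-4)
            assert b.deviance_full <= g.deviance_full + 1e-9

    def test_unbalanced_table_rejected_by_balanced_method(self):
        tab = simulate_table(np.random.default_rng(5)).iloc[:-1]
        with pytest.raises(mx.FitError):
            mx.parametric_bootstrap_compare(tab, factors=("Scene", "Value"),
                                            n_boot=1, method="balanced")


class TestParametricBootstrap:
    def test_zero_observed_diff_gives_p_one(self):
        # response identical across cells within each neuron: the cell-mean
        # model explains nothing beyond the intercept
        rng = np.random.default_rng(6)
        tab = simulate_table(rng, sd_resid=1.0)
        per_neuron = tab.groupby(["monkey_ID", "Neuron_ID"])["NeuronalActivity"].transform("mean")
        tab["NeuronalActivity"] = per_neuron
        res = mx.parametric_bootstrap_compare(tab, factors=("Scene", "Value"),
                                              n_boot=99, seed=3)
        assert res.observed_diff == pytest.approx(0.0, abs=1e-6)
        assert res.p_boot == 1.0

    def test_affine_invariance_of_p(self):
        tab = simulate_table(np.random.default_rng(7), value_effect=0.4)
        r1 = mx.parametric_bootstrap_compare(tab, factors=("Scene", "Value"),
                                             n_boot=99, seed=11)
        t2 = tab.copy()
        t2["NeuronalActivity"] = t2["NeuronalActivity"] * 10.0 + 5.0
        r2 = mx.parametric_bootstrap_compare(t2, factors=("Scene", "Value"),
                                             n_boot=99, seed=11)
        assert r1.p_boot == r2.p_boot
        assert r1.observed_diff == pytest.approx(r2.observed_diff, rel=1e-6)

    def test_strong_effect_detected(self):
        tab = simulate_table(np.random.default_rng(8), n_neurons=30,
                             value_effect=2.0)
        res = mx.parametric_bootstrap_compare(tab, factors=("Scene", "Value"),
                                              n_boot=199, seed=2)
        assert res.p_boot <= 0.01

    def test_power_monotone_in_effect_size(self):
        ps = []
        for eff in (0.0, 0.5, 2.0):
            rej = 0
            for s in range(20):
                tab = simulate_table(np.random.default_rng(900 + s),
                                     n_neurons=20, value_effect=eff)
                r = mx.parametric_bootstrap_compare(
                    tab, factors=("Scene", "Value"), n_boot=99, seed=s)
                rej += r.p_boot <= 0.05
            ps.append(rej / 20)
        assert ps[0] <= 0.25
        assert ps[2] >= ps[1] >= ps[0] - 0.1
        assert ps[2] == 1.0


class TestPosthoc:
    def test_identical_cells_t_zero_p_one(self):
        rng = np.random.default_rng(9)
        tab = simulate_table(rng)
        # force Value cells identical within each (neuron, scene)
        wide = tab.pivot_table(index=["monkey_ID", "Neuron_ID", "Scene"],
                               columns="Value", values="NeuronalActivity").reset_index()
        rows = []
        for r in wide.itertuples(index=False):
            for v in VALUES:
                rows.append((r.good, r.Scene, v, r.monkey_ID, r.Neuron_ID))
        tab2 = pd.DataFrame(rows, columns=["NeuronalActivity", "Scene", "Value",
                                           "monkey_ID", "Neuron_ID"])
        fit = mx.fit_cellmeans_lmm(tab2, factors=("Scene", "Value"))
        cells_good = [(s, "good") for s in SCENES]
        cells_bad = [(s, "bad") for s in SCENES]
        ph = mx.posthoc_pairwise(fit, [("good vs bad", cells_good, cells_bad)], m=6)
        assert ph.loc[0, "t"] == pytest.approx(0.0, abs=1e-8)
        assert ph.loc[0, "p_adjusted"] == 1.0

    def test_bonferroni_arithmetic(self):
        tab = simulate_table(np.random.default_rng(10), value_effect=0.3)
        fit = mx.fit_cellmeans_lmm(tab, factors=("Scene", "Value"))
        fam = [("g vs b", [(s, "good") for s in SCENES], [(s, "bad") for s in SCENES]),
               ("s1 vs s2", [("1", v) for v in VALUES], [("2", v) for v in VALUES])]
        ph = mx.posthoc_pairwise(fit, fam, m=12)
        for _, row in ph.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, 12 * row["p_raw"]))
            assert row["alpha_adjusted"] == pytest.approx(0.05 / 12)

    def test_t_matches_ols_contrast_in_degenerate_limit(self):
        """With no random variation, the GLS contrast t collapses to the
        ordinary two-way ANOVA cell contrast (ML variance scaling)."""
        rng = np.random.default_rng(11)
        tab = simulate_table(rng, sd_monkey=0.0, sd_neuron=0.0, value_effect=1.0)
        fit = mx.fit_cellmeans_lmm(tab, factors=("Scene", "Value"))
        cells_good = [(s, "good") for s in SCENES]
        cells_bad = [(s, "bad") for s in SCENES]
        ph = mx.posthoc_pairwise(fit, [("g vs b", cells_good, cells_bad)], m=1,
                                 df_method="residual")
        y = tab["NeuronalActivity"].to_numpy()
        cell = tab["Scene"] + tab["Value"]
        means = tab.groupby(cell)["NeuronalActivity"].mean()
        resid = y - means[cell].to_numpy()
        sigma2_ml = (resid**2).sum() / len(y)
        n_cell = tab.groupby(cell).size().iloc[0]
        diff = means[[s + "good" for s in SCENES]].mean() - means[[s + "bad" for s in SCENES]].mean()
        se = np.sqrt(sigma2_ml * 2 * (1 / 4) ** 2 * 4 / n_cell)
        assert ph.loc[0, "t"] == pytest.approx(diff / se, abs=1e-4)

    def test_empty_cell_contrast_skipped(self):
        tab = simulate_table(np.random.default_rng(12))
        fit = mx.fit_cellmeans_lmm(tab, factors=("Scene", "Value"))
        fam = [("bogus", [("9", "good")], [("1", "bad")]),
               ("ok", [("1", "good")], [("1", "bad")])]
        ph = mx.posthoc_pairwise(fit, fam, m=2)
        assert list(ph["contrast"]) == ["ok"]
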