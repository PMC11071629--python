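"""Behavioral statistics against independent brute-force oracles and the
published count tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqchoice import behavior as beh
from seqchoice.reference import ACTION_COUNTS_REFERENCE


def _flat_eye(n_ms=2000):
    t = np.arange(n_ms, dtype=float)
    return pd.DataFrame({"t_ms": t, "x_deg": np.zeros(n_ms), "y_deg": np.zeros(n_ms)})


class TestDetectSaccade:
    def test_stationary_trace_returns_none(self):
        assert beh.detect_saccade(_flat_eye(), 500.0) is None

    def test_speed_just_below_threshold_returns_none(self):
        eye = _flat_eye()
        # ramp of 39 deg/s: 0.039 deg per ms
        seg = slice(800, 1200)
        eye.loc[seg, "x_deg"] = (eye.loc[seg, "t_ms"] - 800) * 0.039
        assert beh.detect_saccade(eye, 700.0, search_window=400) is None

    def test_speed_above_threshold_detected(self):
        eye = _flat_eye()
        seg = slice(900, 1300)
        eye.loc[seg, "x_deg"] = (eye.loc[seg, "t_ms"] - 900) * 0.05  # 50 deg/s
        onset = beh.detect_saccade(eye, 700.0, search_window=400)
        assert onset == pytest.approx(900.0, abs=2.0)

    def test_gap_in_trace_raises(self):
        eye = _flat_eye().drop(index=range(900, 950)).reset_index(drop=True)
        with pytest.raises(beh.EyeDataError):
            beh.detect_saccade(eye, 700.0)


def _jump(eye, t0, t1, from_xy, to_xy):
    """Insert a fast linear displacement between t0 and t1 (ms)."""
    t = eye["t_ms"].to_numpy()
    ramp = np.clip((t - t0) / (t1 - t0), 0, 1)
    eye["x_deg"] = from_xy[0] + (to_xy[0] - from_xy[0]) * ramp
    eye["y_deg"] = from_xy[1] + (to_xy[1] - from_xy[1]) * ramp
    return eye


class TestClassifyAction:
    def test_enter_and_hold_is_accept(self):
        eye = _jump(_flat_eye(3000), 1200, 1240, (0, 0), (15, 0))
        assert beh.classify_action(eye, (15.0, 0.0), 1000.0) == "Accept"

    def test_enter_exit_return_is_return(self):
        eye = _flat_eye(3000)
        t = eye["t_ms"].to_numpy()
        out = np.clip((t - 1200) / 40, 0, 1) - np.clip((t - 1390) / 40, 0, 1)
        eye["x_deg"] = 15.0 * out  # dwell on target ~150 ms, then back
        assert beh.classify_action(eye, (15.0, 0.0), 1000.0) == "Return"

    def test_center_hold_is_stay(self):
        eye = _flat_eye(3000)
        eye["x_deg"] += 0.5  # within 1 deg of center throughout
        assert beh.classify_action(eye, (15.0, 0.0), 1000.0) == "Stay"

    def test_saccade_away_is_other(self):
        eye = _jump(_flat_eye(3000), 1200, 1240, (0, 0), (-15, 0))
        assert beh.classify_action(eye, (15.0, 0.0), 1000.0) == "Other"

    def test_pre_target_break_is_fixbreak(self):
        eye = _jump(_flat_eye(3000), 700, 740, (0, 0), (10, 10))
        assert beh.classify_action(eye, (15.0, 0.0), 1500.0, t_fp=500.0) == "FixBreak"

    def test_missing_geometry_raises(self):
        with pytest.raises(ValueError):
            beh.classify_action(_flat_eye(), None, 500.0)


class TestSummarizeActions:
    def test_reference_scene1_return_percentage(self):
        summ = beh.summarize_reference_counts("C")
        assert summ.percentages.loc["Scene 1", "Return"] == 75.3

    def test_pooled_nonswitch_stay_count(self):
        summ = beh.summarize_reference_counts("C")
        assert summ.counts.loc["Non-switch (Scenes 1, 2)", "Stay"] == 598

    def test_single_trial_is_100_percent(self):
        trials = pd.DataFrame({
            "scene": [1], "value": ["bad"], "action": ["Stay"], "rt_ms": [np.nan],
        })
        summ = beh.summarize_actions(trials)
        assert summ.percentages.loc["Scene 1", "Stay"] == 100.0

    def test_counts_sum_to_total(self):
        summ = beh.summarize_reference_counts("S")
        actions = summ.counts.drop(columns="Total")
        assert (actions.sum(axis=1) == summ.counts["Total"]).all()


class TestRoundHalfUp:
    @pytest.mark.parametrize("x,expected", [(21.25, 21.3), (21.24, 21.2),
                                            (6.734, 6.7), (74.157, 74.2)])
    def test_rounding_convention(self, x, expected):
        assert beh.round_half_up(x) == expected


def _welch_oracle(a, b):
    """Textbook Welch statistic, df and p computed from first principles."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_samples_t0_p1(self):
        res = beh.compare_rt_welch([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 30))
            b = rng.normal(0.5, 2, rng.integers(3, 30))
            res = beh.compare_rt_welch(a, b)
            t, df, p = _welch_oracle(a, b)
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.df == pytest.approx(df, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_reference_scale_difference_is_overwhelming(self):
        # good vs bad RTs at the per-scene reference scale
        rng = np.random.default_rng(3)
        good = rng.normal(160.9, 21.6, 1428)
        bad = rng.normal(234.3, 46.7, 1076)
        res = beh.compare_rt_welch(good, bad)
        assert res.p < 1e-10

    def test_too_few_observations_raises(self):
        with pytest.raises(ValueError):
            beh.compare_rt_welch([1.0], [1.0, 2.0])


class TestStayProportion:
    def test_balanced_table_phi_zero(self):
        res = beh.stay_proportion_test((10, 10), (10, 10))
        assert res.phi == pytest.approx(0.0, abs=1e-15)
        assert res.p_fisher == pytest.approx(1.0)

    def test_reference_table_phi_matches_formula(self):
        a, b, c, d = 598, 2213, 261, 2535
        res = beh.stay_proportion_test((a, b), (c, d))
        phi = (a * d - b * c) / np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
        assert res.phi == pytest.approx(phi, abs=1e-12)

    def test_perfect_association_phi_one(self):
        res = beh.stay_proportion_test((7, 0), (0, 7))
        assert res.phi == pytest.approx(1.0)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            beh.stay_proportion_test((0, 0), (5, 5))

    def test_both_table_modes_available(self):
        t1 = beh.reference_stay_table("C", "stay-vs-return")
        t2 = beh.reference_stay_table("C", "stay-vs-all")
        assert t1 == ((598, 2213), (261, 2535))
        assert t2 == ((598, 2888 - 598), (261, 2869 - 261))


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher exact p by direct hypergeometric enumeration."""
    n1, n2 = a + b, c + d
    k = a + c
    n = n1 + n2
    p_obs = stats.hypergeom.pmf(a, n, n1, k)
    total = 0.0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        px = stats.hypergeom.pmf(x, n, n1, k)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


class TestFisherAgainstEnumeration:
    def test_all_small_tables(self):
        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 7):
                    for d in range(0, 7):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        res = beh.stay_proportion_test((a, b), (c, d))
                        assert res.p_fisher == pytest.approx(
                            _fisher_oracle(a, b, c, d), abs=1e-10
                        ), (a, b, c, d)
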