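"""Listener simulation, titration, RAU, mixed models, ratings, ICC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciderev.study import (RATING_PAIRS, ListenerProfile, StimulusBank,
                           bonferroni_adjust, default_listeners,
                           fit_condition_lmm, icc3, rau_transform,
                           round_to_stimulus_grid, run_rating_block,
                           sidak_adjust, simulate_word_scores,
                           titrate_rt60_50)


class _CurveBank:
    """Stub stimulus bank: STOI is a deterministic function of RT60."""

    def __init__(self, fn):
        self.fn = fn

    def stoi(self, seed, condition, rt60=None):
        if condition == "clean":
            return 1.0
        if condition.startswith("clean"):
            return 0.99
        base = self.fn(rt60)
        if condition == "reverb_wpe":
            return min(1.0, base + 0.10)
        if condition == "reverb_wpepf":
            return min(1.0, base + 0.13)
        return base


def _listener(s50=0.55, slope=1000.0, lapse=0.0, seed=0):
    return ListenerProfile("T01", s50, slope, lapse, seed)


class TestWordScores:
    def test_mean_at_s50_is_half(self):
        rng = np.random.default_rng(0)
        li = _listener(s50=0.5, slope=15.0)
        draws = [simulate_word_scores(li, 0.5, 5, rng)
                 for _ in range(10_000)]
        assert np.mean(draws) / 5 == pytest.approx(0.5, abs=0.01)

    def test_upper_asymptote_is_one_minus_lapse(self):
        rng = np.random.default_rng(1)
        li = _listener(s50=0.5, slope=500.0, lapse=0.04)
        draws = [simulate_word_scores(li, 1.0, 5, rng)
                 for _ in range(10_000)]
        assert np.mean(draws) / 5 == pytest.approx(0.96, abs=0.01)

    def test_binomial_variance(self):
        rng = np.random.default_rng(2)
        li = _listener(s50=0.5, slope=12.0, lapse=0.0)
        stoi = 0.55
        p = li.p_correct(stoi)
        draws = np.array([simulate_word_scores(li, stoi, 20, rng)
                          for _ in range(10_000)])
        assert draws.var() == pytest.approx(20 * p * (1 - p), rel=0.10)


class TestTitration:
    def test_midpoint_interpolation(self):
        # a steep listener whose 50% point sits exactly between 0.9 and 1.0
        bank = _CurveBank(lambda rt: 1.0 - 0.5 * rt)   # stoi 0.525 at 0.95
        li = _listener(s50=0.525, slope=1e6)
        res = titrate_rt60_50(li, bank, sentences_per_rt60=50)
        assert res.rt60_50 == pytest.approx(0.95, abs=0.02)

    def test_exact_grid_point(self):
        bank = _CurveBank(lambda rt: 1.0 - 0.5 * rt)
        li = _listener(s50=1.0 - 0.5 * 0.8, slope=1e6, lapse=0.0)
        # deterministic 50% at rt=0.8 requires the binomial to hit the
        # mean; use many sentences so the crossing brackets 0.8 tightly
        res = titrate_rt60_50(li, bank, sentences_per_rt60=200)
        assert res.rt60_50 == pytest.approx(0.8, abs=0.02)

    def test_no_crossing_reports_range(self):
        bank = _CurveBank(lambda rt: 0.9)  # never hard
        li = _listener(s50=0.5, slope=50.0)
        with pytest.raises(ValueError, match="%"):
            titrate_rt60_50(li, bank)

    def test_grid_rounding(self):
        assert round_to_stimulus_grid(0.97) == 0.95
        assert round_to_stimulus_grid(0.98) == 1.0
        assert round_to_stimulus_grid(1.0) == 1.0


class TestRau:
    def test_midpoint_and_floor_values(self):
        # direct evaluation of the arcsine formula
        assert rau_transform(50, 100) == pytest.approx(50.0, abs=0.5)
        assert rau_transform(0, 100) == pytest.approx(-18.4, abs=0.05)
        assert rau_transform(100, 100) == pytest.approx(118.4, abs=0.05)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(min_value=2, max_value=500))
    def test_monotone_and_symmetric(self, n):
        x = np.arange(n + 1)
        vals = rau_transform(x, n)
        assert np.all(np.diff(vals) > 0)
        # symmetry about the midpoint: RAU(x) + RAU(n-x) is constant
        s = vals + vals[::-1]
        assert np.ptp(s) < 1e-9

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            rau_transform(6, 5)
        with pytest.raises(ValueError):
            rau_transform(-1, 5)


class TestAdjustments:
    def test_dominance_and_identity(self, rng):
        p = rng.uniform(0.001, 0.5, size=10)
        assert np.all(sidak_adjust(p, 5) >= p)
        assert np.all(bonferroni_adjust(p, 5) >= p)
        assert np.allclose(sidak_adjust(p, 1), p)
        assert np.allclose(bonferroni_adjust(p, 1), p)
        # Sidak is never more conservative than Bonferroni
        assert np.all(sidak_adjust(p, 5) <= bonferroni_adjust(p, 5) + 1e-12)


class TestLmm:
    @staticmethod
    def _synthetic_scores(effects, subject_sd, resid_sd, seed,
                          n_subjects=15):
        from ciderev.stimuli import CONDITIONS
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_subjects):
            b = rng.normal(0, subject_sd)
            for cond in CONDITIONS:
                for rep in ("test", "retest"):
                    rows.append({
                        "subject_id": f"S{i:02d}",
                        "condition": cond,
                        "replicate": rep,
                        "rau": 60 + effects.get(cond, 0.0) + b
                               + rng.normal(0, resid_sd),
                    })
        return pd.DataFrame(rows)

    def test_fixed_effect_point_estimates(self):
        effects = {"reverb": -40.0, "reverb_wpe": -25.0,
                   "reverb_wpepf": -18.0}
        scores = self._synthetic_scores(effects, 8.0, 5.0, seed=3)
        res = fit_condition_lmm(scores)
        pw = res.pairwise.set_index("pair")
        est = pw.loc["reverb vs reverb_wpe", "estimate"]
        assert est == pytest.approx(15.0, abs=4.0)
        assert res.omnibus["p"].iloc[0] < 1e-6
        assert res.random_intercept_var > 0

    def test_missing_condition_raises(self):
        scores = self._synthetic_scores({}, 5, 5, seed=0)
        with pytest.raises(ValueError, match="missing"):
            fit_condition_lmm(scores[scores.condition != "reverb"])


class TestRatings:
    def test_degenerate_zero_variance_flagged(self):
        # a bank where every condition scores identically: all ratings sit
        # at 50 exactly once the noise is silenced
        bank = _CurveBank(lambda rt: 0.6)
        listeners = default_listeners(6, seed=0)
        thresholds = {l.subject_id: _Threshold(1.0) for l in listeners}
        _, tests = run_rating_block(listeners, thresholds, bank,
                                    "effort", pairs=[("reverb", "reverb")],
                                    noise_sd=0.0, seed=0)
        row = tests.iloc[0]
        assert row["degenerate"]
        assert row["p"] == 1.0

    def test_unknown_pair_label_raises(self):
        bank = _CurveBank(lambda rt: 0.6)
        listeners = default_listeners(3, seed=0)
        thresholds = {l.subject_id: _Threshold(1.0) for l in listeners}
        with pytest.raises(ValueError, match="pair"):
            run_rating_block(listeners, thresholds, bank, "effort",
                             pairs=[("reverb", "nonsense")])

    def test_pair_list_matches_protocol(self):
        assert len(RATING_PAIRS) == 8


class _Threshold:
    def __init__(self, rt):
        self.rt60_50 = rt


class TestIcc:
    def test_identity_gives_one(self):
        r = icc3(np.arange(10.0), np.arange(10.0))
        assert r.icc3 == 1.0

    def test_independent_noise_near_zero(self, rng):
        t = rng.normal(size=200)
        rt = rng.normal(size=200)
        assert abs(icc3(t, rt).icc3) < 0.15

    def test_against_brute_force_anova(self, rng):
        # independent oracle: explicit two-way ANOVA cell decomposition
        t = rng.normal(size=40)
        r = 0.7 * t + rng.normal(size=40) * 0.5
        mine = icc3(t, r)
        data = np.column_stack([t, r])
        n, k = data.shape
        grand = data.mean()
        ss_rows = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
        ss_cols = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
        ss_tot = sum((data[i, j] - grand) ** 2
                     for i in range(n) for j in range(k))
        msr = ss_rows / (n - 1)
        mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse)
        assert mine.icc3 == pytest.approx(expected, abs=1e-10)

    def test_against_pingouin(self, rng):
        import pingouin as pg
        t = rng.normal(size=30)
        r = 0.8 * t + rng.normal(size=30) * 0.4
        mine = icc3(t, r)
        df = pd.DataFrame({"targets": np.tile(np.arange(30), 2),
                           "raters": ["A"] * 30 + ["B"] * 30,
                           "scores": np.r_[t, r]})
        res = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores")
        row = res[res["Type"] == "ICC(C,1)"].iloc[0]
        assert mine.icc3 == pytest.approx(float(row["ICC"]), abs=1e-8)

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            icc3(np.zeros(10), np.zeros(9))

    def test_ci_contains_estimate(self, rng):
        t = rng.normal(size=25)
        r = 0.6 * t + rng.normal(size=25) * 0.6
        res = icc3(t, r)
        assert res.ci95[0] <= res.icc3 <= res.ci95[1]


class TestCohort:
    def test_default_listeners_deterministic_and_valid(self):
        a = default_listeners(15, seed=4)
        b = default_listeners(15, seed=4)
        assert [l.s50 for l in a] == [l.s50 for l in b]
        for l in a:
            assert 0.5 < l.s50 < 0.65
            assert 12.0 <= l.slope <= 20.0
            assert 0.0 <= l.lapse <= 0.05
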