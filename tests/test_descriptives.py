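"""Time-point summaries and retest-correlation descriptives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cogstab.descriptives import (
    retest_correlations,
    retest_vs_lag,
    subject_scores,
    timepoint_means,
)

from .conftest import make_trial_frame


def _trials_from_props(props, task="quantity_discrimination", tp=1, n_trials=12,
                       phase=1, date="2020-08-01"):
    rows = []
    for s, p in enumerate(props):
        k = int(round(p * n_trials))
        for i in range(n_trials):
            rows.append(
                (f"s{s}", "bonobo", task, phase, tp, 1, i + 1, 1 if i < k else 0, date)
            )
    return make_trial_frame(rows)


class TestTimepointMeans:
    def test_no_variance_zero_width_interval(self):
        out = timepoint_means(_trials_from_props([1.0, 1.0, 1.0]))
        row = out.iloc[0]
        assert row["mean_prop_correct"] == 1.0
        assert row["ci_low"] == row["ci_high"] == 1.0
        assert row["chance_flag"] == "above"

    def test_t_interval_hand_computation(self):
        out = timepoint_means(_trials_from_props([0.5, 0.5, 0.75, 0.75]))
        row = out.iloc[0]
        se = np.std([0.5, 0.5, 0.75, 0.75], ddof=1) / 2
        tq = stats.t.ppf(0.975, df=3)
        assert row["mean_prop_correct"] == pytest.approx(0.625)
        assert se == pytest.approx(0.0722, abs=1e-4)
        assert row["ci_low"] == pytest.approx(0.625 - tq * se)
        assert row["ci_high"] == pytest.approx(0.625 + tq * se)
        assert row["chance_flag"] == "overlapping"

    def test_chance_flag_definition_and_gaze_exemption(self):
        above = timepoint_means(_trials_from_props([0.9, 0.8, 1.0]))
        assert (above["ci_low"] > 0.5).all() and above["chance_flag"].eq("above").all()
        gaze = timepoint_means(_trials_from_props([0.9, 0.8, 1.0], task="gaze_following", n_trials=8))
        assert gaze["chance_flag"].eq("not_applicable").all()

    def test_single_subject_warns(self):
        with pytest.warns(UserWarning, match="single subject"):
            out = timepoint_means(_trials_from_props([0.75]))
        assert np.isnan(out["ci_low"]).all()

    def test_row_order_invariance(self, small_cohort):
        trials = small_cohort["trials"]
        shuffled = trials.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = timepoint_means(trials).reset_index(drop=True)
        b = timepoint_means(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestRetestCorrelations:
    def _two_tp(self, p1, p2):
        # 10 trials make the given proportions exactly representable
        t1 = _trials_from_props(p1, tp=1, date="2020-08-01", n_trials=10)
        t2 = _trials_from_props(p2, tp=2, date="2020-08-15", n_trials=10)
        return pd.concat([t1, t2], ignore_index=True)

    def test_identical_scores_r_one(self):
        out = retest_correlations(self._two_tp([0.25, 0.5, 0.75], [0.25, 0.5, 0.75]))
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["lag_days"].iloc[0] == 14

    def test_exact_reversal_r_minus_one(self):
        out = retest_correlations(
            self._two_tp([0.2, 0.4, 0.6, 0.8], [0.8, 0.6, 0.4, 0.2])
        )
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_matches_brute_force_covariance(self):
        p1, p2 = [0.1, 0.3, 0.5, 0.8, 0.9], [0.2, 0.2, 0.6, 0.7, 1.0]
        out = retest_correlations(self._two_tp(p1, p2))
        a, b = np.array(p1), np.array(p2)
        oracle = np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
        assert out["r"].iloc[0] == pytest.approx(oracle)

    def test_few_pairs_and_zero_variance_omitted(self):
        with pytest.warns(UserWarning, match="complete pairs"):
            out = retest_correlations(self._two_tp([0.2, 0.8], [0.4, 0.6]))
        assert out.empty
        with pytest.warns(UserWarning, match="zero variance"):
            out = retest_correlations(self._two_tp([0.5, 0.5, 0.5], [0.2, 0.5, 0.8]))
        assert out.empty

    def test_symmetry_and_diagonal_exclusion(self, small_cohort):
        out = retest_correlations(small_cohort["trials"])
        assert (out["t1"] < out["t2"]).all()  # each unordered pair appears once
        dup = out.duplicated(subset=["task", "phase_1", "t1", "phase_2", "t2"])
        assert not dup.any()


class TestRetestVsLag:
    def _entries(self, rs, lags, task="quantity_discrimination"):
        return pd.DataFrame({"task": task, "lag_days": lags, "r": rs})

    def test_strictly_decreasing_gives_rank_minus_one(self):
        out = retest_vs_lag(self._entries([0.9, 0.7, 0.5, 0.4, 0.2], [10, 20, 30, 40, 50]))
        assert out["rank_corr"].iloc[0] == pytest.approx(-1.0)

    def test_constant_r_gives_zero(self):
        out = retest_vs_lag(self._entries([0.5] * 6, [10, 20, 30, 40, 50, 60]))
        assert out["rank_corr"].iloc[0] == 0.0

    def test_decaying_state_autocorrelation_yields_negative_trend(self):
        # AR(1) latent states: retest r decays with lag by construction
        rng = np.random.default_rng(12)
        n, T, rho = 200, 8, 0.6
        states = np.empty((n, T))
        states[:, 0] = rng.standard_normal(n)
        for t in range(1, T):
            states[:, t] = rho * states[:, t - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        scores = states + 0.3 * rng.standard_normal((n, T))
        rows = []
        for i in range(T):
            for j in range(i + 1, T):
                rows.append(
                    {
                        "task": "direct_causal_inference",
                        "lag_days": 14 * (j - i),
                        "r": np.corrcoef(scores[:, i], scores[:, j])[0, 1],
                    }
                )
        out = retest_vs_lag(pd.DataFrame(rows))
        assert out["rank_corr"].iloc[0] < -0.5

    def test_subject_scores_unit(self, small_cohort):
        s = subject_scores(small_cohort["trials"])
        assert ((s["prop_correct"] >= 0) & (s["prop_correct"] <= 1)).all()
        assert (s["n_correct"] <= s["n_trials"]).all()


def test_figure_mirrors_write_files(tmp_path, small_cohort):
    from cogstab.descriptives import plot_retest_vs_lag, plot_timepoint_means

    trials = small_cohort["trials"]
    plot_timepoint_means(timepoint_means(trials), tmp_path / "means.png")
    plot_retest_vs_lag(retest_correlations(trials), tmp_path / "retest.png")
    assert (tmp_path / "means.png").stat().st_size > 0
    assert (tmp_path / "retest.png").stat().st_size > 0
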