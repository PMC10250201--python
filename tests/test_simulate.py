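"""Synthetic cohort generator: design constants, noise structure, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from scipy.stats import norm

from cogstab.simulate import (
    SimConfig,
    simulate_bivariate_parcels,
    simulate_cohort,
    simulate_dataset,
    simulate_latent_abilities,
    simulate_parcels_direct,
    simulate_trials,
)

from .conftest import ALL_TASKS


def _flat_subjects(n, group="bonobo"):
    return pd.DataFrame({"subject_id": [f"s{i:05d}" for i in range(n)], "group": group})


class TestCohort:
    def test_default_design_constants(self):
        subjects, diary = simulate_cohort(SimConfig(seed=0))
        assert len(subjects) == 43
        sizes = subjects.groupby("group").size()
        assert sizes.to_dict() == {
            "bonobo": 8,
            "chimpanzee_A": 12,
            "chimpanzee_B": 12,
            "gorilla": 6,
            "orangutan": 5,
        }
        # full diary: 14 predictors per subject x phase x time point
        counts = diary.groupby(["subject_id", "phase", "time_point"]).size()
        assert (counts == 14).all()

    def test_same_seed_identical_output(self):
        a = simulate_dataset(SimConfig(seed=3))
        b = simulate_dataset(SimConfig(seed=3))
        pd.testing.assert_frame_equal(a["trials"], b["trials"])
        pd.testing.assert_frame_equal(a["diary"], b["diary"])

    def test_stable_predictors_constant_within_subject(self):
        _, diary = simulate_cohort(SimConfig(seed=1))
        stable = diary[diary["category"] == "stable_individual"]
        nun = stable.groupby(["subject_id", "predictor"])["value"].nunique()
        assert (nun == 1).all()

    def test_config_validation(self):
        with pytest.raises(ValueError, match="missing_rate"):
            SimConfig(missing_rate=1.2).validate()
        with pytest.raises(ValueError, match="increasing"):
            SimConfig(thresholds=(1.0, 0.0)).validate()
        with pytest.raises(ValueError, match="beta"):
            SimConfig(beta={"unknown_pred": 1.0}).validate()


class TestLatentAbilities:
    def test_zero_state_variance_degenerates_to_trait(self):
        cfg = SimConfig(
            seed=2, phases=1, time_points=4,
            state_var={t: 0.0 for t in ALL_TASKS},
        )
        subjects, _ = simulate_cohort(cfg)
        ab = simulate_latent_abilities(cfg, subjects)
        assert np.allclose(ab["state_residual"], 0.0)

    def test_trait_variance_monte_carlo(self):
        cfg = SimConfig(
            seed=9, phases=1, time_points=2,
            trial_counts={"direct_causal_inference": 12},
            trait_var={"direct_causal_inference": 1.0},
            state_var={"direct_causal_inference": 0.3},
        )
        ab = simulate_latent_abilities(cfg, _flat_subjects(100_000))
        traits = ab.drop_duplicates("subject_id")["trait"].to_numpy()
        assert abs(traits.var(ddof=1) - 1.0) < 0.02
        # independence of trait and state residual
        corr = np.corrcoef(ab["trait"], ab["state_residual"])[0, 1]
        assert abs(corr) < 0.01


class TestTrials:
    def test_null_model_hits_chance(self):
        cfg = SimConfig(
            seed=4, phases=1, time_points=3,
            trial_counts={"quantity_discrimination": 12},
            intercepts={"quantity_discrimination": 0.0},
            trait_var={"quantity_discrimination": 0.0},
            state_var={"quantity_discrimination": 0.0},
            missing_rate=0.0,
        )
        subjects = _flat_subjects(400)
        ab = simulate_latent_abilities(cfg, subjects)
        trials = simulate_trials(ab, pd.DataFrame(columns=["subject_id", "phase", "time_point", "predictor", "value"]), cfg)
        assert abs(trials["outcome"].mean() - 0.5) < 0.01

    def test_probit_normal_marginal(self):
        # alpha=1, Var(T)=1, Var(zeta)=0.25: P(correct) = Phi(1/sqrt(2.25))
        cfg = SimConfig(
            seed=5, phases=1, time_points=4,
            trial_counts={"quantity_discrimination": 12},
            intercepts={"quantity_discrimination": 1.0},
            trait_var={"quantity_discrimination": 1.0},
            state_var={"quantity_discrimination": 0.25},
            missing_rate=0.0,
        )
        subjects = _flat_subjects(3000)
        ab = simulate_latent_abilities(cfg, subjects)
        trials = simulate_trials(ab, pd.DataFrame(columns=["subject_id", "phase", "time_point", "predictor", "value"]), cfg)
        expected = ndtr(1.0 / np.sqrt(1 + 1.25))
        assert abs(trials["outcome"].mean() - expected) < 0.01

    def test_attrition_band(self):
        bundle = simulate_dataset(SimConfig(seed=6))
        n_t = bundle["trials"].groupby(["phase", "time_point"])["subject_id"].nunique()
        assert n_t.min() >= 22 and n_t.max() <= 43

    def test_delay_task_absent_in_phase_one(self):
        trials = simulate_dataset(SimConfig(seed=7))["trials"]
        dog = trials[trials["task"] == "delay_of_gratification"]
        assert set(dog["phase"]) == {2}
        gf = trials[trials["task"] == "gaze_following"]
        assert gf.groupby("trial_index")["session"].nunique().max() == 1


class TestParcelLatent:
    def test_dichotomization_at_zero(self):
        cfg = SimConfig(
            seed=8, mode="parcel_latent", phases=1, time_points=2,
            thresholds=(0.0,), missing_rate=0.0,
            trial_counts={"quantity_discrimination": 12},
            trait_var={"quantity_discrimination": 1.0},
            state_var={"quantity_discrimination": 0.25},
        )
        subjects = _flat_subjects(500)
        ab = simulate_latent_abilities(cfg, subjects)
        parcels = simulate_parcels_direct(ab, cfg)
        ystar_pos = ab.merge(
            parcels[parcels["half"] == 1],
            on=["subject_id", "task", "phase", "time_point"],
        )
        # category 1 iff the latent response crossed zero; marginally half do
        assert set(parcels["category"]) == {0, 1}
        assert abs(parcels["category"].mean() - 0.5) < 0.03

    def test_middle_category_mass_matches_normal_cdf(self):
        # T = zeta = 0: P(middle) = Phi(1) - Phi(-1)
        cfg = SimConfig(
            seed=9, mode="parcel_latent", phases=1, time_points=5,
            thresholds=(-1.0, 1.0), missing_rate=0.0,
            trial_counts={"quantity_discrimination": 12},
            trait_var={"quantity_discrimination": 0.0},
            state_var={"quantity_discrimination": 0.0},
        )
        subjects = _flat_subjects(4000)
        ab = simulate_latent_abilities(cfg, subjects)
        parcels = simulate_parcels_direct(ab, cfg)
        expected = norm.cdf(1) - norm.cdf(-1)
        assert abs((parcels["category"] == 1).mean() - expected) < 0.01


class TestBivariateGenerator:
    def test_trait_correlation_realized(self):
        pa, pb = simulate_bivariate_parcels(5000, 2, rho=0.5, seed=3)
        # average the two halves per subject as a crude trait proxy
        a = pa.groupby("subject_id")["category"].mean()
        b = pb.groupby("subject_id")["category"].mean()
        r = np.corrcoef(a, b)[0, 1]
        assert 0.2 < r < 0.5  # attenuated by state + measurement noise

    def test_rho_validation(self):
        with pytest.raises(ValueError):
            simulate_bivariate_parcels(10, 2, rho=1.0)
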