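import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ALL_TASKS = (
    "gaze_following",
    "direct_causal_inference",
    "inference_by_exclusion",
    "quantity_discrimination",
    "delay_of_gratification",
)


def make_trial_frame(rows):
    """Trial table from (subject, group, task, phase, tp, session, idx, outcome, date)."""
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "group",
            "task",
            "phase",
            "time_point",
            "session",
            "trial_index",
            "outcome",
            "date",
        ],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Trial-level synthetic cohort, 1 phase x 5 time points, ~18 subjects."""
    from cogstab.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(
        seed=101,
        phases=1,
        time_points=5,
        group_sizes={"bonobo": 10, "gorilla": 8},
        missing_rate=0.1,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def latent_parcels():
    """parcel_latent draws for one task: n=80 subjects, 6 time points,
    Var(T)=0.75, Var(zeta)=0.25."""
    from cogstab.simulate import (
        SimConfig,
        simulate_cohort,
        simulate_latent_abilities,
        simulate_parcels_direct,
    )

    cfg = SimConfig(
        mode="parcel_latent",
        seed=55,
        phases=1,
        time_points=6,
        group_sizes={"bonobo": 80},
        missing_rate=0.1,
        trait_var={t: 0.75 for t in ALL_TASKS},
        state_var={t: 0.25 for t in ALL_TASKS},
    )
    subjects, _ = simulate_cohort(cfg)
    abilities = simulate_latent_abilities(cfg, subjects)
    parcels = simulate_parcels_direct(abilities, cfg)
    return parcels[parcels["task"] == "direct_causal_inference"]


@pytest.fixture(scope="session")
def fitted_lst(latent_parcels):
    from cogstab.lst import LatentStateTraitModel

    return LatentStateTraitModel(seed=7, draws=600, tune=150, thin=2, rhat_max=1.05).fit(
        latent_parcels
    )


@pytest.fixture(scope="session")
def projection_data():
    """Trial-level cohort with three active, within-subject-varying predictors.

    Time-varying actives keep their coefficients identified next to the
    subject random intercept (purely between-subject signals are partially
    absorbed by it and by the collinear group/age block).
    """
    from cogstab.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(
        seed=31,
        phases=1,
        beta={"observer_present": -0.5, "sociality": 0.5, "rank": 0.5},
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def fitted_reference(projection_data):
    from cogstab.projection import (
        HierarchicalBinomialReference,
        build_design,
        performance_counts,
    )

    counts = performance_counts(projection_data["trials"], "direct_causal_inference", 1)
    X, term_map = build_design(projection_data["diary"], 1)
    ref = HierarchicalBinomialReference(seed=5, n_draws=300)
    ref.term_map_ = term_map
    return ref.fit(X, counts)


def rng(seed=0):
    return np.random.default_rng(seed)


def lst_grid_oracle(cats, kappas, var_t, var_z, n_grid=801, span=8.0):
    """Brute-force grid-integrated log likelihood of the state-trait model.

    Dense trapezoid integration, factorizing the per-occasion state-residual
    integrals conditional on the trait (they are independent given T).
    Independent of the Gauss-Hermite machinery under test.
    """
    from scipy.stats import norm

    from cogstab.ordinal import grm_probs

    cats = np.asarray(cats, dtype=int)
    sd_t, sd_z = np.sqrt(var_t), np.sqrt(var_z)
    tg = np.linspace(-span * sd_t, span * sd_t, n_grid)
    zg = np.linspace(-span * sd_z, span * sd_z, n_grid)
    eta = tg[:, None] + zg[None, :]
    pz = norm.pdf(zg, scale=sd_z)
    prod = np.ones_like(tg)
    for row in cats:
        f = np.ones_like(eta)
        for y, kap in zip(row, kappas):
            if y >= 0:
                f = f * grm_probs(eta, kap)[..., y]
        prod = prod * np.trapezoid(f * pz, zg, axis=1)
    return float(np.log(np.trapezoid(prod * norm.pdf(tg, scale=sd_t), tg)))
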