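"""Synthetic cohort generator mirroring a repeated great-ape testing battery.

The generator emulates the study design the models are built for: 43 subjects
in five social groups (8 bonobos, two chimpanzee groups of 12, 6 gorillas,
5 orangutans), two phases of 14 biweekly time points, five binary-outcome
tasks with fixed per-time-point trial counts (gaze following 8, the others
12; delay of gratification only in phase 2), block-wise attrition, and a
trait + occasion-specific + trial-level noise structure on the probit scale.

Two generative modes are provided:

``trial_level``
    Bernoulli trials with success probability
    ``Phi(alpha_task + T + zeta_t + x'beta)`` — realistic data for which the
    ordinal measurement model is an approximation; carries predictor effects.
``parcel_latent``
    Draws the continuous parcel response ``Y* = T + zeta_t + eps`` directly
    and cuts it at fixed thresholds — the exact generative mirror of the
    latent state-trait measurement model, used for sharp recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .data import GROUPS, PREDICTOR_CATEGORIES, TASKS

__all__ = [
    "SimConfig",
    "simulate_cohort",
    "simulate_latent_abilities",
    "simulate_trials",
    "simulate_parcels_direct",
    "simulate_dataset",
]

# species-level age ranges (years) and female proportions used for the cohort
_AGE_RANGES = {
    "bonobo": (7.3, 39.0),
    "chimpanzee_A": (2.6, 55.9),
    "chimpanzee_B": (2.6, 55.9),
    "gorilla": (2.7, 22.6),
    "orangutan": (17.0, 41.2),
}
_FEMALE_PROP = {
    "bonobo": 3 / 8,
    "chimpanzee_A": 18 / 24,
    "chimpanzee_B": 18 / 24,
    "gorilla": 4 / 6,
    "orangutan": 4 / 5,
}


def _default_group_sizes():
    return {"bonobo": 8, "chimpanzee_A": 12, "chimpanzee_B": 12, "gorilla": 6, "orangutan": 5}


def _default_trait_var():
    # most tasks: reliable (Var S ~ 3) and trait-dominated (Con ~ 0.8);
    # quantity discrimination: noisy half-tests (Var S ~ 1) but near-perfectly
    # consistent true scores
    return {
        "gaze_following": 2.4,
        "direct_causal_inference": 2.4,
        "inference_by_exclusion": 2.4,
        "quantity_discrimination": 0.95,
        "delay_of_gratification": 2.4,
    }


def _default_state_var():
    return {
        "gaze_following": 0.6,
        "direct_causal_inference": 0.6,
        "inference_by_exclusion": 0.6,
        "quantity_discrimination": 0.05,
        "delay_of_gratification": 0.6,
    }


def _default_intercepts():
    # probit intercepts giving marginal accuracies in the observed ballpark:
    # low gaze-following rates, near-ceiling causal inference, intermediate rest
    return {
        "gaze_following": -0.8,
        "direct_causal_inference": 1.2,
        "inference_by_exclusion": 0.2,
        "quantity_discrimination": 0.8,
        "delay_of_gratification": 0.2,
    }


@dataclass
class SimConfig:
    """Study-design and noise-structure parameters of the synthetic cohort."""

    group_sizes: dict = field(default_factory=_default_group_sizes)
    phases: int = 2
    time_points: int = 14
    trial_counts: dict = field(default_factory=lambda: dict(TASKS))
    trait_var: dict = field(default_factory=_default_trait_var)
    state_var: dict = field(default_factory=_default_state_var)
    intercepts: dict = field(default_factory=_default_intercepts)
    #: probit-scale predictor effects, keyed by predictor name (trial_level mode)
    beta: dict = field(default_factory=dict)
    #: additive latent state-mean offsets: {task: {phase: length-T array}}
    state_means: dict = field(default_factory=dict)
    #: probability that a (subject, phase, time point) block is missing
    missing_rate: float = 0.18
    mode: str = "trial_level"
    #: cut points for parcel_latent mode (strictly increasing)
    thresholds: tuple = (-1.2, 0.0, 1.2)
    phase_starts: tuple = (date(2020, 8, 1), date(2021, 5, 26))
    interval_days: int = 14
    seed: int = 0

    def validate(self) -> "SimConfig":
        if set(self.group_sizes) - set(GROUPS):
            raise ValueError(f"unknown groups: {set(self.group_sizes) - set(GROUPS)}")
        for name in ("trait_var", "state_var"):
            if any(v < 0 for v in getattr(self, name).values()):
                raise ValueError(f"{name} entries must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.mode not in ("trial_level", "parcel_latent"):
            raise ValueError(f"unknown mode {self.mode!r}")
        thr = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(thr) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        unknown_beta = set(self.beta) - set(PREDICTOR_CATEGORIES)
        if unknown_beta:
            raise ValueError(f"unknown beta entries: {sorted(unknown_beta)}")
        return self

    def tasks_for_phase(self, phase: int):
        return [t for t in self.trial_counts if not (t == "delay_of_gratification" and phase == 1)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phase_starts"] = [s.isoformat() for s in self.phase_starts]
        return d


def _ar1(rng, n_time, n_series, rho=0.8):
    x = np.empty((n_series, n_time))
    x[:, 0] = rng.standard_normal(n_series)
    for t in range(1, n_time):
        x[:, t] = rho * x[:, t - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n_series)
    return x


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the subject roster and the full 14-predictor diary.

    Stable individual predictors are drawn once per subject; variable
    individual predictors evolve as AR(1) series or per-occasion Bernoulli
    draws; group-life predictors are shared by all members of a group at a
    time point; testing-arrangement predictors vary freely per occasion.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    rows = []
    for group in GROUPS:
        for i in range(config.group_sizes.get(group, 0)):
            lo, hi = _AGE_RANGES[group]
            age = rng.uniform(lo, hi)
            rows.append(
                {
                    "subject_id": f"{group}_{i + 1:02d}",
                    "group": group,
                    "age": round(age, 1),
                    "sex": "female" if rng.random() < _FEMALE_PROP[group] else "male",
                    "rearing_history": "hand" if rng.random() < 0.3 else "mother",
                    "time_in_research": round(max(age - 2.0, 0.5) * rng.uniform(0.4, 1.0), 1),
                }
            )
    subjects = pd.DataFrame(rows)
    n = len(subjects)
    n_occ = config.phases * config.time_points

    rank = _ar1(rng, n_occ, n)
    sociality = _ar1(rng, n_occ, n)
    group_idx = {g: k for k, g in enumerate(GROUPS)}
    outdoors = 6 + 2 * _ar1(rng, n_occ, len(GROUPS))
    disturbances = rng.random((len(GROUPS), n_occ)) < 0.2
    life_events = rng.random((len(GROUPS), n_occ)) < 0.1

    diary_rows = []
    for s, subj in subjects.iterrows():
        for phase in range(1, config.phases + 1):
            for tp in range(1, config.time_points + 1):
                occ = (phase - 1) * config.time_points + (tp - 1)
                g = group_idx[subj["group"]]
                vals = {
                    "group": subj["group"],
                    "age": subj["age"],
                    "sex": subj["sex"],
                    "rearing_history": subj["rearing_history"],
                    "time_in_research": subj["time_in_research"],
                    "rank": round(rank[s, occ], 3),
                    "sickness": int(rng.random() < 0.1),
                    "sociality": round(sociality[s, occ], 3),
                    "time_outdoors": round(outdoors[g, occ], 2),
                    "disturbances": int(disturbances[g, occ]),
                    "life_events": int(life_events[g, occ]),
                    "observer_present": int(rng.random() < 0.3),
                    "study_same_day": int(rng.random() < 0.25),
                    "study_since_last": int(rng.random() < 0.5),
                }
                for pred, val in vals.items():
                    diary_rows.append(
                        {
                            "subject_id": subj["subject_id"],
                            "phase": phase,
                            "time_point": tp,
                            "predictor": pred,
                            "value": val,
                            "category": PREDICTOR_CATEGORIES[pred],
                        }
                    )
    return subjects, pd.DataFrame(diary_rows)


def simulate_latent_abilities(config: SimConfig, subjects: pd.DataFrame) -> pd.DataFrame:
    """Per subject x task: stable trait T; per occasion: state residual zeta_t.

    ``T ~ N(0, trait_var[task])`` and ``zeta_t ~ N(0, state_var[task])``,
    independent across occasions and of T.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(subjects)
    tp_n = config.time_points
    frames = []
    for task in config.trial_counts:
        traits = np.sqrt(config.trait_var[task]) * rng.standard_normal(n)
        sd_z = np.sqrt(config.state_var[task])
        for phase in range(1, config.phases + 1):
            if task == "delay_of_gratification" and phase == 1:
                continue
            zeta = sd_z * rng.standard_normal((n, tp_n))
            mu = np.asarray(
                config.state_means.get(task, {}).get(phase, np.zeros(tp_n)), dtype=float
            )
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": np.repeat(subjects["subject_id"].to_numpy(), tp_n),
                        "group": np.repeat(subjects["group"].to_numpy(), tp_n),
                        "task": task,
                        "phase": phase,
                        "time_point": np.tile(np.arange(1, tp_n + 1), n),
                        "trait": np.repeat(traits, tp_n),
                        "state_residual": zeta.ravel(),
                        "state_mean": np.tile(mu, n),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _attrition_mask(config: SimConfig, subjects: pd.DataFrame, rng) -> set:
    """(subject, phase, tp) blocks that drop out; the first occasion is kept complete."""
    ids = subjects["subject_id"].to_numpy()
    draw = rng.random((len(ids), config.phases, config.time_points))
    draw[:, 0, 0] = 1.0
    hit = np.argwhere(draw < config.missing_rate)
    return {(ids[s], p + 1, t + 1) for s, p, t in hit}


def _diary_effects(diary: pd.DataFrame, beta: dict) -> pd.DataFrame:
    """Linear predictor contribution x'beta per (subject, phase, time_point)."""
    keys = ["subject_id", "phase", "time_point"]
    wide = diary.pivot_table(index=keys, columns="predictor", values="value", aggfunc="first")
    eff = pd.Series(0.0, index=wide.index)
    for pred, b in beta.items():
        if b == 0:
            continue
        col = wide[pred]
        x = pd.to_numeric(col, errors="coerce")
        if x.isna().any():  # categorical predictor: integer codes
            x = pd.Series(pd.factorize(col, sort=True)[0], index=col.index, dtype=float)
        sd = x.std()
        x = (x - x.mean()) / (sd if sd > 0 else 1.0)
        eff = eff + b * x
    return eff.rename("x_beta").reset_index()


def _session_for(task: str, trial_index: np.ndarray) -> np.ndarray:
    if task == "gaze_following":
        return np.where(trial_index <= 4, 1, 2)
    if task in ("direct_causal_inference", "inference_by_exclusion"):
        return np.ones_like(trial_index)
    return np.full_like(trial_index, 2)


def _drop_missing(ab: pd.DataFrame, missing: set) -> pd.DataFrame:
    key = pd.MultiIndex.from_frame(ab[["subject_id", "phase", "time_point"]])
    return ab[~key.isin(missing)]


def simulate_trials(
    abilities: pd.DataFrame, diary: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Bernoulli trial outcomes with P(correct) = Phi(alpha + mu_t + T + zeta_t + x'beta)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    subjects = abilities[["subject_id", "group"]].drop_duplicates()
    missing = _attrition_mask(config, subjects, rng)
    eff = _diary_effects(diary, config.beta)
    ab = abilities.merge(eff, on=["subject_id", "phase", "time_point"], how="left")
    ab["x_beta"] = ab["x_beta"].fillna(0.0)
    ab = ab.sort_values(["task", "subject_id", "phase", "time_point"], kind="mergesort")
    ab = _drop_missing(ab, missing)

    frames = []
    for task, cell in ab.groupby("task", sort=True):
        n_tr = config.trial_counts[task]
        eta = (
            config.intercepts[task]
            + cell["state_mean"].to_numpy()
            + cell["trait"].to_numpy()
            + cell["state_residual"].to_numpy()
            + cell["x_beta"].to_numpy()
        )
        p = ndtr(eta)
        outcomes = (rng.random((len(cell), n_tr)) < p[:, None]).astype(int)
        idx = np.arange(1, n_tr + 1)
        session = _session_for(task, idx)
        n_cells = len(cell)
        tp = np.repeat(cell["time_point"].to_numpy(), n_tr)
        phase = np.repeat(cell["phase"].to_numpy(), n_tr)
        days = (tp - 1) * config.interval_days + (np.tile(session, n_cells) - 1)
        starts = pd.to_datetime(
            [config.phase_starts[p - 1] for p in phase]
        ) + pd.to_timedelta(days, unit="D")
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(cell["subject_id"].to_numpy(), n_tr),
                    "group": np.repeat(cell["group"].to_numpy(), n_tr),
                    "task": task,
                    "phase": phase,
                    "time_point": tp,
                    "session": np.tile(session, n_cells),
                    "trial_index": np.tile(idx, n_cells),
                    "outcome": outcomes.ravel(),
                    "date": starts.date,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_parcels_direct(abilities: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Categorical parcel indicators cut directly from Y* = mu_t + T + zeta_t + eps.

    The exact generative mirror of the latent state-trait measurement model:
    eps ~ N(0, 1) independently per test half, shared thresholds across time.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    subjects = abilities[["subject_id", "group"]].drop_duplicates()
    missing = _attrition_mask(config, subjects, rng)
    thr = np.asarray(config.thresholds, dtype=float)

    ab = abilities.sort_values(
        ["task", "subject_id", "phase", "time_point"], kind="mergesort"
    )
    ab = _drop_missing(ab, missing)
    base = (ab["state_mean"] + ab["trait"] + ab["state_residual"]).to_numpy()
    out = []
    for half in (1, 2):
        ystar = base + rng.standard_normal(len(ab))
        cat = np.searchsorted(thr, ystar)
        df = ab[["subject_id", "group", "task", "phase", "time_point"]].copy()
        df["half"] = half
        df["category"] = cat
        df["raw_sum"] = cat
        df["max_sum"] = len(thr)
        df["complete"] = True
        out.append(df)
    return pd.concat(out, ignore_index=True)


def simulate_bivariate_parcels(
    n_subjects: int,
    time_points: int,
    rho: float,
    trait_vars=(1.0, 1.0),
    state_vars=(0.25, 0.25),
    thresholds=(-1.2, 0.0, 1.2),
    tasks=("direct_causal_inference", "quantity_discrimination"),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parcel indicators for two tasks whose traits correlate at ``rho``.

    Generative mirror of the pairwise LST model: traits bivariate normal,
    state residuals and measurement errors independent across tasks.
    """
    if not -1 < rho < 1:
        raise ValueError("rho must lie in (-1, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    thr = np.asarray(thresholds, dtype=float)
    z = rng.standard_normal((2, n_subjects))
    t_a = np.sqrt(trait_vars[0]) * z[0]
    t_b = np.sqrt(trait_vars[1]) * (rho * z[0] + np.sqrt(1 - rho**2) * z[1])
    out = []
    for task, trait, sv in zip(tasks, (t_a, t_b), state_vars):
        frames = []
        zeta = np.sqrt(sv) * rng.standard_normal((n_subjects, time_points))
        base = trait[:, None] + zeta
        for half in (1, 2):
            ystar = base + rng.standard_normal(base.shape)
            cat = np.searchsorted(thr, ystar)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": np.repeat([f"s{i:04d}" for i in range(n_subjects)], time_points),
                        "task": task,
                        "phase": 1,
                        "time_point": np.tile(np.arange(1, time_points + 1), n_subjects),
                        "half": half,
                        "category": cat.ravel(),
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        if missing_rate > 0:
            drop = rng.random(len(df)) < missing_rate
            df.loc[drop, "category"] = np.nan
        out.append(df)
    return out[0], out[1]


def simulate_dataset(config: SimConfig) -> dict:
    """Convenience bundle: cohort + diary + abilities + outcomes for the configured mode."""
    subjects, diary = simulate_cohort(config)
    abilities = simulate_latent_abilities(config, subjects)
    bundle = {"config": config, "subjects": subjects, "diary": diary, "abilities": abilities}
    if config.mode == "trial_level":
        bundle["trials"] = simulate_trials(abilities, diary, config)
    else:
        bundle["parcels"] = simulate_parcels_direct(abilities, config)
    return bundle
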