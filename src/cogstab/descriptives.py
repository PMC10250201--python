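"""Task-level robustness summaries and retest-correlation descriptives.

Per time point: the mean proportion correct over subject-level means with a
95% t-interval, flagged against the task's chance level where one exists
(two-choice tasks: 0.5; gaze following has no chance level).  Across time
points: product-moment retest correlations of subject scores, annotated with
the temporal distance between sessions, plus a rank-correlation summary of
how retest correlations decay with lag.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CHANCE_LEVELS",
    "subject_scores",
    "timepoint_means",
    "retest_correlations",
    "retest_vs_lag",
    "plot_timepoint_means",
    "plot_retest_vs_lag",
]

#: chance performance where the task has a two-alternative structure
CHANCE_LEVELS = {
    "gaze_following": None,
    "direct_causal_inference": 0.5,
    "inference_by_exclusion": 0.5,
    "quantity_discrimination": 0.5,
    "delay_of_gratification": 0.5,
}


def subject_scores(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject proportion correct per (task, phase, time_point)."""
    g = trials.groupby(["task", "phase", "time_point", "subject_id"], sort=True)
    out = g["outcome"].agg(n_trials="size", n_correct="sum").reset_index()
    out["prop_correct"] = out["n_correct"] / out["n_trials"]
    return out


def timepoint_means(trials: pd.DataFrame, conf: float = 0.95) -> pd.DataFrame:
    """Mean proportion correct per (task, phase, time point) with a t-interval.

    The unit of analysis is the subject: subject-level proportions are
    averaged and the two-sided interval uses the t distribution on n-1
    degrees of freedom.  ``chance_flag`` records whether the interval lies
    above, overlaps, or lies below the task's chance level.
    """
    scores = subject_scores(trials)
    rows = []
    for (task, phase, tp), grp in scores.groupby(["task", "phase", "time_point"]):
        p = grp["prop_correct"].to_numpy()
        n = len(p)
        mean = p.mean()
        if n >= 2:
            se = p.std(ddof=1) / np.sqrt(n)
            tq = stats.t.ppf(0.5 + conf / 2, df=n - 1)
            lo, hi = mean - tq * se, mean + tq * se
        else:
            lo = hi = np.nan
            warnings.warn(f"single subject at {task} phase {phase} t{tp}: CI undefined")
        chance = CHANCE_LEVELS.get(task)
        if chance is None:
            flag = "not_applicable"
        elif np.isnan(lo):
            flag = "overlapping"
        elif lo > chance:
            flag = "above"
        elif hi < chance:
            flag = "below"
        else:
            flag = "overlapping"
        rows.append(
            {
                "task": task,
                "phase": phase,
                "time_point": tp,
                "n_subjects": n,
                "mean_prop_correct": mean,
                "ci_low": lo,
                "ci_high": hi,
                "chance_level": np.nan if chance is None else chance,
                "chance_flag": flag,
            }
        )
    return pd.DataFrame(rows)


def _session1_dates(trials: pd.DataFrame) -> pd.Series:
    d = trials[trials["session"] == 1]
    if d.empty:
        d = trials
    return d.groupby(["phase", "time_point"])["date"].min()


def retest_correlations(
    trials: pd.DataFrame, min_pairs: int = 3, within_phase_only: bool = True
) -> pd.DataFrame:
    """Pearson correlations of subject scores between time-point pairs, per task.

    Only subjects present at both time points enter; pairs with fewer than
    ``min_pairs`` complete subjects or zero variance at either occasion are
    omitted with a warning.  ``lag_days`` is the distance between the two
    occasions' first-session dates.
    """
    scores = subject_scores(trials)
    dates = _session1_dates(trials) if "date" in trials.columns else None
    rows = []
    for task, tgrp in scores.groupby("task"):
        wide = tgrp.pivot_table(
            index="subject_id", columns=["phase", "time_point"], values="prop_correct"
        )
        cols = list(wide.columns)
        for (p1, t1), (p2, t2) in itertools.combinations(cols, 2):
            if within_phase_only and p1 != p2:
                continue
            pair = wide[[(p1, t1), (p2, t2)]].dropna()
            if len(pair) < min_pairs:
                warnings.warn(
                    f"{task} ({p1},{t1})x({p2},{t2}): only {len(pair)} complete pairs"
                )
                continue
            a, b = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if a.std() == 0 or b.std() == 0:
                warnings.warn(f"{task} ({p1},{t1})x({p2},{t2}): zero variance")
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if dates is not None:
                lag = (pd.Timestamp(dates.loc[(p2, t2)]) - pd.Timestamp(dates.loc[(p1, t1)])).days
            else:
                lag = np.nan
            rows.append(
                {
                    "task": task,
                    "phase_1": p1,
                    "t1": t1,
                    "phase_2": p2,
                    "t2": t2,
                    "within_phase": p1 == p2,
                    "lag_days": abs(lag),
                    "r": r,
                    "n_pairs": len(pair),
                }
            )
    return pd.DataFrame(rows)


def retest_vs_lag(entries: pd.DataFrame, min_entries: int = 5) -> pd.DataFrame:
    """Per task: rank correlation (and descriptive slope) of retest r against lag.

    A negative rank correlation indicates that more distant occasions
    correlate less — decaying stability.  Descriptive only; no test.
    """
    rows = []
    for task, grp in entries.groupby("task"):
        if len(grp) < min_entries:
            continue
        lag = grp["lag_days"].to_numpy(dtype=float)
        r = grp["r"].to_numpy(dtype=float)
        if np.ptp(r) == 0 or np.ptp(lag) == 0:
            rho = 0.0
        else:
            rho = float(stats.spearmanr(lag, r).statistic)
        slope = float(np.polyfit(lag, r, 1)[0]) if np.ptp(lag) > 0 else np.nan
        rows.append(
            {"task": task, "n_entries": len(grp), "rank_corr": rho, "slope_per_day": slope}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# minimal figure mirrors (optional outputs)

def plot_timepoint_means(summary: pd.DataFrame, path=None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tasks = summary["task"].unique()
    fig, axes = plt.subplots(len(tasks), 1, figsize=(7, 2.2 * len(tasks)), sharex=True)
    axes = np.atleast_1d(axes)
    for ax, task in zip(axes, tasks):
        d = summary[summary["task"] == task].sort_values(["phase", "time_point"])
        x = (d["phase"] - 1) * d["time_point"].max() + d["time_point"]
        ax.errorbar(
            x, d["mean_prop_correct"],
            yerr=[d["mean_prop_correct"] - d["ci_low"], d["ci_high"] - d["mean_prop_correct"]],
            fmt="k+",
        )
        if d["chance_level"].notna().any():
            ax.axhline(d["chance_level"].dropna().iloc[0], ls="--", lw=0.8)
        ax.set_ylabel(task, fontsize=7)
        ax.set_ylim(0, 1)
    axes[-1].set_xlabel("time point (phases concatenated)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_retest_vs_lag(entries: pd.DataFrame, path=None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tasks = entries["task"].unique()
    fig, axes = plt.subplots(1, len(tasks), figsize=(2.6 * len(tasks), 2.6), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, task in zip(axes, tasks):
        d = entries[entries["task"] == task]
        for ph, grp in d.groupby("phase_1"):
            ax.scatter(grp["lag_days"], grp["r"], s=8, label=f"phase {ph}")
        ax.set_title(task, fontsize=7)
        ax.set_xlabel("lag (days)")
    axes[0].set_ylabel("retest r")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
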