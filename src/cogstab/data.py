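"""Domain tables, trial-table I/O, test-half parceling and ordinal categorization.

The long-format trial table is the package's primary input: one row per
trial of one subject in one task at one time point.  Tasks are scored as
binary outcomes; for modelling, each task x time point is split into two
parallel test halves whose correct-trial sums act as ordinal indicators of a
common latent state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TASKS",
    "GROUPS",
    "PREDICTORS",
    "PREDICTOR_CATEGORIES",
    "SchemaError",
    "IntegrityError",
    "DegeneracyError",
    "read_trial_table",
    "write_trial_table",
    "validate_trials",
    "make_parcels",
    "CategoryMap",
    "build_category_map",
    "categorize_parcels",
    "validate_diary",
]

#: Per-time-point trial counts per task.
TASKS: dict[str, int] = {
    "gaze_following": 8,
    "direct_causal_inference": 12,
    "inference_by_exclusion": 12,
    "quantity_discrimination": 12,
    "delay_of_gratification": 12,
}

#: Social groups (one per species, chimpanzees housed in two groups).
GROUPS = ("bonobo", "chimpanzee_A", "chimpanzee_B", "gorilla", "orangutan")

#: The 14 performance predictors, keyed by the kind of variation they capture.
PREDICTOR_CATEGORIES: dict[str, str] = {
    "group": "stable_individual",
    "age": "stable_individual",
    "sex": "stable_individual",
    "rearing_history": "stable_individual",
    "time_in_research": "stable_individual",
    "rank": "variable_individual",
    "sickness": "variable_individual",
    "sociality": "variable_individual",
    "time_outdoors": "group_life",
    "disturbances": "group_life",
    "life_events": "group_life",
    "observer_present": "testing_arrangement",
    "study_same_day": "testing_arrangement",
    "study_since_last": "testing_arrangement",
}
PREDICTORS = tuple(PREDICTOR_CATEGORIES)

TRIAL_COLUMNS = (
    "subject_id",
    "group",
    "task",
    "phase",
    "time_point",
    "session",
    "trial_index",
    "outcome",
    "date",
)


class SchemaError(ValueError):
    """Input table does not have the required columns/types."""


class IntegrityError(ValueError):
    """Rows violate design invariants; carries row indices in the message."""


class DegeneracyError(ValueError):
    """An indicator carries no information (fewer than 2 observed levels)."""


# ---------------------------------------------------------------------------
# trial table I/O and validation

def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the design invariants.

    Raises :class:`SchemaError` / :class:`IntegrityError` with row-indexed
    diagnostics; returns a normalized copy (sorted dtypes, ISO dates).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    out = df.copy()

    problems: list[str] = []

    def _bad(mask, why):
        idx = out.index[np.asarray(mask)]
        if len(idx):
            problems.append(f"{why} (rows {list(idx[:10])}{'...' if len(idx) > 10 else ''})")

    out["outcome"] = pd.to_numeric(out["outcome"], errors="coerce")
    _bad(~out["outcome"].isin([0, 1]), "outcome not coercible to {0,1}")
    _bad(~out["task"].isin(TASKS), "unknown task")
    _bad(~out["group"].isin(GROUPS), "unknown group")
    for col in ("phase", "time_point", "session", "trial_index"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    _bad(~out["phase"].isin([1, 2]), "phase must be 1 or 2")
    _bad(~out["time_point"].between(1, 14), "time_point must be 1..14")
    _bad(~out["session"].isin([1, 2]), "session must be 1 or 2")
    _bad(out["trial_index"] < 1, "trial_index must be >= 1")
    max_trials = out["task"].map(TASKS)
    _bad(out["trial_index"] > max_trials, "trial_index exceeds the task's trial count")
    _bad(
        (out["task"] == "delay_of_gratification") & (out["phase"] == 1),
        "delay_of_gratification occurs only in phase 2",
    )
    if problems:
        raise IntegrityError("; ".join(problems))

    key = ["subject_id", "task", "phase", "time_point", "trial_index"]
    dup = out.duplicated(subset=key)
    if dup.any():
        raise IntegrityError(
            f"duplicate design key {key} (rows {list(out.index[dup][:10])})"
        )
    out["date"] = pd.to_datetime(out["date"]).dt.date
    for col in ("phase", "time_point", "session", "trial_index", "outcome"):
        out[col] = out[col].astype(int)
    return out


def read_trial_table(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a CSV trial table.

    ``schema`` optionally maps required column names to the names used in the
    file (e.g. ``{"subject_id": "ape"}``).
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return validate_trials(df)


def write_trial_table(df: pd.DataFrame, path) -> None:
    df = df.loc[:, list(TRIAL_COLUMNS)]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# parceling

def make_parcels(trials: pd.DataFrame, scheme: str = "alternating") -> pd.DataFrame:
    """Split each (subject, task, phase, time_point) trial set into two test halves.

    scheme="alternating": odd trial indices -> half 1, even -> half 2.
    scheme="session_balanced": alternate within each session, so both halves
    draw equally on both sessions (relevant for gaze following, whose trials
    come in pairs at the start and end of each session).

    Incomplete trial sets are retained with ``raw_sum`` set to NA and
    ``complete=False`` so that models tolerating missingness can keep the cell.
    """
    if scheme not in ("alternating", "session_balanced"):
        raise ValueError(f"unknown parcel scheme {scheme!r}")
    t = trials.copy()
    if scheme == "alternating":
        t["half"] = np.where(t["trial_index"] % 2 == 1, 1, 2)
    else:
        order = t.groupby(
            ["subject_id", "task", "phase", "time_point", "session"]
        )["trial_index"].rank(method="first").astype(int)
        t["half"] = np.where(order % 2 == 1, 1, 2)

    keys = ["subject_id", "group", "task", "phase", "time_point"]
    cells = t.groupby(keys, sort=True)["outcome"].size().rename("n_present").reset_index()
    sums = (
        t.groupby(keys + ["half"], sort=True)["outcome"].sum().rename("raw_sum").reset_index()
    )
    # two rows per cell even if all its trials landed in one half
    full = cells.merge(pd.DataFrame({"half": [1, 2]}), how="cross")
    full = full.merge(sums, on=keys + ["half"], how="left")
    full["raw_sum"] = full["raw_sum"].fillna(0)
    full["expected"] = full["task"].map(TASKS)
    full["max_sum"] = full["expected"] // 2
    full["complete"] = full["n_present"] == full["expected"]
    full.loc[~full["complete"], "raw_sum"] = np.nan
    full["raw_sum"] = full["raw_sum"].astype("Int64")
    return full[keys + ["half", "raw_sum", "max_sum", "complete"]]


# ---------------------------------------------------------------------------
# ordinal categorization of parcel raw sums

@dataclass(frozen=True)
class CategoryMap:
    """Monotone mapping from parcel raw sums to contiguous ordinal categories.

    Raw-sum levels observed too rarely are merged with neighbouring levels so
    that every retained category strictly exceeds ``min_prop`` marginal
    frequency (the merge rule; recorded with the map for provenance).
    """

    task: str
    half: int
    mapping: dict[int, int] = field(compare=True)
    min_prop: float = 0.05

    @property
    def n_categories(self) -> int:
        return max(self.mapping.values()) + 1

    def apply(self, raw_sum):
        arr = pd.Series(np.asarray(raw_sum).ravel())
        known = sorted(self.mapping)
        # clamp unseen extremes into the outer observed levels
        clamped = arr.clip(lower=known[0], upper=known[-1])
        filled = clamped.where(clamped.isin(known))
        if filled.isna().any() and not arr.isna().any():
            # unseen interior level: snap to nearest mapped level
            filled = clamped.map(lambda v: min(known, key=lambda k: abs(k - v)) if pd.notna(v) else v)
        out = filled.map(self.mapping)
        return out.to_numpy(dtype=float).reshape(np.shape(raw_sum))

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "half": self.half,
            "min_prop": self.min_prop,
            "mapping": {str(k): v for k, v in self.mapping.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryMap":
        return cls(
            task=d["task"],
            half=int(d["half"]),
            mapping={int(k): int(v) for k, v in d["mapping"].items()},
            min_prop=float(d.get("min_prop", 0.05)),
        )


def build_category_map(parcels: pd.DataFrame, min_prop: float = 0.05) -> CategoryMap:
    """Collapse a (task, half)'s raw-sum levels into ordinal categories.

    Levels whose marginal relative frequency does not exceed ``min_prop`` are
    merged inward with the neighbouring level, starting from the tails of the
    distribution, until all categories exceed ``min_prop`` or only two remain.
    """
    tasks = parcels["task"].unique()
    halves = parcels["half"].unique()
    if len(tasks) != 1 or len(halves) != 1:
        raise ValueError("build_category_map expects parcels of a single (task, half)")
    raw = parcels["raw_sum"].dropna().astype(int)
    counts = raw.value_counts().sort_index()
    if len(counts) < 2:
        raise DegeneracyError(
            f"indicator ({tasks[0]}, half {halves[0]}) has {len(counts)} distinct raw sums"
        )
    levels = [[lvl] for lvl in counts.index]
    freqs = list(counts.to_numpy() / counts.sum())

    def deficient():
        return [i for i, f in enumerate(freqs) if f <= min_prop]

    while len(freqs) > 2 and deficient():
        cand = deficient()
        # the deficient level closest to a tail merges first (tie -> left tail)
        i = min(cand, key=lambda j: min(j, len(freqs) - 1 - j))
        if i <= (len(freqs) - 1) / 2:
            j = i + 1  # merge inward, to the right
        else:
            j = i - 1
        lo, hi = min(i, j), max(i, j)
        levels[lo] = levels[lo] + levels[hi]
        freqs[lo] = freqs[lo] + freqs[hi]
        del levels[hi], freqs[hi]

    mapping = {lvl: k for k, grp in enumerate(levels) for lvl in sorted(grp)}
    return CategoryMap(task=tasks[0], half=int(halves[0]), mapping=mapping, min_prop=min_prop)


def categorize_parcels(
    parcels: pd.DataFrame, min_prop: float = 0.05
) -> tuple[pd.DataFrame, dict[tuple[str, int], CategoryMap]]:
    """Attach ordinal ``category`` levels to parcels, per (task, half).

    Returns the augmented table and the category maps used (serializable).
    """
    out = parcels.copy()
    out["category"] = np.nan
    maps: dict[tuple[str, int], CategoryMap] = {}
    for (task, half), grp in parcels.groupby(["task", "half"]):
        cmap = build_category_map(grp, min_prop=min_prop)
        maps[(task, int(half))] = cmap
        mask = (out["task"] == task) & (out["half"] == half) & out["raw_sum"].notna()
        out.loc[mask, "category"] = cmap.apply(out.loc[mask, "raw_sum"].astype(int).to_numpy())
    return out, maps


# ---------------------------------------------------------------------------
# predictor diary

def validate_diary(diary: pd.DataFrame) -> pd.DataFrame:
    """Validate the long-format predictor diary (subject x time point x predictor)."""
    required = {"subject_id", "time_point", "phase", "predictor", "value"}
    missing = required - set(diary.columns)
    if missing:
        raise SchemaError(f"diary missing column(s): {sorted(missing)}")
    bad = ~diary["predictor"].isin(PREDICTORS)
    if bad.any():
        raise IntegrityError(
            f"unknown predictor(s): {sorted(diary.loc[bad, 'predictor'].unique())}"
        )
    counts = diary.groupby(["subject_id", "phase", "time_point"])["predictor"].nunique()
    if (counts != len(PREDICTORS)).any():
        short = counts[counts != len(PREDICTORS)]
        raise IntegrityError(
            f"{len(short)} subject x time point cell(s) lack the full predictor set"
        )
    stable = [p for p, c in PREDICTOR_CATEGORIES.items() if c == "stable_individual"]
    sub = diary[diary["predictor"].isin(stable)]
    nun = sub.groupby(["subject_id", "predictor"])["value"].nunique()
    if (nun > 1).any():
        raise IntegrityError(
            f"stable predictors vary within subject: {nun[nun > 1].index.tolist()[:5]}"
        )
    out = diary.copy()
    out["category"] = out["predictor"].map(PREDICTOR_CATEGORIES)
    return out
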