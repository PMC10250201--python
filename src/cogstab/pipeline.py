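"""Config-driven orchestration of the full analysis pipeline.

Stages: data (simulate or load) -> parcels -> descriptives -> latent state
fits -> latent state-trait fits -> pairwise trait correlations -> predictor
projection.  Each stage persists its tables to the output directory with a
JSON metadata sidecar (config hash, wall time, warnings) and is skipped on
rerun when its inputs' hash is unchanged, unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .data import (
    TASKS,
    categorize_parcels,
    make_parcels,
    read_trial_table,
    validate_diary,
    write_trial_table,
)
from .descriptives import retest_correlations, retest_vs_lag, timepoint_means
from .ls import LatentStateModel
from .lst import BivariateLatentStateTraitModel, LatentStateTraitModel
from .projection import ProjectionPredictiveSelector, performance_counts
from .simulate import SimConfig, simulate_dataset

__all__ = ["RunConfig", "validate_config", "run_pipeline", "ReportBundle"]

STAGES = ["data", "parcels", "describe", "ls", "lst", "correlate", "project"]


@dataclass
class RunConfig:
    """Validated pipeline configuration (seed mandatory; one input mode)."""

    seed: int
    mode: str = "simulate"
    out_dir: str = "cogstab_run"
    trials_path: str | None = None
    diary_path: str | None = None
    sim: dict = field(default_factory=dict)
    tasks: list | None = None
    phases: list = field(default_factory=lambda: [1, 2])
    parcel_scheme: str = "alternating"
    min_prop: float = 0.05
    sampler: dict = field(default_factory=dict)
    projection: dict = field(default_factory=dict)
    pairwise: bool = True
    force: bool = False

    def task_list(self):
        return list(self.tasks) if self.tasks else list(TASKS)

    def cells(self):
        for task, phase in itertools.product(self.task_list(), self.phases):
            if task == "delay_of_gratification" and phase == 1:
                continue
            yield task, phase

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("force", None)
        d.pop("out_dir", None)
        return hashlib.sha1(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


def validate_config(raw: dict):
    """Check a raw config mapping; returns (RunConfig, errors).

    Every violation is reported with its field path; the config is only
    usable when the error list is empty.
    """
    errors = []
    if "seed" not in raw or raw["seed"] is None:
        errors.append("seed: a seed is mandatory")
    mode = raw.get("mode", "simulate")
    if mode not in ("simulate", "load"):
        errors.append(f"mode: must be 'simulate' or 'load', got {mode!r}")
    if mode == "load":
        if not raw.get("trials_path"):
            errors.append("trials_path: required in load mode")
    if mode == "simulate" and raw.get("trials_path"):
        errors.append("trials_path: not allowed in simulate mode (exactly one input mode)")
    tasks = raw.get("tasks")
    if tasks:
        unknown = set(tasks) - set(TASKS)
        if unknown:
            errors.append(f"tasks: unknown {sorted(unknown)}")
    phases = raw.get("phases", [1, 2])
    if not set(phases) <= {1, 2}:
        errors.append(f"phases: must be a subset of [1, 2], got {phases}")
    if tasks and list(tasks) == ["delay_of_gratification"] and list(phases) == [1]:
        errors.append("tasks/phases: delay_of_gratification is run in phase 2 only")
    if raw.get("parcel_scheme", "alternating") not in ("alternating", "session_balanced"):
        errors.append("parcel_scheme: unknown scheme")
    mp = raw.get("min_prop", 0.05)
    if not (0 <= mp < 0.5):
        errors.append("min_prop: must lie in [0, 0.5)")
    if errors:
        return None, errors
    known = {f.name for f in dataclasses.fields(RunConfig)}
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    try:
        SimConfig(seed=cfg.seed, **cfg.sim).validate()
    except (TypeError, ValueError) as e:
        return None, [f"sim: {e}"]
    return cfg, []


@dataclass
class ReportBundle:
    """Per-stage tables plus run metadata; ``partial`` when a stage failed."""

    out_dir: Path
    tables: dict
    metadata: dict
    partial: bool = False


class _Stage:
    def __init__(self, root: Path, name: str, cfg_hash: str, force: bool):
        self.dir = root / name
        self.name = name
        self.cfg_hash = cfg_hash
        self.force = force
        self.meta_path = self.dir / "stage.json"

    def is_done(self) -> bool:
        if self.force or not self.meta_path.exists():
            return False
        try:
            meta = json.loads(self.meta_path.read_text())
        except json.JSONDecodeError:
            return False
        return meta.get("config_hash") == self.cfg_hash and meta.get("status") == "ok"

    def finish(self, n_warnings: int, t0: float):
        self.meta_path.write_text(
            json.dumps(
                {
                    "stage": self.name,
                    "status": "ok",
                    "config_hash": self.cfg_hash,
                    "wall_time_s": round(time.time() - t0, 2),
                    "n_warnings": n_warnings,
                    "version": __version__,
                },
                indent=1,
            )
        )


def _write(df: pd.DataFrame, path: Path, meta: dict):
    df.to_csv(path, index=False)
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1, default=str))


def run_pipeline(config: RunConfig, until: str = "project") -> ReportBundle:
    """Execute the pipeline in stage order up to ``until``.

    A failing stage marks the bundle partial and skips downstream stages,
    preserving its diagnostics in the metadata.
    """
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    (root / "run_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=1, default=str)
    )
    tables: dict = {}
    metadata: dict = {"config_hash": cfg_hash, "version": __version__, "stages": {}}
    partial = False
    stop = STAGES.index(until)

    sampler_kw = dict(config.sampler)
    state: dict = {}
    for name in STAGES[: stop + 1]:
        stage = _Stage(root, name, cfg_hash, config.force)
        stage.dir.mkdir(exist_ok=True)
        t0 = time.time()
        if stage.is_done():
            try:
                _load_stage(name, stage.dir, tables, state)
                metadata["stages"][name] = {"status": "cached"}
                continue
            except FileNotFoundError:
                pass
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                _run_stage(name, config, stage.dir, tables, state, sampler_kw)
            stage.finish(len(caught), t0)
            metadata["stages"][name] = {"status": "ok", "n_warnings": len(caught)}
        except Exception as e:  # noqa: BLE001 - stage isolation is the point
            metadata["stages"][name] = {"status": "failed", "error": repr(e)}
            partial = True
            break
    (root / "report.json").write_text(json.dumps(metadata, indent=1, default=str))
    return ReportBundle(out_dir=root, tables=tables, metadata=metadata, partial=partial)


def _load_stage(name, out, tables, state):
    """Reload a cached stage's artifacts so downstream stages can run."""
    if name == "data":
        state["trials"] = tables["trials"] = read_trial_table(out / "trials.csv")
        diary_path = out / "diary.csv"
        diary = pd.read_csv(diary_path) if diary_path.exists() else None
        state["diary"] = tables["diary"] = diary
    elif name == "parcels":
        state["parcels"] = tables["parcels"] = pd.read_csv(out / "parcels.csv")
    else:
        for csv in out.glob("*.csv"):
            tables[csv.stem] = pd.read_csv(csv)


def _run_stage(name, config, out, tables, state, sampler_kw):
    seed = config.seed
    if name == "data":
        if config.mode == "simulate":
            sim = SimConfig(seed=seed, **config.sim)
            bundle = simulate_dataset(sim)
            trials, diary = bundle.get("trials"), bundle["diary"]
            if trials is None:
                raise ValueError("pipeline requires trial_level simulation mode")
            write_trial_table(trials, out / "trials.csv")
            diary.to_csv(out / "diary.csv", index=False)
        else:
            trials = read_trial_table(config.trials_path)
            diary = (
                validate_diary(pd.read_csv(config.diary_path))
                if config.diary_path
                else None
            )
            write_trial_table(trials, out / "trials.csv")
            if diary is not None:
                diary.to_csv(out / "diary.csv", index=False)
        state["trials"], state["diary"] = trials, diary
        tables["trials"], tables["diary"] = trials, diary
    elif name == "parcels":
        trials = state["trials"]
        keep = trials[trials["task"].isin(config.task_list()) & trials["phase"].isin(config.phases)]
        parcels = make_parcels(keep, scheme=config.parcel_scheme)
        parcels, cmaps = categorize_parcels(parcels, min_prop=config.min_prop)
        _write(parcels, out / "parcels.csv", {"scheme": config.parcel_scheme, "min_prop": config.min_prop})
        (out / "category_maps.json").write_text(
            json.dumps([m.to_dict() for m in cmaps.values()], indent=1)
        )
        state["parcels"] = parcels
        tables["parcels"] = parcels
    elif name == "describe":
        trials = state["trials"]
        tp = timepoint_means(trials)
        rt = retest_correlations(trials)
        lag = retest_vs_lag(rt)
        _write(tp, out / "timepoint_means.csv", {})
        _write(rt, out / "retest_correlations.csv", {})
        _write(lag, out / "retest_vs_lag.csv", {})
        tables["timepoint_means"], tables["retest"], tables["retest_vs_lag"] = tp, rt, lag
    elif name == "ls":
        rows = []
        flags = []
        for task, phase in config.cells():
            cell = state["parcels"].query("task == @task and phase == @phase")
            if cell["category"].dropna().empty:
                continue
            m = LatentStateModel(seed=seed, **sampler_kw).fit(cell)
            s = m.summary_.reset_index()
            s.insert(0, "task", task)
            s.insert(1, "phase", phase)
            rows.append(s)
            f = m.state_mean_change()
            f.insert(0, "task", task)
            f.insert(1, "phase", phase)
            flags.append(f)
        tables["ls_summary"] = pd.concat(rows, ignore_index=True)
        tables["state_mean_change"] = pd.concat(flags, ignore_index=True)
        _write(tables["ls_summary"], out / "ls_summary.csv", sampler_kw)
        _write(tables["state_mean_change"], out / "state_mean_change.csv", {})
    elif name == "lst":
        rows = []
        for task, phase in config.cells():
            cell = state["parcels"].query("task == @task and phase == @phase")
            if cell["category"].dropna().empty:
                continue
            m = LatentStateTraitModel(seed=seed, **sampler_kw).fit(cell)
            for comp, frame in [
                ("consistency", m.consistency_),
                ("occasion_specificity", m.occasion_specificity_),
                ("reliability", m.reliability_),
            ]:
                f = frame.copy()
                f.insert(0, "task", task)
                f.insert(1, "phase", phase)
                f.insert(2, "component", comp)
                rows.append(f)
        tables["lst_components"] = pd.concat(rows, ignore_index=True)
        _write(tables["lst_components"], out / "lst_components.csv", sampler_kw)
    elif name == "correlate":
        if not config.pairwise:
            return
        rows = []
        for phase in config.phases:
            tasks = [t for t, p in config.cells() if p == phase]
            for a, b in itertools.combinations(tasks, 2):
                pa = state["parcels"].query("task == @a and phase == @phase")
                pb = state["parcels"].query("task == @b and phase == @phase")
                if pa["category"].dropna().empty or pb["category"].dropna().empty:
                    continue
                m = BivariateLatentStateTraitModel(seed=seed, **sampler_kw).fit(pa, pb)
                rows.append(
                    {
                        "phase": phase,
                        "task_a": a,
                        "task_b": b,
                        **{k: v for k, v in m.trait_corr_.items()},
                        "substantial": m.substantial_,
                    }
                )
        tables["trait_correlations"] = pd.DataFrame(rows)
        _write(tables["trait_correlations"], out / "trait_correlations.csv", {})
    elif name == "project":
        if state.get("diary") is None:
            return
        rows = []
        for task, phase in config.cells():
            counts = performance_counts(state["trials"], task, phase)
            if counts.empty:
                continue
            sel = ProjectionPredictiveSelector(seed=seed, **config.projection).fit(
                counts, state["diary"], phase=phase
            )
            r = sel.ranking_.copy()
            r.insert(0, "task", task)
            r.insert(1, "phase", phase)
            rows.append(r)
        tables["predictor_ranking"] = pd.concat(rows, ignore_index=True)
        _write(tables["predictor_ranking"], out / "predictor_ranking.csv", config.projection)
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {name}")
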