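"""Simulation-study harness.

Runs simulation sets (default 1000 simulations of 500 trials), applies
both exploration estimators and the learning metric to every
simulation, and sweeps one parameter at a time over the study grid
while holding the others at their defaults. Within a set all models
consume the same raw noise draws per simulation index (common random
numbers), so between-model differences are not confounded by sampling
noise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .estimators import attc_estimate, similarity_ratio, ttc_estimate
from .metrics import learning_metric
from .models import (
    Model,
    NoiseDraws,
    TrialSeries,
    draw_noise_vectors,
    simulate_trials,
)
from .params import (
    FIXED_ALPHA_MODELS,
    Criterion,
    LearnerParams,
    TaskParams,
)

#: One-at-a-time sweep grid: each parameter's values, defaults in
#: LearnerParams / TaskParams (sigma2_m = 9, sigma2_eta_star = 16,
#: alpha = 0.15, target 4 sigma_m, adaptive mean criterion).
TABLE_GRID: dict[str, list] = {
    "sigma2_m": [1, 4, 9, 16, 25],
    "sigma2_eta_star": [1, 4, 16, 36, 64],
    "alpha": [0, 0.1, 0.15, 0.2, 1],
    "target_sigma_units": [0, 2, 4, 6, 8],
    "criterion": [
        Criterion.RANDOM,
        Criterion.ADAPTIVE_MEDIAN,
        Criterion.ADAPTIVE_MEAN,
        Criterion.FIXED,
        Criterion.FIXED_LOW_TARGET,
    ],
}

METHODS = ("ttc", "attc")


@dataclass
class SimulationSet:
    """One (model, parameter set) run: per-simulation estimates, SRs and
    learning scores. Undefined estimates are NaN, never dropped."""

    model: Model
    learner: LearnerParams
    task: TaskParams
    n_sims: int
    n_trials: int
    seed: int
    sr: dict[str, np.ndarray] = field(default_factory=dict)
    sigma2_eta_hat: dict[str, np.ndarray] = field(default_factory=dict)
    learning: np.ndarray | None = None
    series: list[TrialSeries] | None = None


@dataclass(frozen=True)
class SRSummary:
    """Mean/SD (population) of the defined similarity ratios of a set,
    with the fraction of undefined estimates reported explicitly."""

    mean: float
    sd: float
    undefined_fraction: float
    n: int


def run_simulation_set(
    model: Model,
    learner: LearnerParams | None = None,
    task: TaskParams | None = None,
    n_sims: int = 1000,
    n_trials: int = 500,
    seed: int = 0,
    draws: Sequence[NoiseDraws] | None = None,
    methods: Sequence[str] = METHODS,
    keep_series: bool = False,
) -> SimulationSet:
    """Simulate a set and estimate exploration in every simulation.

    Pass a pre-built ``draws`` bank to share raw noise across models.
    Learning is scored only when the resolved target is nonzero.
    """
    model = Model(model)
    learner = learner if learner is not None else LearnerParams()
    task = task if task is not None else TaskParams()
    if draws is None:
        draws = draw_noise_vectors(n_trials, n_sims, seed)
    else:
        n_sims = len(draws)
        n_trials = draws[0].n_trials

    estimators = {"ttc": ttc_estimate, "attc": attc_estimate}
    unknown = set(methods) - set(estimators)
    if unknown:
        raise ValueError(f"unknown estimation method(s) {sorted(unknown)}")

    sr = {m: np.empty(n_sims) for m in methods}
    hat = {m: np.empty(n_sims) for m in methods}
    learning = np.empty(n_sims)
    resolved_target = task.resolve(learner).target
    kept: list[TrialSeries] = []
    for i, d in enumerate(draws):
        series = simulate_trials(model, learner, task, d)
        for meth in methods:
            est = estimators[meth](series)
            hat[meth][i] = est.sigma2_eta_hat
            sr[meth][i] = similarity_ratio(est, learner.sigma2_eta_star)
        learning[i] = (
            learning_metric(series.ep, resolved_target).percent
            if resolved_target != 0
            else math.nan
        )
        if keep_series:
            kept.append(series)
    return SimulationSet(
        model=model,
        learner=learner,
        task=task,
        n_sims=n_sims,
        n_trials=n_trials,
        seed=seed,
        sr=sr,
        sigma2_eta_hat=hat,
        learning=learning,
        series=kept if keep_series else None,
    )


def aggregate_sr(simset: SimulationSet, method: str = "attc") -> SRSummary:
    """Mean and population SD of the defined SRs of one set."""
    values = np.asarray(simset.sr[method], dtype=float)
    defined = values[np.isfinite(values)]
    undefined_fraction = 1.0 - len(defined) / len(values)
    if len(defined) == 0:
        return SRSummary(math.nan, math.nan, 1.0, 0)
    sd = float(np.std(defined, ddof=0)) if len(defined) > 1 else math.nan
    return SRSummary(
        mean=float(np.mean(defined)),
        sd=sd,
        undefined_fraction=float(undefined_fraction),
        n=len(defined),
    )


def _set_value(
    learner: LearnerParams, task: TaskParams, param: str, value
) -> tuple[LearnerParams, TaskParams]:
    if param in ("sigma2_m", "sigma2_eta_star", "alpha"):
        return dataclasses.replace(learner, **{param: value}), task
    if param in ("target_sigma_units", "criterion"):
        return learner, dataclasses.replace(task, **{param: value})
    raise ValueError(f"unknown sweep parameter {param!r}")


def sweep(
    models: Sequence[Model] = tuple(Model),
    grid: dict[str, list] | None = None,
    defaults: LearnerParams | None = None,
    task_defaults: TaskParams | None = None,
    n_sims: int = 1000,
    n_trials: int = 500,
    seed: int = 0,
    out_dir: str | Path | None = None,
    methods: Sequence[str] = METHODS,
    progress: bool = False,
) -> pd.DataFrame:
    """One-at-a-time parameter sweep over the study grid.

    Every (varied parameter, value) defines a simulation set; within a
    set all models share the same noise-draw bank. Intermediate alpha
    values are skipped for the Therrien models, whose learning fraction
    is fixed at 1 (only alpha in {0, 1} is meaningful). Returns a tidy
    frame with one row per set x model x method; with ``out_dir`` the
    frame is also written to ``sweep_summary.csv`` there.
    """
    grid = dict(TABLE_GRID if grid is None else grid)
    defaults = defaults if defaults is not None else LearnerParams()
    task_defaults = task_defaults if task_defaults is not None else TaskParams()
    for param, values in grid.items():  # validate before simulating
        for value in values:
            _set_value(defaults, task_defaults, param, value)
    models = [Model(m) for m in models]

    rows = []
    set_index = 0
    for param, values in grid.items():
        for value in values:
            learner, task = _set_value(defaults, task_defaults, param, value)
            set_seed = _set_seed(seed, set_index)
            draws = draw_noise_vectors(n_trials, n_sims, set_seed)
            for model in models:
                if (
                    param == "alpha"
                    and model in FIXED_ALPHA_MODELS
                    and value not in (0, 1)
                ):
                    continue
                if progress:
                    print(f"[sweep] {param}={value} model={model.value}")
                simset = run_simulation_set(
                    model, learner, task, seed=set_seed, draws=draws,
                    methods=methods,
                )
                mean_learning = (
                    float(np.nanmean(simset.learning))
                    if np.isfinite(simset.learning).any()
                    else math.nan
                )
                for meth in methods:
                    summary = aggregate_sr(simset, meth)
                    rows.append(
                        {
                            "set": set_index,
                            "model": model.value,
                            "param": param,
                            "value": getattr(value, "value", value),
                            "method": meth,
                            "mean_sr": summary.mean,
                            "sd_sr": summary.sd,
                            "undefined_fraction": summary.undefined_fraction,
                            "n_defined": summary.n,
                            "mean_learning": mean_learning,
                            "n_sims": n_sims,
                            "n_trials": n_trials,
                            "seed": set_seed,
                        }
                    )
            set_index += 1
    frame = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / "sweep_summary.csv", index=False)
    return frame


def _set_seed(master_seed: int, set_index: int) -> int:
    """Deterministic per-set seed below 2**31."""
    return int(
        np.random.SeedSequence(
            entropy=master_seed, spawn_key=(set_index,)
        ).generate_state(1, dtype=np.uint32)[0]
        % (2**31)
    )


def sr_vs_learning(
    sets: Iterable[SimulationSet], methods: Sequence[str] = METHODS
) -> pd.DataFrame:
    """One row per simulation pairing SR (per method) with learning.

    The raw material for inspecting whether estimation quality depends
    on how much was learned.
    """
    rows = []
    for simset in sets:
        for i in range(simset.n_sims):
            row = {
                "model": simset.model.value,
                "sigma2_m": simset.learner.sigma2_m,
                "sigma2_eta_star": simset.learner.sigma2_eta_star,
                "alpha": simset.learner.alpha,
                "target_sigma_units": simset.task.target_sigma_units,
                "criterion": simset.task.criterion.value,
                "sim": i,
                "learning_percent": float(simset.learning[i]),
            }
            for meth in methods:
                row[f"sr_{meth}"] = float(simset.sr[meth][i])
            rows.append(row)
    return pd.DataFrame(rows)
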