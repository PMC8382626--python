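"""Trial-log CSV and configuration file I/O.

The trial-log dialect is fixed (comma separator, '.' decimal, UTF-8,
mandatory header, 1-based trial numbers) to avoid locale drift.
Required columns: ``trial``, ``endpoint``, ``reward`` (strictly 0/1);
optional latent columns: ``aim_point``, ``exploration``,
``motor_noise``, ``reward_history``, ``sigma2_eta``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .models import Model, TrialSeries
from .params import Criterion, LearnerParams, TaskParams

REQUIRED_COLUMNS = ("trial", "endpoint", "reward")
LATENT_COLUMNS = {
    "aim_point": "ap",
    "exploration": "eta",
    "motor_noise": "m",
    "reward_history": "rbar",
    "sigma2_eta": "sigma2_eta",
}


def write_trial_series(series: TrialSeries, path: str | Path) -> Path:
    """Write a series to CSV at full float precision, stable column order."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {
        "trial": np.arange(1, series.n_trials + 1),
        "endpoint": series.ep,
        "reward": np.asarray(series.reward, dtype=int),
    }
    for col, attr in LATENT_COLUMNS.items():
        value = getattr(series, attr)
        if value is not None:
            cols[col] = value
    # %.17g guarantees bit-exact float round-trips
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    return path


def read_trial_series(path: str | Path) -> TrialSeries:
    """Read and validate a trial-log CSV.

    Raises a descriptive error for missing required columns, non-binary
    reward values (naming the offending row), or non-contiguous trial
    numbers. Latent columns are optional; a series without them supports
    estimation but not latent-based diagnostics.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    reward = df["reward"].to_numpy()
    bad = ~np.isin(reward, (0, 1))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: non-binary reward {reward[row]!r} at data row "
            f"{row + 1} (trial {df['trial'].iloc[row]!r})"
        )
    trial = df["trial"].to_numpy()
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(trial, expected):
        raise ValueError(
            f"{path}: trial numbers must be contiguous 1..{len(df)}"
        )
    kwargs = {}
    for col, attr in LATENT_COLUMNS.items():
        if col in df.columns:
            kwargs[attr] = df[col].to_numpy(dtype=float)
    return TrialSeries(
        ep=df["endpoint"].to_numpy(dtype=float),
        reward=reward.astype(np.int8),
        **kwargs,
    )


def write_series_batch(
    series_list: Iterable[TrialSeries], directory: str | Path
) -> list[Path]:
    """Write one CSV per simulation with zero-padded indices."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_list = list(series_list)
    width = max(4, len(str(len(series_list))))
    paths = []
    for i, series in enumerate(series_list):
        paths.append(
            write_trial_series(
                series, directory / f"sim_{i + 1:0{width}d}.csv"
            )
        )
    return paths


CONFIG_KEYS = (
    "model",
    "sigma2_m",
    "sigma2_eta_star",
    "alpha",
    "tau",
    "target_sigma_units",
    "criterion",
    "zone_halfwidth",
    "history_window",
    "random_p",
    "n_trials",
    "n_sims",
    "seed",
)


def read_config(path: str | Path) -> dict:
    """Read a flat key-value YAML/JSON simulation configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"{path}: configuration must be a mapping")
    unknown = set(cfg) - set(CONFIG_KEYS) - {"grid"}
    if unknown:
        raise ValueError(f"{path}: unknown configuration key(s) {sorted(unknown)}")
    return dict(cfg)


def write_config(cfg: Mapping, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)
    return path


def config_to_params(
    cfg: Mapping,
) -> tuple[Model, LearnerParams, TaskParams, int, int, int]:
    """Split a flat config into model, learner, task and run parameters."""
    learner = LearnerParams(
        sigma2_m=float(cfg.get("sigma2_m", 9.0)),
        sigma2_eta_star=float(cfg.get("sigma2_eta_star", 16.0)),
        alpha=float(cfg.get("alpha", 0.15)),
        tau=float(cfg.get("tau", 5.0)),
    )
    task = TaskParams(
        target_sigma_units=float(cfg.get("target_sigma_units", 4.0)),
        criterion=Criterion(cfg.get("criterion", "adaptive_mean")),
        zone_halfwidth=float(cfg.get("zone_halfwidth", 1.0)),
        history_window=int(cfg.get("history_window", 10)),
        random_p=float(cfg.get("random_p", 0.5)),
    )
    model = Model(cfg.get("model", "therrien16"))
    return (
        model,
        learner,
        task,
        int(cfg.get("n_trials", 500)),
        int(cfg.get("n_sims", 1000)),
        int(cfg.get("seed", 0)),
    )
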