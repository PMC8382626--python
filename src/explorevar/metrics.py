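"""Learning quantification and pitfall diagnostics."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import TrialSeries


@dataclass(frozen=True)
class LearningScore:
    """Learning as area under the smoothed endpoint curve relative to the
    target: 0% for no learning, 100% for instant full learning. Series
    that overshoot the target can exceed 100%; values are not clipped."""

    percent: float
    window: int


def learning_metric(
    ep: np.ndarray, target: float, window: int = 20
) -> LearningScore:
    """Single-number learning score of an endpoint series.

    The series is smoothed with a trailing running average of ``window``
    trials (shrinking partial windows at the start), and the area under
    the smoothed curve (rectangle rule) is divided by the area under the
    target.
    """
    if target == 0:
        raise ValueError("learning metric undefined for target = 0")
    ep = np.asarray(ep, dtype=float)
    if len(ep) < window:
        raise ValueError(
            f"series of length {len(ep)} shorter than window {window}"
        )
    smoothed = pd.Series(ep).rolling(window, min_periods=1).mean().to_numpy()
    percent = 100.0 * smoothed.sum() / (target * len(ep))
    return LearningScore(percent=float(percent), window=window)


def average_learning_curve(
    series_set: Iterable[TrialSeries | np.ndarray],
) -> pd.DataFrame:
    """Per-trial mean and population SD of endpoints across simulations.

    Returns a frame with columns ``trial`` (1-based), ``mean``, ``sd``
    (ddof 0). Requires at least two series of equal length.
    """
    eps = [
        np.asarray(s.ep if isinstance(s, TrialSeries) else s, dtype=float)
        for s in series_set
    ]
    if len(eps) < 2:
        raise ValueError("need at least two series")
    n = len(eps[0])
    if any(len(e) != n for e in eps):
        raise ValueError("all series must have equal length")
    mat = np.vstack(eps)
    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "mean": mat.mean(axis=0),
            "sd": mat.std(axis=0, ddof=0),
        }
    )


@dataclass(frozen=True)
class NoiseExplorationCorrelation:
    """Sample correlation of exploration and motor-noise draws, split by
    same-trial reward. Performance-dependent criteria select successful
    trials in which the two draws offset each other, so the rewarded
    correlation is negative even though the draws are generated
    independently; under a random criterion both are ~0."""

    rewarded: float
    unrewarded: float
    n_rewarded: int
    n_unrewarded: int


def noise_exploration_correlation(
    series: TrialSeries | Sequence[TrialSeries],
) -> NoiseExplorationCorrelation:
    """Correlation between eta(t) and m(t) on rewarded and non-rewarded
    trials, pooled over the given series. NaN for a category with fewer
    than 3 trials or zero variance in either variable."""
    if isinstance(series, TrialSeries):
        series = [series]
    etas, ms, rs = [], [], []
    for s in series:
        if not s.has_latents:
            raise ValueError("series lacks logged exploration / motor noise")
        etas.append(np.asarray(s.eta, dtype=float))
        ms.append(np.asarray(s.m, dtype=float))
        rs.append(np.asarray(s.reward, dtype=int))
    eta = np.concatenate(etas)
    m = np.concatenate(ms)
    r = np.concatenate(rs)

    def corr(mask: np.ndarray) -> float:
        if mask.sum() < 3:
            return math.nan
        x, y = eta[mask], m[mask]
        if np.std(x) == 0 or np.std(y) == 0:
            return math.nan
        return float(np.corrcoef(x, y)[0, 1])

    rewarded = r == 1
    return NoiseExplorationCorrelation(
        rewarded=corr(rewarded),
        unrewarded=corr(~rewarded),
        n_rewarded=int(rewarded.sum()),
        n_unrewarded=int((~rewarded).sum()),
    )
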