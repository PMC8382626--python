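"""Trial-to-trial-change estimators of exploration variance.

Both estimators separate exploration from motor noise by comparing
detrended variability following non-successful and successful trials,
with variability measured as the median of squared trial-to-trial
changes (robust to the mean shift that learning produces).

TTC: lag-1 changes classified by the reward on the reference trial
t-1; the difference of median squared changes is converted to a
variance with the Thirey-Hickman factor pi/4 and a model-specific
correction factor ``a`` for residual post-success exploration.

ATTC: lag-2 changes (reference trial t-2, immune to the selection bias
of performance-dependent reward) classified by the three-trial reward
sequence (R(t-3), R(t-2), R(t-1)). Only the two sequence sets whose
post-failure minus post-success difference isolates a single
exploration draw — C = (0,1,.) and D = (1,1,.) — contribute; the
single-draw conversion factor 2.19 (the reciprocal of the median of a
chi-square(1) variable) replaces pi/4.

Estimates may legitimately come out negative and are never clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import Model, TrialSeries, reward_history_series

#: Conversion factor between a median squared change built from a
#: single Gaussian draw and the variance of that draw (rounded value
#: used in the weighted estimate; see :func:`single_draw_factor_derived`).
SINGLE_DRAW_FACTOR = 2.19

#: Correction factor for residual post-success exploration in the
#: Therrien18 model: 1 / (1 - 0.12).
T18_CORRECTION = 1.14

#: Minimum changes per class before an estimate is flagged low-reliability.
DEFAULT_MIN_COUNT = 5

#: Retained three-trial sequence classes and their exploration-draw weights.
ATTC_ETA_WEIGHTS = {"C": 3.0, "D": 1.0}


@dataclass(frozen=True)
class ChangeSet:
    """Trial-to-trial changes Delta(t) = EP(t) - EP(t - lag).

    ``t`` holds the 1-based index of the target trial of each change.
    """

    deltas: np.ndarray
    t: np.ndarray
    lag: int


def trial_to_trial_changes(ep: np.ndarray, lag: int) -> ChangeSet:
    """Lag-1 (TTC) or lag-2 (ATTC) endpoint changes."""
    if lag not in (1, 2):
        raise ValueError(f"lag must be 1 or 2, got {lag}")
    ep = np.asarray(ep, dtype=float)
    if len(ep) <= lag:
        raise ValueError(f"series of length {len(ep)} too short for lag {lag}")
    deltas = ep[lag:] - ep[:-lag]
    t = np.arange(lag + 1, len(ep) + 1)
    return ChangeSet(deltas=deltas, t=t, lag=lag)


def _check_rewards(reward: np.ndarray) -> np.ndarray:
    r = np.asarray(reward)
    if not np.isin(r, (0, 1)).all():
        bad = r[~np.isin(r, (0, 1))][0]
        raise ValueError(f"reward values must be 0 or 1, got {bad!r}")
    return r.astype(int)


def classify_ttc(reward: np.ndarray) -> np.ndarray:
    """Labels for lag-1 changes: '+' post-success, '-' post-failure.

    The change ending at trial t is classified by R(t-1); eligible from
    t = 2, so the label array aligns with ``trial_to_trial_changes(ep, 1)``.
    """
    r = _check_rewards(reward)
    return np.where(r[:-1] == 1, "+", "-")


def classify_attc(reward: np.ndarray) -> np.ndarray:
    """Sequence-class labels for lag-2 changes.

    The change ending at trial t is classified by the reward triple
    (R(t-3), R(t-2), R(t-1)): set A = (0,0,.), B = (1,0,.), C = (0,1,.),
    D = (1,1,.); the sign suffix is R(t-1) ('-' failure, '+' success).
    Changes at t = 3 (no fully observed triple) are 'unclassified'.
    Aligns with ``trial_to_trial_changes(ep, 2)``.
    """
    r = _check_rewards(reward)
    n = len(r)
    labels = np.full(n - 2, "unclassified", dtype="<U12")
    if n < 4:
        return labels
    r3 = r[:-3]  # R(t-3) for t = 4..n
    r2 = r[1:-2]  # R(t-2)
    r1 = r[2:-1]  # R(t-1)
    sets = np.array(["A", "B", "C", "D"])[r3 * 1 + r2 * 2]
    signs = np.where(r1 == 1, "+", "-")
    labels[1:] = np.char.add(sets, signs)
    return labels


def median_sq(deltas: np.ndarray) -> float:
    """Median of squared changes; NaN (undefined) for an empty set."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        return math.nan
    return float(np.median(deltas**2))


def single_draw_factor() -> float:
    """The constant 2.19 converting a single-draw median squared change
    to a variance."""
    return SINGLE_DRAW_FACTOR


def single_draw_factor_derived() -> float:
    """Derivation of the single-draw factor: 1 / median(chi-square(1)).

    For x ~ N(0, sigma^2), median(x^2) = sigma^2 * median(chi2_1), so
    sigma^2 = median(x^2) / median(chi2_1) ~= 2.198 * median(x^2).
    """
    return float(1.0 / stats.chi2.ppf(0.5, df=1))


def correction_factor(
    model: Model, series: TrialSeries | None = None, tau: float = 5.0
) -> float:
    """Correction factor ``a`` for post-success exploration.

    Therrien16/Cashaback19 shut exploration off after success, so the
    post-failure minus post-success difference already equals the input
    exploration variance: a = 1. Therrien18 retains a 0.12 fraction
    after success: a = 1.14. Dhawale19's fraction depends on the reward
    history realized in the series; a is computed from the average
    reward history on trials following non-successful and successful
    trials (using the logged history, or an EWMA of the observed reward
    column with the time-scale ``tau`` when latents are unavailable).
    """
    model = Model(model)
    if model in (Model.THERRIEN16, Model.CASHABACK19):
        return 1.0
    if model is Model.THERRIEN18:
        return T18_CORRECTION
    if series is None:
        raise ValueError("dhawale19 correction factor requires a series")
    rbar = series.rbar
    if rbar is None:
        rbar = reward_history_series(series.reward, tau=tau)
    return _dhawale_correction(np.asarray(series.reward), np.asarray(rbar))


def _dhawale_correction(reward: np.ndarray, rbar: np.ndarray) -> float:
    """a = 1 / (mean-(rbar^1.4) - mean+(rbar^1.4)
               - 2 mean-(rbar^0.7) + 2 mean+(rbar^0.7)),
    averaging rbar(t) over trials whose exploration followed a
    non-successful (-) or successful (+) trial."""
    post_fail = reward[:-1] == 0  # selects trials t = 2..n with R(t-1) = 0
    post_succ = ~post_fail
    if not post_fail.any() or not post_succ.any():
        return math.nan
    rb = rbar[1:]
    m14_minus = float(np.mean(rb[post_fail] ** 1.4))
    m14_plus = float(np.mean(rb[post_succ] ** 1.4))
    m07_minus = float(np.mean(rb[post_fail] ** 0.7))
    m07_plus = float(np.mean(rb[post_succ] ** 0.7))
    denom = m14_minus - m14_plus - 2.0 * m07_minus + 2.0 * m07_plus
    if denom == 0.0 or not math.isfinite(denom):
        return math.nan
    return 1.0 / denom


@dataclass
class ExplorationEstimate:
    """Output of a trial-to-trial-change exploration estimator."""

    sigma2_eta_hat: float
    method: str
    correction_a: float
    counts: dict[str, int] = field(default_factory=dict)
    medians: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return math.isfinite(self.sigma2_eta_hat)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "sigma2_eta_hat": self.sigma2_eta_hat,
            "correction_a": self.correction_a,
            "counts": dict(self.counts),
            "medians": dict(self.medians),
            "weights": dict(self.weights),
            "warnings": list(self.warnings),
        }


def ttc_estimate(
    series: TrialSeries,
    model: Model | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
    tau: float = 5.0,
) -> ExplorationEstimate:
    """TTC exploration-variance estimate.

    sigma2_eta_hat = (pi/4) * a * (median_sq(post-failure Delta)
                                   - median_sq(post-success Delta))
    with lag-1 changes. Negative estimates are returned as-is. If either
    reward category is empty the estimate is undefined (NaN) and the
    diagnostic counts say why.
    """
    if model is None:
        model = series.model
    warnings: list[str] = []
    changes = trial_to_trial_changes(series.ep, lag=1)
    labels = classify_ttc(series.reward)
    d_minus = changes.deltas[labels == "-"]
    d_plus = changes.deltas[labels == "+"]
    counts = {"-": int(d_minus.size), "+": int(d_plus.size)}
    medians = {"-": median_sq(d_minus), "+": median_sq(d_plus)}
    a = correction_factor(model, series, tau=tau) if model is not None else 1.0
    if model is None:
        warnings.append("no model given; correction factor a = 1 assumed")
    if d_minus.size == 0 or d_plus.size == 0:
        warnings.append(
            f"undefined estimate: empty category (counts {counts})"
        )
        value = math.nan
    elif not math.isfinite(a):
        warnings.append("undefined estimate: correction factor undefined")
        value = math.nan
    else:
        value = math.pi / 4.0 * a * (medians["-"] - medians["+"])
        if min(counts.values()) < min_count:
            warnings.append(
                f"low reliability: fewer than {min_count} changes in a class"
            )
    return ExplorationEstimate(
        sigma2_eta_hat=value,
        method="ttc",
        correction_a=a,
        counts=counts,
        medians=medians,
        warnings=warnings,
    )


def attc_estimate(
    series: TrialSeries,
    model: Model | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
    tau: float = 5.0,
) -> ExplorationEstimate:
    """ATTC exploration-variance estimate.

    Per retained class pair (C: single failure on the reference trial's
    predecessor; D: double success context):

        estimate_X = 2.19 * (median_sq(X-) - median_sq(X+))

    combined as a weighted mean with weights w_Neta (3 for C, 1 for D,
    the number of exploration draws per change) times w_Ntrials
    (min of the pair's class counts), then scaled by the same correction
    factor ``a`` as the TTC method. No pi/4 factor is needed. If only
    one of C/D is computable its estimate is returned alone (flagged);
    if neither is, the estimate is undefined.
    """
    if model is None:
        model = series.model
    warnings: list[str] = []
    changes = trial_to_trial_changes(series.ep, lag=2)
    labels = classify_attc(series.reward)
    counts: dict[str, int] = {}
    medians: dict[str, float] = {}
    for lab in ("A-", "A+", "B-", "B+", "C-", "C+", "D-", "D+"):
        d = changes.deltas[labels == lab]
        counts[lab] = int(d.size)
        medians[lab] = median_sq(d)
    a = correction_factor(model, series, tau=tau) if model is not None else 1.0
    if model is None:
        warnings.append("no model given; correction factor a = 1 assumed")

    num = 0.0
    den = 0.0
    weights: dict[str, float] = {}
    usable = []
    for cls, w_eta in ATTC_ETA_WEIGHTS.items():
        n_minus, n_plus = counts[f"{cls}-"], counts[f"{cls}+"]
        w_trials = float(min(n_minus, n_plus))
        weights[f"w_Neta,{cls}"] = w_eta
        weights[f"w_Ntrials,{cls}"] = w_trials
        if n_minus == 0 or n_plus == 0:
            continue
        est = SINGLE_DRAW_FACTOR * (medians[f"{cls}-"] - medians[f"{cls}+"])
        num += w_eta * w_trials * est
        den += w_eta * w_trials
        usable.append(cls)
        if min(n_minus, n_plus) < min_count:
            warnings.append(
                f"low reliability: fewer than {min_count} changes in "
                f"class {cls}"
            )
    if not usable or den == 0.0:
        warnings.append(
            "undefined estimate: no computable class pair "
            f"(counts {counts})"
        )
        value = math.nan
    elif not math.isfinite(a):
        warnings.append("undefined estimate: correction factor undefined")
        value = math.nan
    else:
        if len(usable) == 1:
            warnings.append(
                f"single class pair {usable[0]} available; estimate based "
                "on it alone"
            )
        value = a * num / den
    return ExplorationEstimate(
        sigma2_eta_hat=value,
        method="attc",
        correction_a=a,
        counts=counts,
        medians=medians,
        weights=weights,
        warnings=warnings,
    )


def similarity_ratio(
    estimate: ExplorationEstimate | float, sigma2_eta_star: float
) -> float:
    """Estimated over input exploration variance; 1 = perfect recovery."""
    if sigma2_eta_star <= 0:
        raise ValueError(
            f"sigma2_eta_star must be > 0, got {sigma2_eta_star}"
        )
    value = (
        estimate.sigma2_eta_hat
        if isinstance(estimate, ExplorationEstimate)
        else float(estimate)
    )
    return value / sigma2_eta_star
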