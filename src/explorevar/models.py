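"""Reward-based motor-learning simulators.

Each trial a scalar movement endpoint EP is constructed from a latent
aim point AP plus two independent Gaussian perturbations — motor noise
m and exploration eta — after which a binary reward R is issued by the
task's criterion and the learner updates its aim point:

    EP(t) = AP(t) + eta(t) + m(t)                 (always-explore models)
    EP(t) = AP(t) + (1 - R(t-1)) eta(t) + m(t)    (explore-after-failure)

The four models differ in how the aim point is updated and in how the
exploration variance is regulated by reward history; see
:class:`~explorevar.params.Model`. All models share the variance
additivity assumption var(EP - AP) = sigma2_eta + sigma2_m.

Simulations in a set share raw standard-normal draws across models
(common random numbers): the draws depend only on (seed, simulation
index), and each model scales them with its own sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median
from typing import Sequence

import numpy as np

from .params import (
    Criterion,
    LearnerParams,
    Model,
    TaskParams,
    beta_from_tau,
)

#: Scale constant of the variability control function fitted to rat
#: exploratory variances and rescaled to human post-failure variances.
VC_SCALE = 2.18
#: Exponent of the reward-history term of the variability control function.
VC_EXPONENT = 0.7
#: Post-success exploration variance of the Therrien18 model as a
#: fraction of the input exploration variance (the variability control
#: function evaluated at the post-success reference reward history).
T18_POST_SUCCESS_FRACTION = 0.12
#: Reference low-pass-filtered reward histories following a
#: non-successful / successful trial (calibration constants).
RBAR_POST_FAILURE = 0.20
RBAR_POST_SUCCESS = 0.68

_CRITERION_STREAM = 104729  # salt for the reward-criterion RNG substream


def variability_control(sigma2_eta_star: float, rbar: float) -> float:
    """Exploration variance as a function of reward history.

    sigma2_eta = 2.18 * sigma2_eta_star * (rbar**0.7 - 1)**2: a learner
    with a poor recent success rate explores more; a perfect reward
    history (rbar = 1) shuts exploration off.
    """
    if not 0.0 <= rbar <= 1.0:
        raise ValueError(f"rbar must be in [0, 1], got {rbar}")
    if sigma2_eta_star < 0:
        raise ValueError(
            f"sigma2_eta_star must be >= 0, got {sigma2_eta_star}"
        )
    return VC_SCALE * sigma2_eta_star * (rbar**VC_EXPONENT - 1.0) ** 2


def update_reward_history(rbar_prev: float, r_prev: int, beta: float) -> float:
    """One step of the exponentially weighted reward-history filter.

    rbar(t) = rbar(t-1) + beta * (R(t-1) - rbar(t-1)); the increment is
    beta times the reward prediction error of the previous trial.
    """
    if not 0.0 <= rbar_prev <= 1.0:
        raise ValueError(f"rbar_prev must be in [0, 1], got {rbar_prev}")
    if r_prev not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {r_prev}")
    return rbar_prev + beta * (r_prev - rbar_prev)


def evaluate_reward(
    task: TaskParams,
    ep_t: float,
    ep_history: Sequence[float],
    rng: np.random.Generator,
) -> int:
    """Binary reward for endpoint ``ep_t`` under the task's criterion.

    ``ep_history`` holds past endpoints, most recent last; only the last
    ``history_window`` entries are consulted by the adaptive criteria.
    ``task`` must be resolved (``task.target`` set in movement units).

    The fixed criterion rewards endpoints inside the zone
    [target - zone_halfwidth, target + zone_halfwidth] (bounds
    inclusive). The adaptive criteria additionally reward endpoints that
    are at least as close to the target as the mean (or median) of the
    recent endpoints. The random criterion rewards each trial with
    probability ``random_p`` independent of performance. On trials with
    no history the adaptive criteria fall back to the fixed-zone rule.
    """
    if task.target is None:
        raise ValueError("task target is unresolved; call TaskParams.resolve")
    crit = task.criterion
    if crit is Criterion.RANDOM:
        return int(rng.random() < task.random_p)

    target = task.target
    zone = task.zone_halfwidth
    in_zone = target - zone <= ep_t <= target + zone
    if crit in (Criterion.FIXED, Criterion.FIXED_LOW_TARGET) or not ep_history:
        return int(in_zone)

    window = ep_history[-task.history_window:]
    if crit is Criterion.ADAPTIVE_MEAN:
        stat = sum(window) / len(window)
    else:
        stat = median(window)
    if ep_t < target:
        return int(in_zone or stat <= ep_t)
    if ep_t > target:
        return int(in_zone or ep_t <= stat)
    return 1  # ep_t exactly on target


def construct_endpoint(
    model: Model, ap: float, eta: float, m: float, r_prev: int
) -> float:
    """Endpoint from aim point, exploration and motor noise.

    The explore-after-failure models (Therrien16, Cashaback19) gate
    exploration off after a rewarded trial.
    """
    model = Model(model)
    if model in (Model.THERRIEN18, Model.DHAWALE19):
        return ap + eta + m
    return ap + (1 - r_prev) * eta + m


def update_aim_point(
    model: Model,
    ap_prev: float,
    *,
    eta_prev: float = 0.0,
    ep_prev: float = 0.0,
    r_prev: int = 0,
    rpe_prev: float = 0.0,
    alpha: float = 1.0,
) -> float:
    """Aim point for the next trial from the previous trial's outcome.

    Therrien16/18 update with the full rewarded exploration; Cashaback19
    with a fraction alpha of the rewarded endpoint deviation; Dhawale19
    with alpha times the reward prediction error times the exploration
    (an update after success, a correction after failure).
    """
    model = Model(model)
    if model in (Model.THERRIEN16, Model.THERRIEN18):
        return ap_prev + r_prev * eta_prev
    if model is Model.CASHABACK19:
        return ap_prev + alpha * r_prev * (ep_prev - ap_prev)
    return ap_prev + alpha * rpe_prev * eta_prev


@dataclass(frozen=True)
class NoiseDraws:
    """Raw standard-normal draws for one simulation.

    The same (seed, sim_index) always reproduces the same vectors,
    whichever model consumes them — the common-random-numbers contract.
    """

    eta_raw: np.ndarray
    m_raw: np.ndarray
    seed: int
    sim_index: int = 0

    def __post_init__(self) -> None:
        if len(self.eta_raw) != len(self.m_raw):
            raise ValueError("eta_raw and m_raw must have equal length")

    @property
    def n_trials(self) -> int:
        return len(self.eta_raw)

    def criterion_rng(self) -> np.random.Generator:
        """Independent substream for the random reward criterion."""
        return np.random.default_rng(
            [self.seed, self.sim_index, _CRITERION_STREAM]
        )


def draw_noise_vectors(
    n_trials: int, n_sims: int, seed: int
) -> list[NoiseDraws]:
    """Standard-normal exploration and motor-noise draws per simulation.

    Two N(0, 1) vectors of length ``n_trials`` per simulation; on each
    trial the t-th element is later multiplied by the model's sigma_eta
    or sigma_m. Deterministic in (seed, simulation index).
    """
    if n_trials < 1 or n_sims < 1:
        raise ValueError("n_trials and n_sims must be >= 1")
    out = []
    for i in range(n_sims):
        rng = np.random.default_rng([seed, i])
        out.append(
            NoiseDraws(
                eta_raw=rng.standard_normal(n_trials),
                m_raw=rng.standard_normal(n_trials),
                seed=seed,
                sim_index=i,
            )
        )
    return out


@dataclass
class TrialSeries:
    """Per-trial record of one simulation (or one observed session).

    All sequences are aligned, index 0 = trial 1. ``eta`` holds the
    realized exploration (zero on gated trials of the
    explore-after-failure models). Latent columns are ``None`` for
    series read from a minimal CSV log.
    """

    ep: np.ndarray
    reward: np.ndarray
    ap: np.ndarray | None = None
    eta: np.ndarray | None = None
    m: np.ndarray | None = None
    rbar: np.ndarray | None = None
    sigma2_eta: np.ndarray | None = None
    model: Model | None = None
    learner: LearnerParams | None = None
    task: TaskParams | None = None
    seed: int | None = None
    sim_index: int | None = None

    def __post_init__(self) -> None:
        n = len(self.ep)
        for name in ("reward", "ap", "eta", "m", "rbar", "sigma2_eta"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"length of {name} does not match ep")
        r = np.asarray(self.reward)
        if not np.isin(r, (0, 1)).all():
            raise ValueError("reward values must be 0 or 1")

    @property
    def n_trials(self) -> int:
        return len(self.ep)

    @property
    def has_latents(self) -> bool:
        return self.eta is not None and self.m is not None


def simulate_trials(
    model: Model,
    learner: LearnerParams,
    task: TaskParams,
    draws: NoiseDraws,
) -> TrialSeries:
    """Simulate one session of reward-based motor learning.

    All state (aim point, endpoint, reward, reward history, reward
    prediction error, exploration, motor noise) is initialized to zero
    before trial 1. Per trial: regulate the exploration SD from the
    previous outcome / reward history, scale the raw draws, update the
    aim point, construct the endpoint, evaluate reward, and advance the
    reward-history filter. Every latent variable is logged.
    """
    model = Model(model)
    n = draws.n_trials
    if n < 1:
        raise ValueError("need at least one trial")
    task = task.resolve(learner)
    target = task.target
    zone = task.zone_halfwidth
    crit = task.criterion
    hist_w = task.history_window
    alpha = learner.alpha
    beta = learner.beta
    sigma_m = learner.sigma_m
    sigma_eta_star = learner.sigma_eta_star
    s2_star = learner.sigma2_eta_star
    t18_sigma_plus = math.sqrt(T18_POST_SUCCESS_FRACTION) * sigma_eta_star

    eta_raw = draws.eta_raw.tolist()
    m_raw = draws.m_raw.tolist()
    if crit is Criterion.RANDOM:
        random_u = draws.criterion_rng().random(n).tolist()
        random_p = task.random_p
    adaptive = crit in (Criterion.ADAPTIVE_MEAN, Criterion.ADAPTIVE_MEDIAN)
    use_mean = crit is Criterion.ADAPTIVE_MEAN

    ap_l: list[float] = []
    ep_l: list[float] = []
    r_l: list[int] = []
    eta_l: list[float] = []
    m_l: list[float] = []
    rbar_l: list[float] = []
    s2_l: list[float] = []

    ap = 0.0
    ep_prev = 0.0
    eta_prev = 0.0
    r_prev = 0
    rbar = 0.0
    rpe_prev = 0.0
    history: list[float] = []

    for t in range(n):
        if t > 0:
            # reward history through the previous trial's outcome
            rbar += beta * (r_prev - rbar)
            # aim-point update from the previous trial
            if model is Model.THERRIEN16 or model is Model.THERRIEN18:
                if alpha != 0.0 and r_prev:
                    ap += eta_prev
            elif model is Model.CASHABACK19:
                if r_prev:
                    ap += alpha * (ep_prev - ap)
            else:
                ap += alpha * rpe_prev * eta_prev

        # exploration SD regulated by reward (history)
        if model is Model.THERRIEN16 or model is Model.CASHABACK19:
            sig_eta = 0.0 if r_prev else sigma_eta_star
            s2_t = sig_eta * sig_eta
        elif model is Model.THERRIEN18:
            sig_eta = t18_sigma_plus if r_prev else sigma_eta_star
            s2_t = sig_eta * sig_eta
        else:
            s2_t = VC_SCALE * s2_star * (rbar**VC_EXPONENT - 1.0) ** 2
            sig_eta = math.sqrt(s2_t)

        eta = eta_raw[t] * sig_eta
        m = m_raw[t] * sigma_m
        ep = ap + eta + m

        # reward criterion
        if crit is Criterion.RANDOM:
            r = 1 if random_u[t] < random_p else 0
        else:
            in_zone = target - zone <= ep <= target + zone
            if adaptive and history:
                window = history[-hist_w:]
                if use_mean:
                    stat = sum(window) / len(window)
                else:
                    stat = median(window)
                if ep < target:
                    r = 1 if (in_zone or stat <= ep) else 0
                elif ep > target:
                    r = 1 if (in_zone or ep <= stat) else 0
                else:
                    r = 1
            else:
                r = 1 if in_zone else 0

        ap_l.append(ap)
        ep_l.append(ep)
        r_l.append(r)
        eta_l.append(eta)
        m_l.append(m)
        rbar_l.append(rbar)
        s2_l.append(s2_t)

        rpe_prev = r - rbar
        eta_prev = eta
        ep_prev = ep
        r_prev = r
        history.append(ep)

    return TrialSeries(
        ep=np.array(ep_l),
        reward=np.array(r_l, dtype=np.int8),
        ap=np.array(ap_l),
        eta=np.array(eta_l),
        m=np.array(m_l),
        rbar=np.array(rbar_l),
        sigma2_eta=np.array(s2_l),
        model=model,
        learner=learner,
        task=task,
        seed=draws.seed,
        sim_index=draws.sim_index,
    )


def reward_history_series(
    reward: np.ndarray, beta: float | None = None, tau: float = 5.0
) -> np.ndarray:
    """Low-pass-filtered reward history per trial from a reward column.

    Zero-initialized; rbar(t) reflects rewards through trial t-1. Used
    to reconstruct the Dhawale19 correction factor for observed data
    where the true reward history was not logged.
    """
    if beta is None:
        beta = beta_from_tau(tau)
    r = np.asarray(reward, dtype=float)
    rbar = np.empty(len(r))
    x = 0.0
    for t in range(len(r)):
        rbar[t] = x
        x += beta * (r[t] - x)
    return rbar
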