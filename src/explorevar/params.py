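"""Learner and task parameter containers.

A simulated learner is described by four parameters: the motor-noise
variance ``sigma2_m`` (inevitable variability, never available for
learning), the input exploration variance ``sigma2_eta_star`` (the
purposeful variability an estimator should recover), the learning
fraction ``alpha``, and — for learners that regulate exploration by
reward history — the reward-history time-scale ``tau`` in trials.

A task is described by the target amplitude (expressed in units of the
motor-noise SD) and a reward criterion: how a scalar movement endpoint
is converted into binary success feedback.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from enum import Enum


class Model(str, Enum):
    """The four reward-based motor-learning models.

    - ``therrien16``: explore only after failure, update aim with the full
      rewarded exploration.
    - ``therrien18``: always explore, with reduced variance after success;
      update aim with the full rewarded exploration.
    - ``cashaback19``: explore only after failure; update aim with a
      fraction ``alpha`` of the rewarded endpoint deviation (partial
      knowledge of the actual reach).
    - ``dhawale19``: always explore, with variance set by a low-pass
      filtered reward history; update aim with ``alpha`` times the reward
      prediction error times the exploration.
    """

    THERRIEN16 = "therrien16"
    THERRIEN18 = "therrien18"
    CASHABACK19 = "cashaback19"
    DHAWALE19 = "dhawale19"


#: Models whose aim-point update uses the full exploration (learning
#: fraction fixed at 1; alpha = 0 disables updating entirely).
FIXED_ALPHA_MODELS = frozenset({Model.THERRIEN16, Model.THERRIEN18})


class Criterion(str, Enum):
    """Reward criteria: how an endpoint earns binary success feedback."""

    RANDOM = "random"
    ADAPTIVE_MEDIAN = "adaptive_median"
    ADAPTIVE_MEAN = "adaptive_mean"
    FIXED = "fixed"
    FIXED_LOW_TARGET = "fixed_low_target"


def beta_from_tau(tau: float) -> float:
    """Reward-rate update fraction from the reward-history time-scale.

    beta = 1 - exp(-1/tau). The longer the memory window tau, the less a
    single trial outcome moves the reward-history estimate. tau = 5
    trials gives beta ~= 0.18.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    return 1.0 - math.exp(-1.0 / tau)


@dataclass(frozen=True)
class LearnerParams:
    """Who the simulated learner is.

    Parameters
    ----------
    sigma2_m
        Motor-noise variance (movement units squared).
    sigma2_eta_star
        Input exploration variance (movement units squared); the ground
        truth a trial-to-trial-change estimator should recover.
    alpha
        Learning fraction in [0, 1]. Ignored (fixed at 1) by the
        Therrien models except alpha = 0, which disables updating.
    tau
        Reward-history time-scale in trials (> 0); only consumed by the
        Dhawale19 model.
    """

    sigma2_m: float = 9.0
    sigma2_eta_star: float = 16.0
    alpha: float = 0.15
    tau: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma2_m < 0:
            raise ValueError(f"sigma2_m must be >= 0, got {self.sigma2_m}")
        if self.sigma2_eta_star < 0:
            raise ValueError(
                f"sigma2_eta_star must be >= 0, got {self.sigma2_eta_star}"
            )
        if not 0 <= self.alpha <= 1:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")

    @property
    def beta(self) -> float:
        """Derived reward-rate update fraction, 1 - exp(-1/tau)."""
        return beta_from_tau(self.tau)

    @property
    def sigma_m(self) -> float:
        return math.sqrt(self.sigma2_m)

    @property
    def sigma_eta_star(self) -> float:
        return math.sqrt(self.sigma2_eta_star)


@dataclass(frozen=True)
class TaskParams:
    """What task is performed.

    The target amplitude is expressed as a multiple of the learner's
    motor-noise SD (``target_sigma_units``); call :meth:`resolve` with a
    learner to fix it in raw movement units. The ``fixed_low_target``
    criterion overrides the multiplier with 2.
    """

    target_sigma_units: float = 4.0
    criterion: Criterion = Criterion.ADAPTIVE_MEAN
    zone_halfwidth: float = 1.0
    history_window: int = 10
    random_p: float = 0.5
    target: float | None = None  # resolved amplitude in movement units

    def __post_init__(self) -> None:
        object.__setattr__(self, "criterion", Criterion(self.criterion))
        if self.zone_halfwidth <= 0:
            raise ValueError(
                f"zone_halfwidth must be > 0, got {self.zone_halfwidth}"
            )
        if self.history_window < 1:
            raise ValueError(
                f"history_window must be >= 1, got {self.history_window}"
            )
        if not 0 <= self.random_p <= 1:
            raise ValueError(f"random_p must be in [0, 1], got {self.random_p}")

    @property
    def effective_sigma_units(self) -> float:
        """Target multiplier after the low-target override."""
        if self.criterion is Criterion.FIXED_LOW_TARGET:
            return 2.0
        return self.target_sigma_units

    def resolve(self, learner: LearnerParams) -> "TaskParams":
        """Return a copy with ``target`` fixed in movement units."""
        return dataclasses.replace(
            self, target=self.effective_sigma_units * learner.sigma_m
        )
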