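"""Scripted-reward fixtures for estimator verification.

A fixture is a trial series whose rewards follow an explicit script
(bypassing any reward criterion) while aim point and endpoint follow a
learner's update equations with known noise draws. With motor noise
zero, the realized lag-2 change in each three-trial reward-sequence
class equals a closed-form expression in the exploration draws, so the
sequence algebra behind the ATTC estimator can be checked exactly.

Besides the four named models, ``model="gated"`` gives the generic
explore-after-failure learner with a free learning fraction alpha
(exploration gated by the previous reward, aim updated with
alpha * R(t-1) * eta(t-1)) that the sequence-class expressions are
written for; the Therrien16 model is its alpha = 1 case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import (
    T18_POST_SUCCESS_FRACTION,
    VC_EXPONENT,
    VC_SCALE,
    Model,
    TrialSeries,
)
from .params import LearnerParams

_GATED = "gated"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a scripted trial series.

    ``rewards`` is the explicit 0/1 outcome sequence. ``eta_raw`` and
    ``m_raw`` are explicit standard-normal-scale draws; if omitted they
    are drawn from N(0, 1) with ``seed``. The draws are scaled with the
    learner's sigmas and gating rules exactly as in a simulation.
    """

    rewards: Sequence[int]
    model: Model | str = Model.THERRIEN16
    learner: LearnerParams = field(default_factory=LearnerParams)
    eta_raw: Sequence[float] | None = None
    m_raw: Sequence[float] | None = None
    alpha: float | None = None  # override for the "gated" learner
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r not in (0, 1) for r in self.rewards):
            raise ValueError("scripted rewards must be 0 or 1")
        n = len(self.rewards)
        for name in ("eta_raw", "m_raw"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"{name} length must match rewards length")


def make_fixture(spec: FixtureSpec) -> TrialSeries:
    """Build a trial series with scripted rewards and known draws."""
    model = spec.model if spec.model == _GATED else Model(spec.model)
    learner = spec.learner
    n = len(spec.rewards)
    rng = np.random.default_rng(spec.seed)
    eta_raw = (
        np.asarray(spec.eta_raw, dtype=float)
        if spec.eta_raw is not None
        else rng.standard_normal(n)
    )
    m_raw = (
        np.asarray(spec.m_raw, dtype=float)
        if spec.m_raw is not None
        else rng.standard_normal(n)
    )
    alpha = spec.alpha if spec.alpha is not None else learner.alpha
    beta = learner.beta
    sig_m = learner.sigma_m
    sig_star = learner.sigma_eta_star
    s2_star = learner.sigma2_eta_star

    ap_l, ep_l, eta_l, m_l, rbar_l, s2_l = [], [], [], [], [], []
    ap = 0.0
    ep_prev = 0.0
    eta_prev = 0.0
    r_prev = 0
    rbar = 0.0
    rpe_prev = 0.0
    for t in range(n):
        if t > 0:
            rbar += beta * (r_prev - rbar)
            if model in (Model.THERRIEN16, Model.THERRIEN18):
                if alpha != 0.0 and r_prev:
                    ap += eta_prev
            elif model is Model.CASHABACK19:
                if r_prev:
                    ap += alpha * (ep_prev - ap)
            elif model is Model.DHAWALE19:
                ap += alpha * rpe_prev * eta_prev
            else:  # gated generic learner
                if r_prev:
                    ap += alpha * eta_prev

        if model in (Model.THERRIEN16, Model.CASHABACK19) or model == _GATED:
            sig_eta = 0.0 if r_prev else sig_star
            s2_t = sig_eta * sig_eta
        elif model is Model.THERRIEN18:
            s2_t = (T18_POST_SUCCESS_FRACTION if r_prev else 1.0) * s2_star
            sig_eta = s2_t**0.5
        else:
            s2_t = VC_SCALE * s2_star * (rbar**VC_EXPONENT - 1.0) ** 2
            sig_eta = s2_t**0.5

        eta = eta_raw[t] * sig_eta
        m = m_raw[t] * sig_m
        ep = ap + eta + m
        r = int(spec.rewards[t])

        ap_l.append(ap)
        ep_l.append(ep)
        eta_l.append(eta)
        m_l.append(m)
        rbar_l.append(rbar)
        s2_l.append(s2_t)

        rpe_prev = r - rbar
        eta_prev = eta
        ep_prev = ep
        r_prev = r

    return TrialSeries(
        ep=np.array(ep_l),
        reward=np.array(spec.rewards, dtype=np.int8),
        ap=np.array(ap_l),
        eta=np.array(eta_l),
        m=np.array(m_l),
        rbar=np.array(rbar_l),
        sigma2_eta=np.array(s2_l),
        model=model if isinstance(model, Model) else None,
        learner=learner,
        task=None,
        seed=spec.seed,
    )
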