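"""Product-limit (Kaplan-Meier) and Nelson-Aalen estimators.

These are the nonparametric workhorses reused everywhere else: the censoring
distribution Ghat for inverse-probability-of-censoring weights (Fine-Gray,
Brier score), the Nelson-Aalen limit of the Breslow baseline, and Greenwood
variances for the survival curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset
from .stepfun import StepFunction

__all__ = ["KaplanMeierEstimate", "kaplan_meier", "nelson_aalen", "censoring_km"]


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Shat(t) with its Greenwood variance, plus the at-risk/death tables."""

    survival: StepFunction
    variance: StepFunction  # Greenwood Var[Shat(t)]
    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def __call__(self, t):
        return self.survival(t)

    def left_limit(self, t):
        return self.survival.left_limit(t)


def _risk_table(times: np.ndarray, flags: np.ndarray):
    """Unique times with an occurrence, at-risk counts and occurrence counts."""
    times = np.asarray(times, float)
    flags = np.asarray(flags).astype(bool)
    ut = np.unique(times[flags])
    n_at_risk = np.array([(times >= t).sum() for t in ut])
    n_events = np.array([((times == t) & flags).sum() for t in ut])
    return ut, n_at_risk, n_events


def kaplan_meier(times, event_flags) -> KaplanMeierEstimate:
    """Product-limit estimator Shat(t) = prod_{t_j <= t} (1 - d_j/n_j),
    right-continuous, Shat(0) = 1, with Greenwood variance."""
    times = np.asarray(times, float)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    ut, n_risk, d = _risk_table(times, event_flags)
    if ut.size == 0:  # all censored
        empty = np.array([])
        return KaplanMeierEstimate(
            StepFunction(empty, empty, init=1.0),
            StepFunction(empty, empty, init=0.0),
            empty, empty.astype(int), empty.astype(int),
        )
    surv = np.cumprod(1.0 - d / n_risk)
    # Greenwood: Var = S(t)^2 * sum d/(n(n-d)); terms with n == d give S = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = d / (n_risk * (n_risk - d))
        terms[n_risk == d] = np.inf
        gw = surv**2 * np.cumsum(terms)
    gw[surv == 0.0] = 0.0
    return KaplanMeierEstimate(
        StepFunction(ut, surv, init=1.0),
        StepFunction(ut, gw, init=0.0),
        ut, n_risk, d,
    )


def nelson_aalen(times, event_flags) -> StepFunction:
    """Cumulative-hazard estimator sum_{t_j <= t} d_j / n_j."""
    ut, n_risk, d = _risk_table(times, event_flags)
    if ut.size == 0:
        return StepFunction(np.array([]), np.array([]), init=0.0)
    return StepFunction(ut, np.cumsum(d / n_risk), init=0.0)


def censoring_km(ds_or_times, events=None) -> KaplanMeierEstimate:
    """Kaplan-Meier of the censoring distribution Ghat(t): the event roles
    are flipped, so 'events' here are the censorings (code 0)."""
    if isinstance(ds_or_times, SurvivalDataset):
        times, events = ds_or_times.times, ds_or_times.events
    else:
        times = ds_or_times
    censored = np.asarray(events) == 0
    return kaplan_meier(times, censored)
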