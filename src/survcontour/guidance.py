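"""Model-selection guidance and fit metrics.

The recommendation logic mirrors the guided workflow a survival analyst
follows: competing risks and interval censoring gate the choice first, then
the preferred model family, then stratification.  The metrics are Harrell's
concordance index and the IPCW integrated Brier score, the two standard
checks of predictive fit for survival models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset
from .errors import UndefinedMetricError, UnsupportedCombinationError
from .km import censoring_km

__all__ = [
    "StudyAnswers",
    "Recommendation",
    "recommend_model",
    "concordance_index",
    "brier_scores",
    "integrated_brier",
]

logger = logging.getLogger("survcontour")


@dataclass(frozen=True)
class StudyAnswers:
    competing_risks: bool = False
    interval_censored: bool = False
    family_preference: str = "unsure"  # parametric|nonparametric|semiparametric|unsure
    needs_strata: bool = False

    def __post_init__(self):
        if self.family_preference not in (
            "parametric", "nonparametric", "semiparametric", "unsure",
        ):
            raise ValueError(f"unknown family preference {self.family_preference!r}")


@dataclass(frozen=True)
class Recommendation:
    model: str
    rationale: str
    requires_backend: bool = False


def recommend_model(answers: StudyAnswers) -> Recommendation:
    """Walk the decision tree: competing risks -> Fine-Gray; interval
    censoring -> parametric Weibull; otherwise the preferred family, with
    stratification refining the Cox choice."""
    if answers.competing_risks and answers.interval_censored:
        raise UnsupportedCombinationError(
            "no offered model handles competing risks together with "
            "interval censoring; analyse one aspect at a time"
        )
    if answers.competing_risks:
        return Recommendation(
            "fine_gray",
            "competing events preclude the event of interest; the "
            "subdistribution-hazard model acts directly on cumulative incidence",
        )
    if answers.interval_censored:
        return Recommendation(
            "weibull_interval",
            "event times known only within visit windows: the parametric "
            "Weibull likelihood integrates over each interval",
        )
    fam = answers.family_preference
    if fam == "parametric":
        return Recommendation(
            "weibull",
            "a parametric fit extrapolates smoothly, an advantage when "
            "out-of-sample prediction is the priority",
        )
    if fam == "nonparametric":
        return Recommendation(
            "spline_backend",
            "flexible spline-based hazards are served through the backend "
            "adapter; no native spline model is provided",
            requires_backend=True,
        )
    # semiparametric or unsure -> Cox
    if answers.needs_strata:
        return Recommendation(
            "stratified_cox",
            "stratification lets the baseline hazard differ across levels "
            "of a covariate while sharing the coefficients",
        )
    return Recommendation(
        "cox",
        "the Cox model avoids assumptions on the baseline hazard and is the "
        "mainstay of applied survival analysis",
    )


# ---------------------------------------------------------------------------
# metrics


def concordance_index(times, event_flags, risk_scores) -> float:
    """Harrell's C: among comparable pairs (earlier observed event vs. a
    subject observed longer), the fraction where the higher risk score
    belongs to the earlier event; score ties count 1/2."""
    t = np.asarray(times, float)
    e = np.asarray(event_flags).astype(bool)
    s = np.asarray(risk_scores, float)
    if t.size < 2:
        raise ValueError("need at least 2 subjects")
    # pair (i, j) comparable iff t_i < t_j and subject i had the event
    comparable = (t[:, None] < t[None, :]) & e[:, None]
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise UndefinedMetricError(
            "no comparable pairs under censoring; the C-index is undefined"
        )
    conc = (s[:, None] > s[None, :]) & comparable
    tied = (s[:, None] == s[None, :]) & comparable
    return float((conc.sum() + 0.5 * tied.sum()) / n_pairs)


def brier_scores(pred_times, pred_matrix, ds: SurvivalDataset) -> np.ndarray:
    """IPCW Brier score BS(t) at each prediction time.

    ``pred_matrix[i, j]`` is the model's S(t_j | x_i).  Weights: subjects
    with an observed event before t contribute (0 - S)^2 / Ghat(T_i-);
    subjects still at risk at t contribute (1 - S)^2 / Ghat(t); censored-
    before-t subjects drop out.
    """
    t_grid = np.asarray(pred_times, float)
    S = np.asarray(pred_matrix, float)
    if S.shape != (ds.n, t_grid.size):
        raise ValueError(f"prediction matrix must be (n={ds.n}, n_times={t_grid.size})")
    T = ds.times
    delta = ds.events >= 1
    G = censoring_km(T, ds.events)
    G_Ti = np.asarray(G.left_limit(T), float)
    G_t = np.asarray(G(t_grid), float)

    died = (T[:, None] <= t_grid[None, :]) & delta[:, None]
    alive = T[:, None] > t_grid[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        w_died = np.where(died, 1.0 / G_Ti[:, None], 0.0)
        w_alive = np.where(alive, 1.0 / G_t[None, :], 0.0)
    w_died = np.where(np.isfinite(w_died), w_died, 0.0)
    w_alive = np.where(np.isfinite(w_alive), w_alive, 0.0)
    bs = (w_died * S**2 + w_alive * (1.0 - S) ** 2).sum(axis=0) / ds.n
    return bs


def integrated_brier(pred_times, pred_matrix, ds: SurvivalDataset, window=None) -> float:
    """Trapezoidal time-average of BS(t) over ``window`` (default: the span
    of the prediction grid).  If Ghat hits 0 inside the window the window is
    truncated with a warning (weights would blow up past that point)."""
    t_grid = np.asarray(pred_times, float)
    window = (float(t_grid[0]), float(t_grid[-1])) if window is None else window
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty integration window")
    G = censoring_km(ds.times, ds.events)
    grid_in = t_grid[(t_grid >= t0) & (t_grid <= t1)]
    g_vals = np.asarray(G(grid_in), float)
    if np.any(g_vals <= 0):
        t1_new = float(grid_in[np.argmax(g_vals <= 0)])
        warnings.warn(
            f"censoring survival reaches 0 at t = {t1_new:g}; "
            f"integration window truncated from {t1:g}",
            stacklevel=2,
        )
        t1 = t1_new
    mask = (t_grid >= t0) & (t_grid <= t1)
    if mask.sum() < 2:
        raise ValueError("window too narrow for the prediction grid")
    bs = brier_scores(t_grid, pred_matrix, ds)[mask]
    tt = t_grid[mask]
    return float(np.trapezoid(bs, tt) / (tt[-1] - tt[0]))
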