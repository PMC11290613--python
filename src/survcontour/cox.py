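"""Cox proportional hazards: Newton-Raphson partial likelihood (Efron or
Breslow ties), Breslow baseline cumulative hazard, conditional survival
prediction with the standard asymptotic variance.

The model: h(t | x) = h0(t) exp(x'beta).  The partial likelihood is
maximized on the centered design; the stored baseline refers to x = 0
(uncentered), so Lambda(t|x) = Lambda0(t) exp(x'beta) directly.

The baseline uses the Breslow step estimator
    Lambda0(t) = sum_{t_j <= t} d_j / sum_{i in R(t_j)} exp(x_i' beta)
for either ties method (the convention of mainstream Cox software); with
beta = 0 it reduces exactly to the Nelson-Aalen estimator.

The variance of the predicted cumulative hazard combines the Breslow
increment term with the delta-method term in beta:
    Var[Lambda(t|x)] = e^{2 x'b} [ sum d_j / S0_j^2  +  Q(t)' V Q(t) ],
    Q(t) = sum (d_j / S0_j) (x - xbar_j),
where xbar_j is the risk-set weighted covariate mean at t_j and V the
inverse observed information.  Bands are formed on the log(-log S) scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import SurvivalDataset
from .design import DesignMatrix, build_design
from .errors import ConvergenceError, DegenerateDesignError
from .stepfun import StepFunction

__all__ = [
    "CoxFit",
    "fit_cox",
    "fit_stratified_cox",
    "breslow_baseline",
    "predict_survival_cox",
    "PredictionResult",
]

logger = logging.getLogger("survcontour")

#: relative log-partial-likelihood convergence tolerance
NR_TOL = 1e-9
NR_MAX_ITER = 50
#: coefficients beyond this magnitude with a non-vanishing score signal
#: monotone-likelihood divergence
DIVERGENCE_BETA = 10.0


# ---------------------------------------------------------------------------
# partial-likelihood engine


class _StratumData:
    """Per-stratum precomputation for the grouped partial likelihood."""

    def __init__(self, times, events, Xc):
        order = np.argsort(times, kind="stable")
        self.ts = times[order]
        self.ev = events[order].astype(bool)
        self.X = Xc[order]
        self.d_idx = np.flatnonzero(self.ev)
        dt = self.ts[self.d_idx]
        self.ut = np.unique(dt)
        self.first = np.searchsorted(self.ts, self.ut, side="left")
        # group boundaries of tied deaths (d_idx already time-sorted)
        self.starts = np.searchsorted(dt, self.ut, side="left")
        self.d = np.diff(np.append(self.starts, dt.size))
        self.J = np.repeat(np.arange(self.ut.size), self.d)
        # Efron fractions l/d_j for l = 0..d_j-1
        self.frac = np.concatenate([np.arange(dj) / dj for dj in self.d]) if dt.size else np.array([])
        self.sum_x_deaths = self.X[self.d_idx].sum(axis=0) if dt.size else np.zeros(Xc.shape[1])

    @property
    def n_events(self) -> int:
        return self.d_idx.size


def _revcum(a):
    return np.cumsum(a[::-1], axis=0)[::-1]


class _CoxEngine:
    """Sum of per-stratum log partial likelihood, score and information."""

    def __init__(self, times, events, Xc, ties="efron", strata=None):
        self.p = Xc.shape[1]
        self.ties = ties
        if strata is None:
            groups = [np.arange(times.shape[0])]
            self.labels = [None]
        else:
            self.labels = sorted(np.unique(strata).tolist())
            groups = [np.flatnonzero(strata == lab) for lab in self.labels]
        self.strata = []
        for lab, idx in zip(self.labels, groups):
            sd = _StratumData(times[idx], events[idx], Xc[idx])
            if sd.n_events == 0:
                logger.warning("stratum %r has zero events; it contributes no terms", lab)
            self.strata.append(sd)

    def loglik_grad_info(self, beta):
        p = self.p
        ll, g, H = 0.0, np.zeros(p), np.zeros((p, p))
        for sd in self.strata:
            if sd.n_events == 0:
                continue
            eta = sd.X @ beta
            r = np.exp(eta)
            rX = r[:, None] * sd.X
            rXX = rX[:, :, None] * sd.X[:, None, :]
            S0 = _revcum(r)[sd.first]
            S1 = _revcum(rX)[sd.first]
            S2 = _revcum(rXX)[sd.first]
            rd = np.add.reduceat(r[sd.d_idx], sd.starts)
            s1d = np.add.reduceat(rX[sd.d_idx], sd.starts)
            s2d = np.add.reduceat(rXX[sd.d_idx], sd.starts)
            f = sd.frac if self.ties == "efron" else np.zeros_like(sd.frac)
            J = sd.J
            phi = S0[J] - f * rd[J]
            Znum = S1[J] - f[:, None] * s1d[J]
            Z = Znum / phi[:, None]
            ll += float(eta[sd.d_idx].sum() - np.log(phi).sum())
            g += sd.sum_x_deaths - Z.sum(axis=0)
            S2t = (S2[J] - f[:, None, None] * s2d[J]) / phi[:, None, None]
            H += S2t.sum(axis=0) - np.einsum("ep,eq->pq", Z, Z)
        return ll, g, H

    def baseline_ingredients(self, beta, center):
        """Per-stratum Breslow baseline pieces at the fitted beta, converted
        to the uncentered (x = 0) convention."""
        out = {}
        shift = float(np.exp(center @ beta))  # S0_unc = S0_c * exp(c'b)
        for lab, sd in zip(self.labels, self.strata):
            if sd.n_events == 0:
                out[lab] = _BaselineIngredients.empty(self.p)
                continue
            r = np.exp(sd.X @ beta)
            S0c = _revcum(r)[sd.first]
            S1c = _revcum(r[:, None] * sd.X)[sd.first]
            S0 = S0c * shift
            xbar = S1c / S0c[:, None] + center  # uncentered risk-set mean
            inc = sd.d / S0
            out[lab] = _BaselineIngredients(
                times=sd.ut,
                increments=inc,
                cum_a=np.cumsum(sd.d / S0**2),
                cum_b=np.cumsum(inc),
                cum_c=np.cumsum(inc[:, None] * xbar, axis=0),
            )
        return out


@dataclass
class _BaselineIngredients:
    """Breslow baseline and the prefix sums its variance needs."""

    times: np.ndarray          # distinct event times
    increments: np.ndarray     # d_j / S0_j (uncentered)
    cum_a: np.ndarray          # cumsum d_j / S0_j^2
    cum_b: np.ndarray          # cumsum d_j / S0_j = Lambda0
    cum_c: np.ndarray          # cumsum (d_j/S0_j) * xbar_j, shape (G, p)

    @classmethod
    def empty(cls, p):
        z = np.array([])
        return cls(z, z, z, z, np.zeros((0, p)))

    @property
    def cumhaz(self) -> StepFunction:
        return StepFunction(self.times, self.cum_b, init=0.0)

    def to_dict(self):
        return {
            "times": self.times.tolist(),
            "increments": self.increments.tolist(),
            "cum_a": self.cum_a.tolist(),
            "cum_b": self.cum_b.tolist(),
            "cum_c": self.cum_c.tolist(),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(*(np.asarray(d[k], float) for k in ("times", "increments", "cum_a", "cum_b")),
                   np.asarray(d["cum_c"], float))


def _newton(engine, p, context="partial likelihood"):
    """Maximize via Newton-Raphson with step-halving; detect monotone
    likelihood (runaway coefficients with a non-vanishing score)."""
    beta = np.zeros(p)
    ll, g, H = engine.loglik_grad_info(beta)
    if not np.all(np.isfinite(H)) or np.any(np.diag(H) <= 1e-12):
        raise DegenerateDesignError(
            f"{context}: information matrix is singular at beta = 0 "
            "(no within-risk-set covariate variation)"
        )
    converged = False
    n_iter = 0
    for n_iter in range(1, NR_MAX_ITER + 1):
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise DegenerateDesignError(f"{context}: singular information matrix") from exc
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new, g_new, H_new = engine.loglik_grad_info(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            cand, ll_new, g_new, H_new = beta, ll, g, H
        if np.max(np.abs(cand)) > DIVERGENCE_BETA:
            # distinguish a genuine interior optimum from a likelihood that
            # keeps rising toward infinity (monotone likelihood): probe outward
            ll_out = engine.loglik_grad_info(1.5 * cand)[0]
            if np.max(np.abs(g_new)) > 1e-4 or ll_out >= ll_new - 1e-10:
                raise ConvergenceError(
                    f"{context}: coefficient beyond |beta| > {DIVERGENCE_BETA:g} with "
                    "the likelihood still rising -- monotone likelihood (e.g. a "
                    "covariate perfectly orders the events). Consider removing or "
                    "coarsening that covariate."
                )
        done = (
            abs(ll_new - ll) <= NR_TOL * (abs(ll_new) + NR_TOL)
            and np.max(np.abs(g_new)) < 1e-8 * (1 + abs(ll_new))
        )
        beta, ll, g, H = cand, ll_new, g_new, H_new
        if done:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"{context}: no convergence in {NR_MAX_ITER} iterations (last |score| = "
            f"{np.max(np.abs(g)):.3g})"
        )
    return beta, ll, g, H, n_iter


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class PredictionResult:
    """A conditional curve with the variance of log Lambda(t|x) (equal to the
    variance on the log(-log) probability scale)."""

    times: np.ndarray
    values: np.ndarray            # S(t|x) or F1(t|x)
    var_log_cumhaz: np.ndarray    # NaN where Lambda = 0
    outcome_type: str             # "survival" | "cumulative_incidence"


@dataclass
class CoxFit:
    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    ties_method: str
    design: DesignMatrix
    baselines: dict                     # stratum label (None = single) -> _BaselineIngredients
    stratified: bool = False
    outcome_type: str = "survival"
    model_tag: str = "cox"
    dataset: SurvivalDataset | None = field(default=None, repr=False)

    @property
    def column_names(self):
        return self.design.column_names

    @property
    def baseline_cumhaz(self) -> dict:
        return {lab: ing.cumhaz for lab, ing in self.baselines.items()}

    def linear_predictor(self, row: np.ndarray) -> float:
        return float(np.asarray(row, float) @ self.beta)

    def predict_curve(self, row, times, stratum=None) -> PredictionResult:
        """S(t|x) = exp(-Lambda0(t) e^{x'b}) with Var[log Lambda(t|x)]."""
        times = np.asarray(times, float)
        if np.any(times < 0):
            raise ValueError("prediction times must be non-negative")
        row = np.asarray(row, float)
        ing = self._ingredients(stratum)
        idx = np.searchsorted(ing.times, times, side="right") - 1
        lam0 = np.where(idx >= 0, ing.cum_b[np.clip(idx, 0, None)], 0.0)
        eta = self.linear_predictor(row)
        lam = lam0 * np.exp(eta)
        values = np.exp(-lam)
        var = np.full_like(times, np.nan)
        pos = idx >= 0
        if pos.any():
            k = np.clip(idx[pos], 0, None)
            q = row[None, :] * ing.cum_b[k, None] - ing.cum_c[k]  # Q(t)
            var_lam_over_e2eta = ing.cum_a[k] + np.einsum(
                "tp,pq,tq->t", q, self.covariance, q
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                var[pos] = var_lam_over_e2eta / ing.cum_b[k] ** 2
        return PredictionResult(times, values, var, self.outcome_type)

    def predict_survival_matrix(self, rows: np.ndarray, times, stratum=None) -> np.ndarray:
        """Vectorized S(t|x_i) for many covariate rows (metrics use this)."""
        times = np.asarray(times, float)
        ing = self._ingredients(stratum)
        idx = np.searchsorted(ing.times, times, side="right") - 1
        lam0 = np.where(idx >= 0, ing.cum_b[np.clip(idx, 0, None)], 0.0)
        eta = np.asarray(rows, float) @ self.beta
        return np.exp(-np.outer(np.exp(eta), lam0))

    def _ingredients(self, stratum) -> _BaselineIngredients:
        if not self.stratified:
            return self.baselines[None]
        if stratum is None:
            raise ValueError(
                f"stratified fit: pass stratum= one of {sorted(map(str, self.baselines))}"
            )
        return self.baselines[stratum]

    def refit(self, ds: SurvivalDataset) -> "CoxFit":
        if self.stratified:
            return fit_stratified_cox(ds, ties=self.ties_method)
        return fit_cox(ds, ties=self.ties_method)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_tag": self.model_tag,
                "beta": self.beta.tolist(),
                "covariance": self.covariance.tolist(),
                "loglik": self.loglik,
                "n_iter": self.n_iter,
                "ties_method": self.ties_method,
                "stratified": self.stratified,
                "outcome_type": self.outcome_type,
                "design": self.design.to_dict(),
                "baselines": {
                    ("" if lab is None else str(lab)): ing.to_dict()
                    for lab, ing in self.baselines.items()
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CoxFit":
        d = json.loads(text)
        return cls(
            beta=np.asarray(d["beta"], float),
            covariance=np.asarray(d["covariance"], float),
            loglik=float(d["loglik"]),
            n_iter=int(d["n_iter"]),
            converged=True,
            ties_method=d["ties_method"],
            design=DesignMatrix.from_dict(d["design"]),
            baselines={
                (None if lab == "" else lab): _BaselineIngredients.from_dict(v)
                for lab, v in d["baselines"].items()
            },
            stratified=bool(d["stratified"]),
            outcome_type=d["outcome_type"],
            model_tag=d["model_tag"],
        )


# ---------------------------------------------------------------------------
# fitting entry points


def _prepare(ds: SurvivalDataset, design: DesignMatrix | None):
    if ds.interval_mode:
        raise ValueError("Cox fitting needs right-censored data (a single time column)")
    design = design if design is not None else build_design(ds)
    design.check_informative()
    events = ds.events.copy()
    if np.any(events >= 2):
        warnings.warn(
            "competing-cause codes (>= 2) treated as censored at their time "
            "(cause-specific hazard convention); consider fit_fine_gray",
            stacklevel=3,
        )
        events = np.where(events >= 2, 0, events)
    if not np.any(events == 1):
        raise ValueError("no events of interest (code 1) to fit on")
    return design, events.astype(bool)


def fit_cox(ds: SurvivalDataset, design: DesignMatrix | None = None, ties: str = "efron") -> CoxFit:
    """Classic Cox model.  Competing-cause codes are censored with a warning."""
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    design, events = _prepare(ds, design)
    engine = _CoxEngine(ds.times, events, design.centered, ties=ties)
    beta, ll, g, H, n_iter = _newton(engine, design.p, context="Cox partial likelihood")
    cov = np.linalg.inv(H)
    baselines = engine.baseline_ingredients(beta, design.center)
    return CoxFit(
        beta=beta, covariance=cov, loglik=ll, n_iter=n_iter, converged=True,
        ties_method=ties, design=design, baselines=baselines, dataset=ds,
    )


def fit_stratified_cox(
    ds: SurvivalDataset, design: DesignMatrix | None = None, ties: str = "efron"
) -> CoxFit:
    """Cox model with a shared beta but a separate Breslow baseline per
    stratum; the partial likelihood is the product over strata."""
    if ds.strata is None:
        raise ValueError("dataset has no stratum column")
    design, events = _prepare(ds, design)
    strata = np.asarray(ds.strata)
    labels, counts = np.unique(strata, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 strata")
    engine = _CoxEngine(ds.times, events, design.centered, ties=ties, strata=strata)
    beta, ll, g, H, n_iter = _newton(
        engine, design.p, context="stratified Cox partial likelihood"
    )
    cov = np.linalg.inv(H)
    baselines = engine.baseline_ingredients(beta, design.center)
    return CoxFit(
        beta=beta, covariance=cov, loglik=ll, n_iter=n_iter, converged=True,
        ties_method=ties, design=design, baselines=baselines, stratified=True,
        model_tag="stratified_cox", dataset=ds,
    )


def breslow_baseline(fit: CoxFit) -> StepFunction | dict:
    """The Breslow baseline cumulative hazard Lambda0(t) (per stratum when
    stratified).  With beta = 0 this is exactly the Nelson-Aalen estimator."""
    if not fit.converged:
        raise ConvergenceError("fit did not converge; baseline unavailable")
    if fit.stratified:
        return fit.baseline_cumhaz
    return fit.baseline_cumhaz[None]


def predict_survival_cox(fit: CoxFit, covariate_row, time_grid, stratum=None) -> PredictionResult:
    """Conditional survival with the variance of log Lambda(t|x)."""
    row = np.asarray(covariate_row, float)
    if row.shape != (fit.design.p,):
        raise ValueError(
            f"covariate row has {row.shape} entries; design expects {fit.design.p}"
        )
    return fit.predict_curve(row, time_grid, stratum=stratum)
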