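"""Parametric Weibull survival regression (AFT form) for right- and
interval-censored data.

Model: S(t | x) = exp( -(t / (lambda * exp(x' gamma)))^k ), i.e. an
accelerated-failure-time model with Weibull baseline: shape k, scale lambda,
log-time coefficients gamma.  Under proportional hazards the same model has
coefficients beta_PH = -k * gamma.

Likelihood (log):
  right mode:     events contribute log f(t|x), censored -(t/a)^k
  interval mode:  exact times log f, windows log[S(L|x) - S(R|x)]
                  with S(inf) = 0 and S(0) = 1.

Optimization is quasi-Newton (BFGS) over theta = (log k, log lambda, gamma)
on the centered design; the covariance is the inverse of a central-difference
Hessian at the optimum, mapped back to the uncentered parameterization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .cox import PredictionResult
from .data import SurvivalDataset
from .design import DesignMatrix, build_design
from .errors import ConvergenceError, UnidentifiableError
from . import cox as _cox  # noqa: F401  (shared prediction conventions)

__all__ = ["WeibullFit", "fit_weibull"]


def _numeric_hessian(fun, x, rel_step=1e-4):
    """Central-difference Hessian; accurate enough for Wald covariances."""
    x = np.asarray(x, float)
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


@dataclass
class WeibullFit:
    shape: float                    # k
    scale: float                    # lambda (at x = 0, uncentered)
    gamma: np.ndarray               # AFT coefficients on log-time
    covariance: np.ndarray          # for (log k, log lambda, gamma)
    loglik: float
    censoring_mode: str             # "right" | "interval"
    design: DesignMatrix
    converged: bool = True
    n_iter: int = 0
    outcome_type: str = "survival"
    model_tag: str = "weibull"
    dataset: SurvivalDataset | None = field(default=None, repr=False)

    @property
    def beta_ph(self) -> np.ndarray:
        """Equivalent proportional-hazards coefficients, -k * gamma."""
        return -self.shape * self.gamma

    def se(self) -> dict:
        """Delta-method standard errors on the natural scale."""
        sd = np.sqrt(np.diag(self.covariance))
        return {
            "shape": self.shape * sd[0],
            "scale": self.scale * sd[1],
            "gamma": sd[2:],
        }

    def predict_curve(self, row, times, stratum=None) -> PredictionResult:
        """Closed-form S(t|x); variance of log(-log S) by the delta method.

        psi = log(-log S) = k (log t - log lambda - x' gamma) with gradient
        (psi, -k, -k x) w.r.t. (log k, log lambda, gamma).
        """
        times = np.asarray(times, float)
        row = np.asarray(row, float)
        k, lam = self.shape, self.scale
        log_a = np.log(lam) + float(row @ self.gamma)
        with np.errstate(divide="ignore"):
            psi = k * (np.log(times) - log_a)
        values = np.exp(-np.exp(psi))
        var = np.full_like(times, np.nan)
        ok = times > 0
        if ok.any():
            grad = np.empty((ok.sum(), 2 + row.size))
            grad[:, 0] = psi[ok]
            grad[:, 1] = -k
            grad[:, 2:] = -k * row[None, :]
            var[ok] = np.einsum("tp,pq,tq->t", grad, self.covariance, grad)
        return PredictionResult(times, values, var, "survival")

    def predict_survival_matrix(self, rows, times, stratum=None) -> np.ndarray:
        times = np.asarray(times, float)
        a = self.scale * np.exp(np.asarray(rows, float) @ self.gamma)
        with np.errstate(divide="ignore"):
            z = (times[None, :] / a[:, None]) ** self.shape
        return np.exp(-z)

    def refit(self, ds: SurvivalDataset) -> "WeibullFit":
        return fit_weibull(ds, mode=self.censoring_mode)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_tag": self.model_tag,
                "shape": self.shape,
                "scale": self.scale,
                "gamma": self.gamma.tolist(),
                "covariance": self.covariance.tolist(),
                "loglik": self.loglik,
                "censoring_mode": self.censoring_mode,
                "design": self.design.to_dict(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "WeibullFit":
        d = json.loads(text)
        return cls(
            shape=float(d["shape"]),
            scale=float(d["scale"]),
            gamma=np.asarray(d["gamma"], float),
            covariance=np.asarray(d["covariance"], float),
            loglik=float(d["loglik"]),
            censoring_mode=d["censoring_mode"],
            design=DesignMatrix.from_dict(d["design"]),
        )


def weibull_loglik(theta, Xc, mode, right_data=None, interval_data=None):
    """Log-likelihood at theta = (log k, log lambda_c, gamma) on the
    centered design.  Exposed for brute-force cross-checks."""
    lk, llam = theta[0], theta[1]
    gamma = np.asarray(theta[2:], float)
    k = np.exp(lk)
    log_a = llam + Xc @ gamma

    if mode == "right":
        t, ev = right_data
        with np.errstate(divide="ignore"):
            logt = np.log(np.where(t > 0, t, 1.0))
        u = k * (logt - log_a)          # log z^k where z = t/a
        z = np.where(t > 0, np.exp(u), 0.0)
        ll = np.sum(np.where(ev, lk - logt + u, 0.0)) - z.sum()
        return float(ll)

    L, R = interval_data
    ll = 0.0
    exact = L == R
    if exact.any():
        t = L[exact]
        logt = np.log(t)
        u = k * (logt - log_a[exact])
        ll += np.sum(lk - logt + u - np.exp(u))
    win = ~exact
    if win.any():
        la = log_a[win]
        Lw, Rw = L[win], R[win]
        with np.errstate(divide="ignore"):
            zL = np.where(Lw > 0, np.exp(k * (np.log(np.maximum(Lw, 1e-300)) - la)), 0.0)
        SL = np.exp(-zL)
        SR = np.where(
            np.isinf(Rw), 0.0, np.exp(-np.exp(k * (np.log(np.maximum(Rw, 1e-300)) - la)))
        )
        diff = SL - SR
        if np.any(diff <= 0):
            return -np.inf
        ll += np.sum(np.log(diff))
    return float(ll)


def fit_weibull(
    ds: SurvivalDataset, design: DesignMatrix | None = None, mode: str | None = None
) -> WeibullFit:
    """Maximum-likelihood Weibull AFT fit.

    ``mode`` defaults to the dataset's censoring mode.  Right mode requires
    at least one event; interval mode at least one finite window or exact
    time (otherwise the scale is unidentifiable).
    """
    if mode is None:
        mode = "interval" if ds.interval_mode else "right"
    if mode not in ("right", "interval"):
        raise ValueError("mode must be 'right' or 'interval'")
    design = design if design is not None else build_design(ds)
    design.check_informative()
    Xc = design.centered

    if mode == "right":
        if ds.interval_mode:
            raise ValueError("dataset is interval-censored; use mode='interval'")
        ev = ds.events == 1
        if not ev.any():
            raise UnidentifiableError(
                "all observations right-censored: the Weibull likelihood is flat"
            )
        if np.any(ds.times[ev] <= 0):
            raise ValueError("event times must be positive for the Weibull model")
        args = dict(right_data=(ds.times, ev), interval_data=None)
        t_init = np.median(ds.times[ev])
    else:
        if not ds.interval_mode:
            raise ValueError("dataset is right-censored; use mode='right'")
        L, R = ds.interval_left, ds.interval_right
        informative = np.isfinite(R)
        if not informative.any():
            raise UnidentifiableError(
                "no finite interval or exact time: the likelihood is flat"
            )
        args = dict(right_data=None, interval_data=(L, R))
        mid = np.where(np.isfinite(R), 0.5 * (L + R), L)
        t_init = np.median(mid[mid > 0]) if np.any(mid > 0) else 1.0

    def nll(theta):
        v = -weibull_loglik(theta, Xc, mode, **args)
        # a large finite penalty keeps finite-difference gradients usable
        return v if np.isfinite(v) else 1e10

    x0 = np.concatenate([[0.0, np.log(max(t_init, 1e-8))], np.zeros(design.p)])
    res = optimize.minimize(nll, x0, method="BFGS", options={"gtol": 1e-8, "maxiter": 500})
    if not res.success and np.max(np.abs(res.jac)) > 1e-3:
        # one polish from the BFGS endpoint before giving up
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000})
        if res2.fun <= res.fun:
            res = res2
        if np.max(np.abs(optimize.approx_fprime(res.x, nll, 1e-6))) > 1e-2:
            raise ConvergenceError(
                f"Weibull fit did not converge: {res.message} "
                f"(nll {res.fun:.6g}, {res.nit} iterations)"
            )

    theta = res.x
    H = _numeric_hessian(nll, theta)
    cov_c = np.linalg.pinv(H)

    # map (log k, log lambda_c, gamma) -> uncentered log lambda = log lambda_c - c'gamma
    c = design.center
    p = design.p
    Jac = np.eye(2 + p)
    Jac[1, 2:] = -c
    cov = Jac @ cov_c @ Jac.T
    gamma = theta[2:]
    return WeibullFit(
        shape=float(np.exp(theta[0])),
        scale=float(np.exp(theta[1] - c @ gamma)),
        gamma=gamma,
        covariance=cov,
        loglik=float(-res.fun),
        censoring_mode=mode,
        design=design,
        n_iter=int(res.nit),
        dataset=ds,
    )
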