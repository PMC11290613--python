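"""The time x covariate matrix of conditional predictions.

A fitted model plus a covariate grid and an adjuster profile yields a
:class:`SurvivalSurface`: predicted survival (or cumulative incidence) at
every (covariate value, time) cell, optionally with pointwise confidence
bands.  This is the interchange object between estimation and rendering.

Bands are formed on the log(-log) scale -- log(-log S) for survival,
log(-log(1 - F)) for incidence -- which keeps them inside (0, 1); where the
estimate sits at 0 or 1 the band collapses to the point value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import SurvivalDataset
from .design import DesignMatrix
from .errors import DegenerateDesignError, RangeError

__all__ = [
    "GridSpec",
    "CovariateProfile",
    "SurvivalSurface",
    "build_grid",
    "default_time_grid",
    "default_profile",
    "compute_surface",
    "surface_ci",
    "value_at",
]


@dataclass(frozen=True)
class GridSpec:
    covariate_values: np.ndarray
    time_grid: np.ndarray

    def __post_init__(self):
        cv = np.asarray(self.covariate_values, float)
        tg = np.asarray(self.time_grid, float)
        if cv.size < 2 or np.any(np.diff(cv) <= 0):
            raise ValueError("covariate grid must be >= 2 strictly increasing values")
        if tg.size < 1 or np.any(np.diff(tg) <= 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "covariate_values", cv)
        object.__setattr__(self, "time_grid", tg)


@dataclass(frozen=True)
class CovariateProfile:
    """Fixed adjuster values the surface is conditioned on; each entry is
    tagged with its provenance (user-specified or package default)."""

    values: dict = field(default_factory=dict)   # adjuster -> value / level
    sources: dict = field(default_factory=dict)  # adjuster -> "user" | "default"

    def __getitem__(self, k):
        return self.values[k]

    def items(self):
        return self.values.items()


@dataclass
class SurvivalSurface:
    time_grid: np.ndarray
    covariate_values: np.ndarray
    values: np.ndarray                # (n_covariate, n_times)
    outcome_type: str                 # "survival" | "cumulative_incidence"
    model_tag: str = ""
    predictor_name: str = "x"
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    ci_level: float | None = None
    profile: CovariateProfile = field(default_factory=CovariateProfile)

    @property
    def has_bands(self) -> bool:
        return self.lower is not None and self.upper is not None

    def to_json(self) -> str:
        d = {
            "times": self.time_grid.tolist(),
            "covariate": self.covariate_values.tolist(),
            "values": self.values.tolist(),
            "outcome_type": self.outcome_type,
            "model_tag": self.model_tag,
            "predictor_name": self.predictor_name,
            "ci_level": self.ci_level,
            "profile": {
                k: {"value": v, "source": self.profile.sources.get(k, "user")}
                for k, v in self.profile.items()
            },
        }
        if self.has_bands:
            d["lower"] = self.lower.tolist()
            d["upper"] = self.upper.tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "SurvivalSurface":
        d = json.loads(text)
        prof = CovariateProfile(
            {k: v["value"] for k, v in d.get("profile", {}).items()},
            {k: v["source"] for k, v in d.get("profile", {}).items()},
        )
        return cls(
            time_grid=np.asarray(d["times"], float),
            covariate_values=np.asarray(d["covariate"], float),
            values=np.asarray(d["values"], float),
            outcome_type=d["outcome_type"],
            model_tag=d.get("model_tag", ""),
            predictor_name=d.get("predictor_name", "x"),
            lower=None if "lower" not in d else np.asarray(d["lower"], float),
            upper=None if "upper" not in d else np.asarray(d["upper"], float),
            ci_level=d.get("ci_level"),
            profile=prof,
        )


# ---------------------------------------------------------------------------
# grids and profiles


def build_grid(
    ds: SurvivalDataset,
    predictor: str | None = None,
    strategy: str = "linear",
    n_points: int = 100,
    time_grid=None,
    quantile_trim: tuple[float, float] | None = None,
) -> GridSpec:
    """Covariate axis over the observed range (linear or quantile spacing,
    duplicates collapsed); time axis defaults to the observed event times
    with 0 prepended."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    vals = ds.column(predictor) if predictor else ds.predictor
    vals = np.asarray(vals, float)
    vals = vals[np.isfinite(vals)]
    if np.unique(vals).size < 2:
        raise DegenerateDesignError("constant predictor: the covariate axis is degenerate")
    if quantile_trim is not None:
        lo, hi = np.quantile(vals, quantile_trim)
    else:
        lo, hi = vals.min(), vals.max()
    if strategy == "linear":
        cv = np.linspace(lo, hi, n_points)
    elif strategy == "quantile":
        cv = np.unique(np.quantile(vals, np.linspace(0, 1, n_points)))
    else:
        raise ValueError("strategy must be 'linear' or 'quantile'")
    tg = np.asarray(time_grid, float) if time_grid is not None else default_time_grid(ds)
    return GridSpec(cv, tg)


def default_time_grid(ds: SurvivalDataset) -> np.ndarray:
    """Sorted unique observed event times, with 0 prepended."""
    if ds.interval_mode:
        pts = np.unique(
            np.concatenate([ds.interval_left, ds.interval_right[np.isfinite(ds.interval_right)]])
        )
        pts = pts[pts > 0]
    else:
        pts = np.unique(ds.times[ds.events >= 1])
        pts = pts[pts > 0]
    return np.concatenate([[0.0], pts])


def default_profile(ds: SurvivalDataset, design: DesignMatrix | None = None) -> CovariateProfile:
    """Median for continuous adjusters, most frequent level for categorical
    ones (frequency ties broken by sorted level order)."""
    values, sources = {}, {}
    for name, adj in ds.adjusters.items():
        if adj.kind == "continuous":
            values[name] = float(np.median(adj.values[np.isfinite(adj.values)]))
        else:
            lv, ct = np.unique(adj.values.astype(str), return_counts=True)
            values[name] = sorted(lv[ct == ct.max()])[0]
        sources[name] = "default"
    return CovariateProfile(values, sources)


# ---------------------------------------------------------------------------
# surfaces


def _bands_from_var(values, var, outcome_type, ci_level):
    """Pointwise bands on the log(-log) scale, collapsed at the boundary."""
    z = stats.norm.ppf(0.5 + ci_level / 2)
    S = values if outcome_type == "survival" else 1.0 - values
    lower = values.copy()
    upper = values.copy()
    ok = np.isfinite(var) & (S > 0) & (S < 1)
    se = np.sqrt(var[ok])
    # S^(exp(±z se)): monotone transform of psi = log(-log S)
    s_lo = S[ok] ** np.exp(z * se)
    s_hi = S[ok] ** np.exp(-z * se)
    if outcome_type == "survival":
        lower[ok], upper[ok] = s_lo, s_hi
    else:  # incidence: F = 1 - S, band order flips
        lower[ok], upper[ok] = 1.0 - s_hi, 1.0 - s_lo
    return lower, upper


def compute_surface(
    model,
    grid: GridSpec,
    profile: CovariateProfile | None = None,
    ci_level: float | None = 0.95,
    stratum=None,
) -> SurvivalSurface:
    """Evaluate the model at every (grid covariate value, time) cell with the
    adjusters held at the profile.  Bands appear when the model supplies an
    asymptotic variance; backend models yield point surfaces."""
    design: DesignMatrix = model.design
    profile = profile if profile is not None else CovariateProfile()
    cv, tg = grid.covariate_values, grid.time_grid

    obs = design.matrix[:, 0] if design.matrix.size else None
    if obs is not None and obs.size:
        span = obs.max() - obs.min()
        if span > 0 and (cv.min() < obs.min() - span or cv.max() > obs.max() + span):
            warnings.warn(
                "covariate grid extends far beyond the observed range; "
                "predictions there are extrapolations",
                stacklevel=2,
            )

    values = np.empty((cv.size, tg.size))
    var = np.empty_like(values)
    for i, x in enumerate(cv):
        row = design.encode_row(x, profile.values)
        res = model.predict_curve(row, tg, stratum=stratum)
        values[i] = res.values
        var[i] = res.var_log_cumhaz
    outcome = model.outcome_type
    surf = SurvivalSurface(
        time_grid=tg,
        covariate_values=cv,
        values=values,
        outcome_type=outcome,
        model_tag=getattr(model, "model_tag", type(model).__name__),
        predictor_name=design.predictor_name,
        profile=profile,
    )
    if ci_level is not None and np.isfinite(var).any():
        surf.lower, surf.upper = _bands_from_var(values, var, outcome, ci_level)
        surf.ci_level = ci_level
    return surf


def surface_ci(
    model,
    surface: SurvivalSurface,
    method: str = "delta",
    ci_level: float = 0.95,
    n_boot: int = 200,
    seed: int | None = None,
    stratum=None,
) -> SurvivalSurface:
    """Attach pointwise bands: ``delta`` (asymptotic, log(-log) scale) or
    ``bootstrap`` (percentile over resampled refits; needs the originating
    dataset on the model)."""
    grid = GridSpec(surface.covariate_values, surface.time_grid)
    if method == "delta":
        return compute_surface(model, grid, surface.profile, ci_level=ci_level, stratum=stratum)
    if method != "bootstrap":
        raise ValueError("method must be 'delta' or 'bootstrap'")
    ds = getattr(model, "dataset", None)
    if ds is None:
        raise ValueError("bootstrap bands need the originating dataset on the model")
    rng = np.random.default_rng(seed)
    stack = np.empty((n_boot,) + surface.values.shape)
    b = 0
    attempts = 0
    while b < n_boot:
        attempts += 1
        if attempts > 3 * n_boot:
            raise RuntimeError("too many failed bootstrap refits")
        idx = rng.integers(0, ds.n, ds.n)
        try:
            refit = model.refit(ds.take(idx))
            stack[b] = compute_surface(
                refit, grid, surface.profile, ci_level=None, stratum=stratum
            ).values
        except Exception:  # resample produced a degenerate dataset; redraw
            continue
        b += 1
    alpha = 1 - ci_level
    out = SurvivalSurface(
        time_grid=surface.time_grid,
        covariate_values=surface.covariate_values,
        values=surface.values,
        outcome_type=surface.outcome_type,
        model_tag=surface.model_tag,
        predictor_name=surface.predictor_name,
        lower=np.quantile(stack, alpha / 2, axis=0),
        upper=np.quantile(stack, 1 - alpha / 2, axis=0),
        ci_level=ci_level,
        profile=surface.profile,
    )
    return out


def value_at(surface: SurvivalSurface, t: float, x: float):
    """Hover lookup: step in time (last knot <= t, matching the estimators'
    step functions), linear interpolation in the covariate."""
    tg, cv = surface.time_grid, surface.covariate_values
    if not (0 <= t <= tg[-1]):
        raise RangeError(f"t = {t} outside [0, {tg[-1]}]")
    if not (cv[0] <= x <= cv[-1]):
        raise RangeError(f"x = {x} outside [{cv[0]}, {cv[-1]}]")
    ti = np.searchsorted(tg, t, side="right") - 1
    if ti < 0:  # t in [0, first knot): survival 1, incidence 0
        est = 1.0 if surface.outcome_type == "survival" else 0.0
        return est, est, est

    def interp(mat):
        return float(np.interp(x, cv, mat[:, ti]))

    est = interp(surface.values)
    lo = interp(surface.lower) if surface.has_bands else est
    hi = interp(surface.upper) if surface.has_bands else est
    return est, lo, hi
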