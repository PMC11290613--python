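"""Adapter protocol for external survival predictors.

Advanced models (spline hazards, random survival forests, deep survival
networks) are not reimplemented here; anything that can produce a
probability curve over a time grid can be displayed by wrapping it in a
:class:`BackendAdapter`.  The wrapper enforces the surface contract: values
clipped to [0, 1] and monotone in time (running minimum for survival,
running maximum for cumulative incidence), with violations logged.
"""

from __future__ import annotations

import logging
from typing import Protocol, runtime_checkable

import numpy as np

from .cox import PredictionResult
from .data import SurvivalDataset
from .design import build_design
from .errors import AdapterError

__all__ = ["BackendAdapter", "WrappedBackend", "wrap_backend", "NativeAdapter"]

logger = logging.getLogger("survcontour")


@runtime_checkable
class BackendAdapter(Protocol):
    #: "survival" or "cumulative_incidence"
    outcome_type: str

    def fit(self, dataset: SurvivalDataset) -> None: ...

    def predict_survival(self, covariate_row, time_grid) -> np.ndarray: ...


class WrappedBackend:
    """A fitted external predictor satisfying the surface contract."""

    model_tag = "backend"

    def __init__(self, adapter: BackendAdapter, ds: SurvivalDataset):
        self.adapter = adapter
        self.outcome_type = getattr(adapter, "outcome_type", "survival")
        if self.outcome_type not in ("survival", "cumulative_incidence"):
            raise AdapterError(f"adapter declares unknown outcome {self.outcome_type!r}")
        self.design = build_design(ds)
        self.dataset = ds
        adapter.fit(ds)

    def predict_curve(self, row, times, stratum=None) -> PredictionResult:
        times = np.asarray(times, float)
        raw = np.asarray(self.adapter.predict_survival(np.asarray(row, float), times), float)
        if raw.shape != times.shape:
            raise AdapterError(
                f"adapter returned shape {raw.shape}, expected {times.shape}"
            )
        if not np.all(np.isfinite(raw)):
            raise AdapterError("adapter returned non-finite probabilities")
        vals = np.clip(raw, 0.0, 1.0)
        if np.any(vals != raw):
            logger.warning("adapter probabilities outside [0,1] clipped")
        if self.outcome_type == "survival":
            mono = np.minimum.accumulate(vals)
        else:
            mono = np.maximum.accumulate(vals)
        if np.any(mono != vals):
            logger.warning("adapter curve not monotone in time; enforced")
        return PredictionResult(times, mono, np.full_like(times, np.nan), self.outcome_type)

    def refit(self, ds: SurvivalDataset) -> "WrappedBackend":
        return WrappedBackend(self.adapter, ds)


def wrap_backend(adapter: BackendAdapter, ds: SurvivalDataset) -> WrappedBackend:
    """Fit *adapter* on *ds* and return a predictor honoring the surface
    contract (clipping + monotonization, violations logged)."""
    if not (hasattr(adapter, "fit") and hasattr(adapter, "predict_survival")):
        raise AdapterError("adapter must implement fit() and predict_survival()")
    return WrappedBackend(adapter, ds)


class NativeAdapter:
    """Expose one of this package's own fitted models through the adapter
    protocol (useful for testing adapters end to end)."""

    def __init__(self, fit):
        self._fit = fit
        self.outcome_type = fit.outcome_type

    def fit(self, dataset: SurvivalDataset) -> None:
        pass  # already fitted

    def predict_survival(self, covariate_row, time_grid):
        return self._fit.predict_curve(covariate_row, time_grid).values
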