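"""Right-continuous step functions.

The nonparametric objects in survival analysis -- Kaplan-Meier survival
curves, Breslow / Nelson-Aalen cumulative hazards, censoring-distribution
estimates -- are all right-continuous step functions with a finite set of
jump points.  This tiny class stores the knots and post-jump values and
evaluates by binary search, including the left limit needed for
inverse-probability-of-censoring weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StepFunction"]


@dataclass(frozen=True)
class StepFunction:
    """``f(t) = init`` for ``t < x[0]``, ``f(t) = y[k]`` for ``x[k] <= t < x[k+1]``.

    Parameters
    ----------
    x : sorted, strictly increasing knot locations.
    y : value taken at and after each knot (until the next one).
    init : value before the first knot.
    """

    x: np.ndarray
    y: np.ndarray
    init: float = 1.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size > 1 and np.any(np.diff(x) <= 0):
            raise ValueError("knots must be strictly increasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __call__(self, t):
        return self._eval(t, side="right")

    def left_limit(self, t):
        """f(t-): the value just before t (equals f(t) except at knots)."""
        return self._eval(t, side="left")

    def _eval(self, t, side):
        t = np.asarray(t, dtype=float)
        if self.x.size == 0:
            out = np.full(t.shape, self.init)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.x, t, side=side) - 1
        out = np.where(idx < 0, self.init, self.y[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {"x": self.x.tolist(), "y": self.y.tolist(), "init": self.init}

    @classmethod
    def from_dict(cls, d: dict) -> "StepFunction":
        return cls(np.asarray(d["x"], float), np.asarray(d["y"], float), float(d["init"]))
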