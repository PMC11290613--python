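"""Design-matrix construction: predictor first, adjusters expanded after it.

Categorical adjusters are one-hot encoded with the first sorted level as the
reference (dropped).  Column order is deterministic: predictor, then
adjusters in role order, levels in sorted order.  Fitting is done on the
centered matrix for numerical stability; the per-column means are kept so
that predictions can be made on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset
from .errors import DegenerateDesignError, RoleError

__all__ = ["DesignMatrix", "build_design"]


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n, p) raw (uncentered) values
    column_names: list[str]
    center: np.ndarray  # per-column means
    predictor_name: str
    #: categorical adjuster -> (all sorted levels, reference level)
    categorical_levels: dict[str, tuple[list[str], str]]
    continuous_adjusters: list[str]

    def __post_init__(self):
        if not hasattr(self, "_adjuster_order"):
            self._adjuster_order = []

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    @property
    def centered(self) -> np.ndarray:
        return self.matrix - self.center

    def check_informative(self) -> None:
        """Constant columns make the fit unidentifiable."""
        const = np.ptp(self.matrix, axis=0) == 0
        if const.any():
            names = [self.column_names[i] for i in np.flatnonzero(const)]
            raise DegenerateDesignError(
                f"constant design column(s): {', '.join(names)}"
            )

    def encode_row(self, predictor_value: float, profile: dict | None = None) -> np.ndarray:
        """Build one raw covariate row: the predictor at *predictor_value*,
        every adjuster at its profile value (level name for categoricals)."""
        profile = dict(profile or {})
        row = np.zeros(self.p)
        row[0] = predictor_value
        j = 1
        for name in self.continuous_adjusters_order():
            if name in self.categorical_levels:
                levels, ref = self.categorical_levels[name]
                level = str(profile.get(name, ref))
                if level not in levels:
                    raise RoleError(f"unknown level {level!r} for adjuster {name!r}")
                for lvl in levels[1:]:
                    row[j] = 1.0 if level == lvl else 0.0
                    j += 1
            else:
                if name not in profile:
                    raise RoleError(f"profile missing continuous adjuster {name!r}")
                row[j] = float(profile[name])
                j += 1
        return row

    def continuous_adjusters_order(self) -> list[str]:
        """Adjusters in their original role order (both kinds)."""
        return self._adjuster_order

    def to_dict(self) -> dict:
        return {
            "column_names": self.column_names,
            "center": self.center.tolist(),
            "predictor_name": self.predictor_name,
            "categorical_levels": {
                k: [levels, ref] for k, (levels, ref) in self.categorical_levels.items()
            },
            "continuous_adjusters": self.continuous_adjusters,
            "adjuster_order": self._adjuster_order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignMatrix":
        dm = cls(
            matrix=np.zeros((0, len(d["column_names"]))),
            column_names=list(d["column_names"]),
            center=np.asarray(d["center"], float),
            predictor_name=d["predictor_name"],
            categorical_levels={
                k: (list(v[0]), v[1]) for k, v in d["categorical_levels"].items()
            },
            continuous_adjusters=list(d["continuous_adjusters"]),
        )
        dm._adjuster_order = list(d["adjuster_order"])
        return dm


def build_design(ds: SurvivalDataset) -> DesignMatrix:
    cols = [np.asarray(ds.predictor, float)]
    names = [ds.predictor_name]
    cat_levels: dict[str, tuple[list[str], str]] = {}
    cont: list[str] = []
    order: list[str] = []
    for name, adj in ds.adjusters.items():
        order.append(name)
        if adj.kind == "continuous":
            cols.append(np.asarray(adj.values, float))
            names.append(name)
            cont.append(name)
        else:
            levels = sorted(np.unique(adj.values.astype(str)).tolist())
            cat_levels[name] = (levels, levels[0])
            for lvl in levels[1:]:  # reference level dropped
                cols.append((adj.values.astype(str) == lvl).astype(float))
                names.append(f"{name}[{lvl}]")
    X = np.column_stack(cols)
    dm = DesignMatrix(
        matrix=X,
        column_names=names,
        center=X.mean(axis=0),
        predictor_name=ds.predictor_name,
        categorical_levels=cat_levels,
        continuous_adjusters=cont,
    )
    dm._adjuster_order = order
    return dm
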