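"""Subject-level survival tables: column roles, validation, summaries.

This module owns the event-coding convention used throughout the package:

* ``0``  -- right-censored
* ``1``  -- event of interest
* ``>=2`` -- competing causes (flags the dataset as competing-risks)

and the two censoring modes: *right* (a single time column) and *interval*
(left/right bound columns, where an empty cell or the token ``Inf`` in the
right bound means the event was never observed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyDataError, ParseError, RoleError

__all__ = [
    "ColumnRoles",
    "AdjusterColumn",
    "SurvivalDataset",
    "CovariateSummary",
    "ValidationReport",
    "Violation",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "summarize_covariate",
]

logger = logging.getLogger("survcontour")

#: adjusters with at most this many distinct numeric values are treated as
#: categorical unless the caller says otherwise
MAX_CATEGORICAL_LEVELS = 10


@dataclass(frozen=True)
class ColumnRoles:
    """Which column plays which part in the model.

    Exactly one of ``time`` (right-censored mode) or the pair
    ``interval_left``/``interval_right`` (interval-censored mode) must be set.
    """

    event: str
    predictor: str
    time: str | None = None
    interval_left: str | None = None
    interval_right: str | None = None
    adjusters: tuple[str, ...] = ()
    stratum: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "adjusters", tuple(self.adjusters))
        right_mode = self.time is not None
        interval_mode = self.interval_left is not None or self.interval_right is not None
        if right_mode == interval_mode:
            raise RoleError(
                "set exactly one of 'time' or the pair 'interval_left'/'interval_right'"
            )
        if interval_mode and (self.interval_left is None or self.interval_right is None):
            raise RoleError("interval mode needs both 'interval_left' and 'interval_right'")
        if self.predictor in self.adjusters:
            raise RoleError(f"predictor {self.predictor!r} also listed among adjusters")

    @property
    def interval_mode(self) -> bool:
        return self.time is None

    def all_columns(self) -> list[str]:
        cols = [self.event, self.predictor]
        if self.interval_mode:
            cols = [self.interval_left, self.interval_right] + cols
        else:
            cols = [self.time] + cols
        cols += list(self.adjusters)
        if self.stratum is not None:
            cols.append(self.stratum)
        return cols


@dataclass(frozen=True)
class AdjusterColumn:
    name: str
    values: np.ndarray
    kind: str  # "continuous" | "categorical"

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown adjuster kind {self.kind!r}")


@dataclass
class SurvivalDataset:
    """Validated, in-memory survival data: the single source for fitting,
    profiling and histograms.

    ``times`` is set in right-censored mode; ``interval_left``/``interval_right``
    in interval mode (``interval_right`` may be ``+inf`` for right-censored
    subjects).
    """

    events: np.ndarray
    predictor: np.ndarray
    predictor_name: str
    times: np.ndarray | None = None
    interval_left: np.ndarray | None = None
    interval_right: np.ndarray | None = None
    adjusters: dict[str, AdjusterColumn] = field(default_factory=dict)
    strata: np.ndarray | None = None
    n_dropped: int = 0
    truth: dict | None = None  # ground truth attached by the simulators

    @property
    def n(self) -> int:
        return int(self.events.shape[0])

    @property
    def interval_mode(self) -> bool:
        return self.times is None

    @property
    def competing_risks(self) -> bool:
        return bool(np.any(self.events >= 2))

    @classmethod
    def from_arrays(
        cls,
        times=None,
        events=None,
        predictor=None,
        predictor_name: str = "x",
        interval_left=None,
        interval_right=None,
        adjusters: dict[str, np.ndarray] | None = None,
        adjuster_kinds: dict[str, str] | None = None,
        strata=None,
        truth: dict | None = None,
    ) -> "SurvivalDataset":
        events = np.asarray(events, dtype=int)
        adj = {}
        for name, vals in (adjusters or {}).items():
            vals = np.asarray(vals)
            kind = (adjuster_kinds or {}).get(name)
            if kind is None:
                kind = _detect_kind(pd.Series(vals))
            if kind == "continuous":
                vals = vals.astype(float)
            adj[name] = AdjusterColumn(name, vals, kind)
        return cls(
            events=events,
            predictor=np.asarray(predictor, dtype=float),
            predictor_name=predictor_name,
            times=None if times is None else np.asarray(times, dtype=float),
            interval_left=None if interval_left is None else np.asarray(interval_left, float),
            interval_right=None if interval_right is None else np.asarray(interval_right, float),
            adjusters=adj,
            strata=None if strata is None else np.asarray(strata),
            truth=truth,
        )

    def column(self, name: str) -> np.ndarray:
        """Look a column up by name across all roles."""
        if name == self.predictor_name:
            return self.predictor
        if name in self.adjusters:
            return self.adjusters[name].values
        raise RoleError(f"no column named {name!r} in this dataset")

    def take(self, idx) -> "SurvivalDataset":
        """Row subset / resample (used by the bootstrap)."""
        idx = np.asarray(idx)
        return replace(
            self,
            events=self.events[idx],
            predictor=self.predictor[idx],
            times=None if self.times is None else self.times[idx],
            interval_left=None if self.interval_left is None else self.interval_left[idx],
            interval_right=None if self.interval_right is None else self.interval_right[idx],
            adjusters={
                k: AdjusterColumn(v.name, v.values[idx], v.kind)
                for k, v in self.adjusters.items()
            },
            strata=None if self.strata is None else self.strata[idx],
            n_dropped=0,
        )

    def to_frame(self, roles: ColumnRoles | None = None) -> pd.DataFrame:
        roles = roles or self.default_roles()
        data = {}
        if self.interval_mode:
            data[roles.interval_left] = self.interval_left
            data[roles.interval_right] = self.interval_right
        else:
            data[roles.time] = self.times
        data[roles.event] = self.events
        data[roles.predictor] = self.predictor
        for name in roles.adjusters:
            data[name] = self.adjusters[name].values
        if roles.stratum is not None:
            data[roles.stratum] = self.strata
        return pd.DataFrame(data)

    def default_roles(self) -> ColumnRoles:
        return ColumnRoles(
            time=None if self.interval_mode else "time",
            interval_left="left" if self.interval_mode else None,
            interval_right="right" if self.interval_mode else None,
            event="event",
            predictor=self.predictor_name,
            adjusters=tuple(self.adjusters),
            stratum=None if self.strata is None else "stratum",
        )


@dataclass(frozen=True)
class CovariateSummary:
    """Marginal summary of one covariate: the median/mode used for adjuster
    profiles and the histogram drawn beside the contour plot.

    ``histogram`` is a list of ``(bin_left, bin_right, count)``; continuous
    bins are half-open ``[left, right)`` except the last, which is closed.
    For categorical columns each entry is ``(level, level, count)``.
    """

    column: str
    kind: str
    n_missing: int
    histogram: tuple
    median: float | None = None
    mode: object | None = None


@dataclass(frozen=True)
class Violation:
    code: str
    message: str
    rows: tuple[int, ...] = ()


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_json(self) -> str:
        return json.dumps(
            [
                {"code": v.code, "message": v.message, "rows": list(v.rows)}
                for v in self.violations
            ]
        )

    def __str__(self) -> str:
        if self.ok:
            return "dataset OK"
        return "\n".join(f"[{v.code}] {v.message}" for v in self.violations)


# ---------------------------------------------------------------------------
# reading / writing


def _detect_kind(series: pd.Series, max_levels: int = MAX_CATEGORICAL_LEVELS) -> str:
    numeric = pd.to_numeric(series, errors="coerce")
    if numeric.isna().any() and not series.isna().all():
        return "categorical"
    if series.dropna().nunique() <= max_levels:
        return "categorical"
    return "continuous"


def _numeric_or_raise(series: pd.Series, colname: str) -> np.ndarray:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0])
        raise ParseError(
            f"column {colname!r}: non-numeric value {series.iloc[row]!r} at row {row}"
        )
    return out.values.astype(float)


def read_dataset(
    path,
    roles: ColumnRoles,
    delimiter: str | None = None,
    max_categorical_levels: int = MAX_CATEGORICAL_LEVELS,
    categorical_overrides: dict[str, str] | None = None,
) -> SurvivalDataset:
    """Read a delimited text file and validate it against *roles*.

    Rows with missing values in any role column are dropped (complete-case on
    role columns only); the count is logged and stored on the dataset.
    The delimiter is taken from the extension (``.tsv`` -> tab) unless given.
    """
    path = str(path)
    if delimiter is None:
        delimiter = "\t" if path.endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=delimiter)
    return dataset_from_frame(
        df,
        roles,
        max_categorical_levels=max_categorical_levels,
        categorical_overrides=categorical_overrides,
    )


def dataset_from_frame(
    df: pd.DataFrame,
    roles: ColumnRoles,
    max_categorical_levels: int = MAX_CATEGORICAL_LEVELS,
    categorical_overrides: dict[str, str] | None = None,
) -> SurvivalDataset:
    missing = [c for c in roles.all_columns() if c not in df.columns]
    if missing:
        raise RoleError(f"role column(s) not in header: {', '.join(repr(c) for c in missing)}")

    df = df.copy()
    if roles.interval_mode:
        # sentinel for never-observed subjects: blank or "Inf" -> +infinity
        right = df[roles.interval_right]
        right = right.replace(
            {"Inf": np.inf, "inf": np.inf, "INF": np.inf, "": np.inf}
        )
        right = pd.to_numeric(right, errors="coerce")
        right = right.fillna(np.inf)
        df[roles.interval_right] = right

    role_cols = roles.all_columns()
    keep = df[role_cols].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d row(s) with missing values in role columns", n_dropped)
    df = df.loc[keep]
    if len(df) == 0:
        raise EmptyDataError("zero usable rows after dropping incomplete rows")

    events = _numeric_or_raise(df[roles.event], roles.event)
    if not np.allclose(events, np.round(events)):
        row = int(np.flatnonzero(~np.isclose(events, np.round(events)))[0])
        raise ParseError(f"column {roles.event!r}: non-integer event code at row {row}")
    events = events.astype(int)

    overrides = categorical_overrides or {}
    adjusters, kinds = {}, {}
    for name in roles.adjusters:
        kind = overrides.get(
            name, _detect_kind(df[name], max_levels=max_categorical_levels)
        )
        kinds[name] = kind
        if kind == "continuous":
            adjusters[name] = _numeric_or_raise(df[name], name)
        else:
            adjusters[name] = df[name].astype(str).values

    ds = SurvivalDataset.from_arrays(
        times=None
        if roles.interval_mode
        else _numeric_or_raise(df[roles.time], roles.time),
        events=events,
        predictor=_numeric_or_raise(df[roles.predictor], roles.predictor),
        predictor_name=roles.predictor,
        interval_left=None
        if not roles.interval_mode
        else _numeric_or_raise(df[roles.interval_left], roles.interval_left),
        interval_right=None
        if not roles.interval_mode
        else df[roles.interval_right].values.astype(float),
        adjusters=adjusters,
        adjuster_kinds=kinds,
        strata=None if roles.stratum is None else df[roles.stratum].astype(str).values,
    )
    ds.n_dropped = n_dropped
    return ds


def write_dataset(ds: SurvivalDataset, path, roles: ColumnRoles | None = None) -> None:
    """Write back to CSV so that re-reading with the same roles round-trips."""
    df = ds.to_frame(roles)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation & summaries


def validate_dataset(ds: SurvivalDataset) -> ValidationReport:
    """Check every dataset invariant; violations are data, not exceptions."""
    v: list[Violation] = []

    def rows_where(mask) -> tuple[int, ...]:
        return tuple(int(i) for i in np.flatnonzero(mask))

    if ds.interval_mode:
        neg = ds.interval_left < 0
        if neg.any():
            v.append(Violation("negative_time", "interval left bound < 0", rows_where(neg)))
        bad = ds.interval_left > ds.interval_right
        if bad.any():
            v.append(
                Violation(
                    "interval_order",
                    "interval left bound exceeds right bound",
                    rows_where(bad),
                )
            )
    else:
        neg = ds.times < 0
        if neg.any():
            v.append(Violation("negative_time", "negative survival time", rows_where(neg)))

    bad_codes = ds.events < 0
    if bad_codes.any():
        v.append(Violation("event_code", "event code < 0", rows_where(bad_codes)))

    finite = ds.predictor[np.isfinite(ds.predictor)]
    if np.unique(finite).size < 2:
        v.append(
            Violation(
                "degenerate_predictor",
                "predictor has fewer than 2 distinct finite values; "
                "the contour axis would be degenerate",
            )
        )
    return ValidationReport(tuple(v))


def summarize_covariate(
    ds: SurvivalDataset, column: str, n_bins: int = 30
) -> CovariateSummary:
    """Equal-width histogram over the observed range plus median (continuous)
    or most-frequent level (categorical)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = ds.column(column)
    kind = (
        ds.adjusters[column].kind if column in ds.adjusters else "continuous"
    )

    if kind == "categorical":
        s = pd.Series(values).dropna()
        if s.empty:
            raise EmptyDataError(f"column {column!r}: all values missing")
        counts = s.value_counts()
        top = counts.max()
        # frequency ties broken by sorted level order
        mode = sorted(counts.index[counts == top])[0]
        hist = tuple(
            (lvl, lvl, int(counts[lvl])) for lvl in sorted(counts.index)
        )
        return CovariateSummary(
            column=column,
            kind="categorical",
            n_missing=int(len(values) - len(s)),
            histogram=hist,
            mode=mode,
        )

    vals = np.asarray(values, float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise EmptyDataError(f"column {column!r}: all values missing")
    lo, hi = float(finite.min()), float(finite.max())
    if lo == hi:
        # constant column: a single degenerate bin
        hist = ((lo, hi, int(finite.size)),)
    else:
        counts, edges = np.histogram(finite, bins=n_bins, range=(lo, hi))
        hist = tuple(
            (float(edges[i]), float(edges[i + 1]), int(counts[i]))
            for i in range(n_bins)
        )
    return CovariateSummary(
        column=column,
        kind="continuous",
        n_missing=int(vals.size - finite.size),
        histogram=hist,
        median=float(np.median(finite)),
    )
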