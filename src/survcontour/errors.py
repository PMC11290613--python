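"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`SurvContourError`, so callers (and the CLI) can catch one type.
"""


class SurvContourError(Exception):
    """Base class for all survcontour errors."""


class RoleError(SurvContourError, KeyError):
    """A column role refers to a column that does not exist, or roles clash."""


class ParseError(SurvContourError, ValueError):
    """A cell could not be parsed as the type its role requires."""


class EmptyDataError(SurvContourError, ValueError):
    """No usable rows (or values) remain after validation."""


class DegenerateDesignError(SurvContourError, ValueError):
    """The design matrix carries no usable information (constant column,
    no within-stratum comparisons, degenerate covariate axis ...)."""


class ConvergenceError(SurvContourError, RuntimeError):
    """An iterative fit failed to converge, including monotone-likelihood
    divergence in partial-likelihood models."""


class UnidentifiableError(SurvContourError, ValueError):
    """The likelihood carries no information about a parameter
    (e.g. Weibull fit with every observation right-censored)."""


class AdapterError(SurvContourError, ValueError):
    """An external prediction backend violated its contract."""


class FormatError(SurvContourError, ValueError):
    """Unsupported or inconsistent export format."""


class ConsistencyError(SurvContourError, ValueError):
    """Two figure inputs describe different covariates."""


class RangeError(SurvContourError, ValueError):
    """A query point lies outside the valid span of a surface."""


class UnsupportedCombinationError(SurvContourError, ValueError):
    """A study-design combination no offered model covers
    (competing risks together with interval censoring)."""


class UndefinedMetricError(SurvContourError, ValueError):
    """A fit metric is undefined for the given data
    (e.g. no comparable pairs for the concordance index)."""
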