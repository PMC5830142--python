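"""OLS marginal-effect regression of workforce density on city determinants.

The outcome (doctors or nurses per 10,000 people) is modelled as

    y_i = alpha + sum_k beta_k x_ki + u_i,

fit by ordinary least squares.  Because the model is linear, the marginal
effect dy/dx of each covariate coincides with its coefficient; the
accessor is nevertheless kept separate so a non-linear fitter could slot
in behind the same interface.  Categorical covariates enter as indicator
(dummy) columns for every non-reference level.  Standard errors default to
the heteroskedasticity-robust HC1 sandwich — areal data are rarely
homoskedastic — with classical OLS errors available via ``cov_type``.

The fitted residuals, design-column means and outcome mean feed the
concentration-index decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import schema
from .exceptions import (
    ConfigurationError,
    EstimationError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "CategoricalSpec",
    "ModelSpec",
    "Design",
    "RegressionResult",
    "build_design",
    "fit_ols",
    "significance_stars",
]


@dataclass(frozen=True)
class CategoricalSpec:
    """A categorical covariate with its level set and reference level."""

    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.levels:
            raise ConfigurationError(
                f"reference {self.reference!r} not among levels of {self.name!r}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError(f"duplicate levels in categorical {self.name!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Which columns enter the model, and how.

    ``continuous`` columns are passed through; each entry of
    ``categoricals`` is expanded into indicators for its non-reference
    levels, in level order.
    """

    outcome: str
    continuous: tuple[str, ...] = ()
    categoricals: tuple[CategoricalSpec, ...] = ()

    def __post_init__(self) -> None:
        names = list(self.continuous) + [c.name for c in self.categoricals]
        if self.outcome in names:
            raise ConfigurationError(
                f"outcome {self.outcome!r} cannot also be a covariate"
            )
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate covariate names in model spec")

    @classmethod
    def default(cls, outcome: str) -> "ModelSpec":
        """Full city-schema spec: all continuous covariates plus all
        categoricals with their conventional references (youngest age
        band, shortest service band, men, Han, lowest education, East
        China)."""
        cats = tuple(
            CategoricalSpec(name=name, levels=levels, reference=levels[0])
            for name, levels in schema.CATEGORICAL_LEVELS.items()
        )
        return cls(
            outcome=outcome,
            continuous=schema.CONTINUOUS_COLUMNS,
            categoricals=cats,
        )

    def design_columns(self) -> tuple[str, ...]:
        """Deterministic design-column order: continuous in spec order,
        then each categorical's non-reference levels in level order."""
        cols = list(self.continuous)
        for cat in self.categoricals:
            cols += [
                schema.indicator_name(cat.name, lv)
                for lv in cat.levels
                if lv != cat.reference
            ]
        return tuple(cols)


@dataclass(frozen=True)
class Design:
    """Materialized design matrix (without the constant)."""

    matrix: pd.DataFrame
    dropped: tuple[str, ...] = ()
    #: map design column -> ("continuous", name) or ("indicator", column, level)
    terms: dict = field(default_factory=dict)


def build_design(table: pd.DataFrame, spec: ModelSpec) -> Design:
    """Expand a city table into the model's design matrix.

    Indicator columns that are constant in the data (e.g. a level no city
    takes) carry no information and are dropped with a warning rather
    than poisoning the fit.
    """
    missing = [c for c in (spec.outcome,) + spec.continuous if c not in table.columns]
    missing += [c.name for c in spec.categoricals if c.name not in table.columns]
    if missing:
        raise SchemaError(f"table is missing required columns: {missing}")

    cols: dict[str, np.ndarray] = {}
    terms: dict[str, tuple] = {}
    for name in spec.continuous:
        cols[name] = table[name].to_numpy(dtype=float)
        terms[name] = ("continuous", name)
    for cat in spec.categoricals:
        values = table[cat.name].astype(str)
        bad = sorted(set(values) - set(cat.levels))
        if bad:
            raise ValidationError(
                f"column {cat.name!r} contains unknown level(s) {bad}"
            )
        for lv in cat.levels:
            if lv == cat.reference:
                continue
            col = schema.indicator_name(cat.name, lv)
            cols[col] = (values == lv).to_numpy(dtype=float)
            terms[col] = ("indicator", cat.name, lv)

    X = pd.DataFrame(cols, index=table.index)
    degenerate = tuple(
        c for c in X.columns if terms[c][0] == "indicator" and X[c].nunique() == 1
    )
    if degenerate:
        warnings.warn(
            f"dropping degenerate indicator column(s) {list(degenerate)}",
            UserWarning,
            stacklevel=2,
        )
        X = X.drop(columns=list(degenerate))
        for c in degenerate:
            terms.pop(c)
    return Design(matrix=X, dropped=degenerate, terms=terms)


def significance_stars(p: float) -> str:
    """Conventional significance flag: ``***`` p<0.001, ``**`` p<0.01,
    ``*`` p<0.05 (strict inequalities), else ``ns``."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p-value must be in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class RegressionResult:
    """Fitted linear model with marginal effects and diagnostics."""

    spec: ModelSpec
    terms: tuple[str, ...]
    intercept: float
    intercept_se: float
    effects: dict
    std_errors: dict
    pvalues: dict
    significance: dict
    residuals: np.ndarray
    fitted: np.ndarray
    term_means: dict
    outcome_mean: float
    nobs: int
    cov_type: str
    dropped: tuple[str, ...] = ()
    term_kinds: dict = field(default_factory=dict)

    @property
    def marginal_effects(self) -> dict:
        """dy/dx per design column; identical to the coefficients in a
        linear model."""
        return dict(self.effects)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "dydx": self.effects[t],
                "std_err": self.std_errors[t],
                "p_value": self.pvalues[t],
                "significance": self.significance[t],
            }
            for t in self.terms
        ]
        return pd.DataFrame(rows).set_index("term")

    def summary(self) -> str:
        """Text report in the conventional layout: dy/dx, Std. Err.,
        stars; reference levels shown as Ref rows."""
        width = max(
            [len("Variable")]
            + [len(t) for t in self.terms]
            + [len(f"  {lv}") for c in self.spec.categoricals for lv in c.levels]
            + [len(c.name) for c in self.spec.categoricals]
        )
        lines = [
            f"OLS marginal effects for {self.spec.outcome}  (n={self.nobs}, SE={self.cov_type})",
            f"{'Variable'.ljust(width)}  {'dy/dx':>12}  {'Std. Err.':>12}",
            "-" * (width + 30),
        ]

        def effect_row(label: str, term: str) -> str:
            star = self.significance[term]
            star = "" if star == "ns" else star
            return (
                f"{label.ljust(width)}  {self.effects[term]:>12.4f}{star:<3}"
                f"{self.std_errors[term]:>10.4f}"
            )

        for t in self.spec.continuous:
            if t in self.effects:
                lines.append(effect_row(t, t))
        for cat in self.spec.categoricals:
            lines.append(cat.name)
            for lv in cat.levels:
                label = f"  {lv}"
                if lv == cat.reference:
                    lines.append(f"{label.ljust(width)}  {'Ref':>12}")
                    continue
                term = schema.indicator_name(cat.name, lv)
                if term in self.effects:
                    lines.append(effect_row(label, term))
                else:
                    lines.append(f"{label.ljust(width)}  {'(dropped)':>12}")
        lines.append("-" * (width + 30))
        lines.append("* p<0.05, ** p<0.01, *** p<0.001")
        return "\n".join(lines)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns that do not increase the rank of [1 | X]."""
    n = X.shape[0]
    kept = np.ones((n, 1))
    rank = 1
    bad = []
    for j, name in enumerate(names):
        cand = np.hstack([kept, X[:, j : j + 1]])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept, rank = cand, r
        else:
            bad.append(name)
    return bad


def fit_ols(
    table: pd.DataFrame, spec: ModelSpec, cov_type: str = "HC1"
) -> RegressionResult:
    """Fit the linear model by OLS.

    Parameters
    ----------
    table : DataFrame
        City table containing the outcome and all spec columns.
    spec : ModelSpec
    cov_type : {"HC1", "nonrobust"}
        Sandwich (default) or classical standard errors.

    Raises
    ------
    EstimationError
        If the design is rank deficient after dropping degenerate
        indicator columns, or n is too small.
    """
    design = build_design(table, spec)
    X = design.matrix
    y = table[spec.outcome].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise EstimationError(
            f"need more observations ({n}) than design columns plus intercept ({p + 1})"
        )
    Xmat = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.hstack([np.ones((n, 1)), Xmat])) < p + 1:
        bad = _collinear_columns(Xmat, list(X.columns))
        raise EstimationError(f"design is rank deficient; collinear terms: {bad}")

    exog = sm.add_constant(X, has_constant="add")
    model = sm.OLS(y, exog)
    res = model.fit() if cov_type == "nonrobust" else model.fit(cov_type=cov_type)

    terms = tuple(X.columns)
    effects = {t: float(res.params[t]) for t in terms}
    std_errors = {t: float(res.bse[t]) for t in terms}
    pvalues = {t: float(res.pvalues[t]) for t in terms}
    stars = {t: significance_stars(min(max(pvalues[t], 0.0), 1.0)) for t in terms}
    return RegressionResult(
        spec=spec,
        terms=terms,
        intercept=float(res.params["const"]),
        intercept_se=float(res.bse["const"]),
        effects=effects,
        std_errors=std_errors,
        pvalues=pvalues,
        significance=stars,
        residuals=np.asarray(res.resid, dtype=float),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        term_means={t: float(X[t].mean()) for t in terms},
        outcome_mean=float(y.mean()),
        nobs=n,
        cov_type=cov_type,
        dropped=design.dropped,
        term_kinds=dict(design.terms),
    )
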