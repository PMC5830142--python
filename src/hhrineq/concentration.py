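"""Concentration index and concentration curve.

The concentration index of a nonnegative health variable h against a
living-standards ranking is

    C = (2 / mu) * cov(h, r),

with mu the mean of h and r the fractional rank.  C is dimensionless,
bounded in [-1, 1] for nonnegative h, zero under perfect equality, and
positive when h is concentrated among richer units (pro-rich).  The
covariance is the population (1/N) covariance throughout the package; this
keeps the decomposition identity exact.

The generalized concentration index GC = 2*cov(u, r) omits the division by
the variable's own mean and is therefore defined for sign-changing
variables such as regression residuals.

Standard errors: the point estimate is distribution-free, but its sampling
variance is not; two estimators are provided.  The "convenient regression"
regresses (2*var(r)/mu)*h_i on r_i — the OLS slope is algebraically equal
to C and its heteroskedasticity-robust standard error is a standard SE for
C.  The bootstrap resamples units with replacement and re-ranks each draw.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DomainError, ValidationError
from .ranks import RankedVariable, fractional_rank

__all__ = [
    "ConcentrationResult",
    "CurvePoints",
    "ConcentrationModel",
    "concentration_index",
    "generalized_concentration_index",
    "concentration_index_se",
    "concentration_curve",
    "curve_position",
]


@dataclass(frozen=True)
class ConcentrationResult:
    """Concentration index with (optionally) its uncertainty.

    ``se`` and the interval bounds are ``None`` until filled by an SE
    method; ``method`` records the rank convention, ``se_method`` the SE
    estimator.
    """

    c: float
    mu: float
    n: int
    se: float | None = None
    ci95_low: float | None = None
    ci95_high: float | None = None
    method: str = "midpoint"
    se_method: str | None = None

    def summary(self) -> str:
        lines = [
            "Concentration index",
            "-" * 43,
            f"C        {self.c: .6f}",
            f"mean     {self.mu: .6f}",
            f"n        {self.n:d}",
            f"ranks    {self.method}",
        ]
        if self.se is not None:
            lines += [
                f"SE       {self.se: .6f}   ({self.se_method})",
                f"95% CI   ({self.ci95_low: .6f}, {self.ci95_high: .6f})",
            ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "c": self.c,
            "mu": self.mu,
            "n": self.n,
            "se": self.se,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "rank_method": self.method,
            "se_method": self.se_method,
        }


@dataclass(frozen=True)
class CurvePoints:
    """Knots of a concentration curve.

    ``cum_pop_share[k]`` is the cumulative population share of the k
    poorest units; ``cum_health_share[k]`` the cumulative share of the
    health variable they hold.  Starts at (0, 0), ends at (1, 1).
    """

    cum_pop_share: np.ndarray
    cum_health_share: np.ndarray

    def __post_init__(self) -> None:
        x, y = self.cum_pop_share, self.cum_health_share
        if x.shape != y.shape:
            raise ValidationError("curve coordinate arrays differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cum_pop_share": self.cum_pop_share,
                "cum_health_share": self.cum_health_share,
            }
        )

    def area_index(self) -> float:
        """Concentration index implied by the curve: twice the signed area
        between the diagonal and the curve (trapezoid rule).  Agrees with
        the covariance formula up to O(1/N); useful as an independent
        cross-check."""
        area = np.trapezoid(self.cum_health_share, self.cum_pop_share)
        return float(1.0 - 2.0 * area)


def _pop_cov(a: np.ndarray, b: np.ndarray) -> float:
    """Population (1/N) covariance."""
    return float(np.mean((a - a.mean()) * (b - b.mean())))


def _check_lengths(h: np.ndarray, ranked: RankedVariable) -> None:
    if h.shape[0] != ranked.n:
        raise ValidationError(
            f"length mismatch: {h.shape[0]} values vs {ranked.n} ranks"
        )


def concentration_index(h, ranked: RankedVariable) -> ConcentrationResult:
    """Concentration index C = (2/mu) cov(h, r).

    ``h`` must be nonnegative with strictly positive mean; ``ranked`` are
    the fractional ranks of the living-standards variable for the same
    units, in the same row order.
    """
    h = np.asarray(h, dtype=float)
    _check_lengths(h, ranked)
    mu = float(np.mean(h))
    if mu <= 0.0:
        raise DomainError(f"concentration index requires mean > 0, got {mu}")
    c = 2.0 * _pop_cov(h, ranked.ranks) / mu
    return ConcentrationResult(c=c, mu=mu, n=ranked.n, method=ranked.method)


def generalized_concentration_index(u, ranked: RankedVariable) -> float:
    """Generalized concentration index GC = 2 cov(u, r).

    Not divided by the mean of ``u``; defined for sign-changing inputs
    (regression residuals).  In the decomposition the residual term is
    GC_u divided by the *outcome* mean.
    """
    u = np.asarray(u, dtype=float)
    _check_lengths(u, ranked)
    return 2.0 * _pop_cov(u, ranked.ranks)


def concentration_index_se(
    h,
    ranked: RankedVariable,
    method: str = "convenient_regression",
    n_boot: int = 1000,
    seed: int = 0,
) -> ConcentrationResult:
    """Concentration index with a standard error and 95% interval.

    method="convenient_regression"
        OLS of (2 var(r)/mu) h_i on r_i; the slope equals C exactly and
        its HC1 robust SE is reported.
    method="bootstrap"
        ``n_boot`` resamples of units with replacement; ranks are
        recomputed within each resample; SE is the draw standard
        deviation.

    Both report ci95 = C +/- 1.96 SE.  A degenerate (constant) health
    variable yields C = 0 with SE 0.
    """
    h = np.asarray(h, dtype=float)
    base = concentration_index(h, ranked)

    if np.ptp(h) == 0.0:
        return replace(
            base, se=0.0, ci95_low=base.c, ci95_high=base.c, se_method=method
        )

    if method == "convenient_regression":
        r = ranked.ranks
        lhs = (2.0 * ranked.variance / base.mu) * h
        fit = sm.OLS(lhs, sm.add_constant(r)).fit(cov_type="HC1")
        se = float(fit.bse[1])
    elif method == "bootstrap":
        if n_boot < 100:
            raise ValidationError(f"n_boot must be >= 100, got {n_boot}")
        rng = np.random.default_rng(seed)
        n = ranked.n
        draws = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            rb = fractional_rank(ranked.values[idx], method=ranked.method)
            hb = h[idx]
            mu_b = hb.mean()
            draws[b] = (
                2.0 * _pop_cov(hb, rb.ranks) / mu_b if mu_b > 0 else np.nan
            )
        se = float(np.nanstd(draws, ddof=1))
    else:
        raise ValidationError(
            f"unknown se method {method!r}; use 'convenient_regression' or 'bootstrap'"
        )

    return replace(
        base,
        se=se,
        ci95_low=base.c - 1.96 * se,
        ci95_high=base.c + 1.96 * se,
        se_method=method,
    )


def concentration_curve(h, ranked: RankedVariable) -> CurvePoints:
    """Concentration-curve knots over units sorted by living standard.

    Point k is (k/N, sum of the k smallest-ranked units' h over total h),
    with (0, 0) prepended.  Requires nonnegative h with positive total.
    """
    h = np.asarray(h, dtype=float)
    _check_lengths(h, ranked)
    if np.any(h < 0.0):
        raise ValidationError("concentration curve requires nonnegative values")
    total = h.sum()
    if total <= 0.0:
        raise DomainError("concentration curve requires a positive total")
    hs = h[ranked.order]
    n = ranked.n
    x = np.arange(n + 1, dtype=float) / n
    y = np.concatenate(([0.0], np.cumsum(hs) / total))
    # guard against cumulative rounding at the endpoint
    y[-1] = 1.0
    return CurvePoints(cum_pop_share=x, cum_health_share=y)


def curve_position(curve: CurvePoints, tol: float = 1e-9) -> str:
    """Classify a concentration curve against the equality diagonal.

    Returns ``"coincident"``, ``"above"`` (pro-poor), ``"below"``
    (pro-rich) or ``"crossing"``, judged at the interior knots with
    tolerance ``tol``.
    """
    d = curve.cum_health_share[1:-1] - curve.cum_pop_share[1:-1]
    if d.size == 0 or np.all(np.abs(d) <= tol):
        return "coincident"
    if np.all(d >= -tol):
        return "above"
    if np.all(d <= tol):
        return "below"
    return "crossing"


class ConcentrationModel:
    """Concentration-index model for one health variable.

    statsmodels-style: construct from data, then :meth:`fit` returns a
    :class:`ConcentrationResult`.

    Parameters
    ----------
    health : array-like
        Nonnegative health variable (e.g. doctors per 10,000 people).
    living_standard : array-like
        Ranking variable (e.g. per-capita GDP), same units order.
    rank_method : {"midpoint", "paper"}
    weights : array-like, optional
        Sampling weights for the ranks (midpoint only).
    """

    def __init__(self, health, living_standard, rank_method="midpoint", weights=None):
        self.health = np.asarray(health, dtype=float)
        self.ranked = fractional_rank(living_standard, method=rank_method, weights=weights)
        if self.health.shape[0] != self.ranked.n:
            raise ValidationError("health and living_standard differ in length")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        ranking: str = "pergdp",
        rank_method: str = "midpoint",
        weights: str | None = None,
    ) -> "ConcentrationModel":
        w = data[weights].to_numpy() if weights is not None else None
        return cls(
            data[outcome].to_numpy(),
            data[ranking].to_numpy(),
            rank_method=rank_method,
            weights=w,
        )

    def fit(
        self,
        se_method: str = "convenient_regression",
        n_boot: int = 1000,
        seed: int = 0,
    ) -> ConcentrationResult:
        return concentration_index_se(
            self.health, self.ranked, method=se_method, n_boot=n_boot, seed=seed
        )

    def curve(self) -> CurvePoints:
        return concentration_curve(self.health, self.ranked)
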