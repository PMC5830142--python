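"""Fractional living-standards ranks.

The concentration index ranks units (here: cities) by a living-standards
variable and replaces the variable by its fractional rank r_i in (0, 1].
Two conventions are supported:

``midpoint`` (default)
    r_i = (i - 0.5)/N for the i-th unit in ascending order.  Ranks are
    centred at 1/2, which keeps the index within its +/-1 bounds and is the
    standard convention in the inequality-measurement literature.

``paper``
    r_i = i/N, the convention some applied studies use; retained for
    fidelity when replicating published numbers.

Ties in the ranking variable receive the mean of the ranks they span, so
the result is invariant to the input ordering of tied units.  With
sampling weights (midpoint convention only) the rank is the cumulative
weight up to the unit's midpoint divided by the total weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .exceptions import InsufficientDataError, ValidationError

__all__ = ["RankedVariable", "fractional_rank"]

_METHODS = ("midpoint", "paper")


@dataclass(frozen=True)
class RankedVariable:
    """A ranking variable paired with fractional ranks.

    Attributes
    ----------
    values : ndarray
        The living-standards values, in input row order.
    ranks : ndarray
        Fractional ranks in (0, 1], aligned with ``values``.
    order : ndarray
        Stable permutation sorting units by ``values`` ascending.
    method : str
        Rank convention, ``"midpoint"`` or ``"paper"``.
    weights : ndarray or None
        Sampling weights, if ranks are weighted.
    """

    values: np.ndarray
    ranks: np.ndarray
    order: np.ndarray
    method: str
    weights: np.ndarray | None = field(default=None)

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    def __post_init__(self) -> None:
        if self.values.shape != self.ranks.shape:
            raise ValidationError("values and ranks must have the same length")
        r = self.ranks
        if np.any(r <= 0.0) or np.any(r > 1.0):
            raise ValidationError("fractional ranks must lie in (0, 1]")

    @property
    def variance(self) -> float:
        """Population (1/N) variance of the ranks; enters the convenient
        regression used for standard errors."""
        return float(np.var(self.ranks))


def fractional_rank(
    living_standard,
    method: str = "midpoint",
    weights=None,
) -> RankedVariable:
    """Fractional ranks of a living-standards variable.

    Parameters
    ----------
    living_standard : array-like
        One value per unit (e.g. per-capita GDP per city).
    method : {"midpoint", "paper"}
        ``midpoint`` gives (i - 0.5)/N, ``paper`` gives i/N.
    weights : array-like, optional
        Positive sampling weights; only defined for ``midpoint``.

    Returns
    -------
    RankedVariable
        Ranks aligned with the input order.
    """
    x = np.asarray(living_standard, dtype=float)
    if x.ndim != 1:
        raise ValidationError("living_standard must be one-dimensional")
    n = x.shape[0]
    if n < 2:
        raise InsufficientDataError(
            f"need at least 2 units to rank, got {n}"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError("living_standard contains non-finite values")
    if method not in _METHODS:
        raise ValidationError(f"unknown rank method {method!r}; use one of {_METHODS}")

    order = np.argsort(x, kind="stable")

    if weights is None:
        # average positional rank handles ties (mean of spanned positions)
        avg_pos = rankdata(x, method="average")
        if method == "paper":
            ranks = avg_pos / n
        else:
            ranks = (avg_pos - 0.5) / n
        return RankedVariable(values=x, ranks=ranks, order=order, method=method)

    w = np.asarray(weights, dtype=float)
    if w.shape != x.shape:
        raise ValidationError("weights must have the same length as living_standard")
    if np.any(~np.isfinite(w)) or np.any(w <= 0.0):
        raise ValidationError("weights must be positive and finite")
    if method != "midpoint":
        raise ValidationError("weighted ranks are only defined for method='midpoint'")

    # weighted midpoint rank, tied values share the midpoint of their block
    xs = x[order]
    ws = w[order]
    total = ws.sum()
    ranks_sorted = np.empty(n, dtype=float)
    cum = 0.0
    i = 0
    while i < n:
        j = i
        block = 0.0
        while j < n and xs[j] == xs[i]:
            block += ws[j]
            j += 1
        ranks_sorted[i:j] = (cum + 0.5 * block) / total
        cum += block
        i = j
    ranks = np.empty(n, dtype=float)
    ranks[order] = ranks_sorted
    return RankedVariable(values=x, ranks=ranks, order=order, method=method, weights=w)
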