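"""Concentration-curve figures.

A concentration curve is plotted against the 45-degree equality line; a
curve below the diagonal signals pro-rich concentration of the health
variable, above the diagonal pro-poor.
"""

from __future__ import annotations

from collections.abc import Mapping

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .concentration import CurvePoints  # noqa: E402

__all__ = ["plot_concentration_curve"]


def plot_concentration_curve(
    curves: CurvePoints | Mapping[str, CurvePoints],
    path=None,
    ax=None,
    title: str | None = None,
):
    """Draw one or more concentration curves with the equality line.

    Parameters
    ----------
    curves : CurvePoints or mapping label -> CurvePoints
    path : path-like, optional
        If given, the figure is saved (PNG/SVG by extension).
    ax : matplotlib Axes, optional
        Draw into an existing axes instead of a new figure.

    Returns
    -------
    matplotlib.axes.Axes
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], color="tab:brown", lw=1.2, label="line of equality")
    if isinstance(curves, CurvePoints):
        curves = {"concentration curve": curves}
    for label, curve in curves.items():
        ax.plot(
            curve.cum_pop_share,
            curve.cum_health_share,
            lw=1.6,
            label=label,
        )
    ax.set_xlabel("cumulative population share (ranked by living standards)")
    ax.set_ylabel("cumulative health-variable share")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_aspect("equal")
    ax.legend(loc="upper left", frameon=False, fontsize=8)
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
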