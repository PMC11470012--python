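"""Complementary-cumulative-frequency plots of dancefloor data and fits.

The recruitment "hump" at short durations shows up as a shoulder in
``1 - F(x)`` on a log scale, which is why these plots (rather than
histograms) are the standard diagnostic for scout/recruit mixtures.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike

from .distributions import MixtureParams, mixture_cdf

__all__ = ["plot_ccdf"]


def plot_ccdf(
    durations: ArrayLike,
    params: MixtureParams | None = None,
    ax=None,
    log_y: bool = True,
    label: str | None = None,
    **line_kwargs,
):
    """Plot the empirical complementary CDF, optionally with a fitted curve.

    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    x = np.sort(np.asarray(durations, dtype=float))
    ccdf = 1.0 - np.arange(1, x.size + 1) / x.size
    if ax is None:
        _, ax = plt.subplots()
    ax.step(x, ccdf, where="post", label=label or "data")
    if params is not None:
        grid = np.linspace(x[0], x[-1], 400)
        ax.plot(grid, 1.0 - mixture_cdf(grid, params), label="fitted model", **line_kwargs)
    if log_y:
        ax.set_yscale("log")
    ax.set_xlabel("waggle-run duration (s)")
    ax.set_ylabel("complementary cumulative frequency")
    ax.legend()
    return ax
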