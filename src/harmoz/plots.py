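"""Optional matplotlib figures: age-trend scatter with CI band, and
per-group kernel density estimates of Z. Purely presentational."""

from __future__ import annotations

import numpy as np

from .evaluation import AgeTrend, kdef

__all__ = ["plot_age_trend", "plot_group_kdefs"]


def plot_age_trend(trend: AgeTrend, ages=None, log10_volumes=None, ax=None, title=None):
    """Regression line with pointwise 95% CI band; optional raw scatter."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if ages is not None and log10_volumes is not None:
        ax.scatter(ages, log10_volumes, s=8, alpha=0.4, color="gray")
    ax.plot(trend.ages, trend.fitted, color="tab:blue", label="regression")
    ax.plot(trend.ages, trend.ci_low, color="tab:red", lw=0.8, label="95% CI")
    ax.plot(trend.ages, trend.ci_high, color="tab:green", lw=0.8)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("log10 volume (mm³)")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax


def plot_group_kdefs(z_by_group: dict[str, np.ndarray], ax=None, title=None):
    """Kernel density estimate of the Z-score per diagnostic group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, z in z_by_group.items():
        grid, dens = kdef(np.asarray(z))
        ax.plot(grid, dens, label=label)
    ax.axvline(-2.0, color="k", ls="--", lw=0.8)
    ax.set_xlabel("harmonized Z")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax
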