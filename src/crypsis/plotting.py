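"""Plots for PSR curves and PLSR component scores."""

from __future__ import annotations

import numpy as np

from crypsis.phylo_eigen import PSRCurve


def plot_psr_curve(curves: dict[str, PSRCurve], ax=None):
    """PSR curves against the 1:1 Brownian-motion line.

    ``curves`` maps trait names to PSRCurve objects; returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        x = np.concatenate([[0.0], curve.cum_eigenvalue_fraction])
        y = np.concatenate([[0.0], curve.r_squared])
        ax.plot(x, y, marker="o", ms=3, label=f"{name} ({curve.mean_deviation:+.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="Brownian motion")
    ax.set_xlabel("cumulative relative eigenvalue")
    ax.set_ylabel("sequential $R^2$")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    return ax


def plot_component_scores(results, response_index: int = 0, ax=None):
    """First-component predictor scores against the synthetic response."""
    import matplotlib.pyplot as plt

    if results.fit_ is None:
        raise ValueError("no retained component to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    t1 = results.fit_.T[:, 0]
    u1 = results.model.Y @ results.fit_.C[:, 0]
    ax.scatter(t1, u1, s=8, alpha=0.6)
    b = float(t1 @ u1) / float(t1 @ t1)
    xs = np.linspace(t1.min(), t1.max(), 2)
    ax.plot(xs, b * xs, "k-", lw=1)
    ax.set_xlabel("PLSR component 1 score")
    ax.set_ylabel("synthetic response score")
    return ax
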