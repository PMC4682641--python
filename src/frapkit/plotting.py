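"""Plotting helpers for recovery fits and cohort boxplots."""

from __future__ import annotations

import numpy as np

from .cohort import BoxSummary


def plot_recovery(results, ax=None, label=None):
    """Recovery data points with the fitted curve, half-time marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = results.model.times
    ax.plot(t, results.model.values, "k.", ms=3, alpha=0.6)
    tt = np.linspace(0, t[-1], 400)
    ax.plot(tt, results.predict(tt), "-", label=label or f"{results.n_components}-component fit")
    th = results.t_half
    ax.axvline(th, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("time after bleach (s)")
    ax.set_ylabel("normalized intensity")
    ax.legend()
    return ax


def plot_box_summaries(summaries: dict, ax=None, ylabel=None):
    """Boxplot from precomputed BoxSummary objects (median, IQR box,
    1.5 x IQR whiskers, outliers as points)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = list(summaries)
    stats = []
    for name in labels:
        s: BoxSummary = summaries[name]
        stats.append(
            {
                "med": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "whislo": s.whisker_low,
                "whishi": s.whisker_high,
                "fliers": np.asarray(s.outliers),
                "label": name,
            }
        )
    ax.bxp(stats, showfliers=True)
    if ylabel:
        ax.set_ylabel(ylabel)
    return ax
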