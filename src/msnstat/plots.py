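"""Result figures: stacked status fractions and the concordance trade-off curve."""

from __future__ import annotations

import pandas as pd

CATEGORY_ORDER = ["tp", "fp", "tn", "fn", "unknown"]
CATEGORY_COLORS = {
    "tp": "#2b7bba",
    "fp": "#9ecae1",
    "tn": "#31a354",
    "fn": "#de2d26",
    "unknown": "#bdbdbd",
}


def plot_simulation_fractions(summary: pd.DataFrame, path=None):
    """Stacked bars of status-category fractions per method, one panel per
    scenario; ``summary`` is the output of ``summarize_scenarios``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scenarios = list(dict.fromkeys(summary["scenario"]))
    fig, axes = plt.subplots(len(scenarios), 1, figsize=(7, 2.2 * len(scenarios)), squeeze=False)
    for ax, scen in zip(axes.ravel(), scenarios):
        sub = summary[summary["scenario"] == scen]
        labels = [
            f"{m.upper()} {t:g}" for m, t in dict.fromkeys(zip(sub["method"], sub["threshold"]))
        ]
        bottom = None
        wide = sub.pivot_table(
            index=["method", "threshold"], columns="category", values="fraction", sort=False
        )
        for cat in CATEGORY_ORDER:
            if cat not in wide.columns:
                continue
            vals = wide[cat].to_numpy()
            ax.bar(labels, vals, bottom=bottom, label=cat.upper() if cat != "unknown" else "Unknown",
                   color=CATEGORY_COLORS[cat])
            bottom = vals if bottom is None else bottom + vals
        ax.set_ylabel("fraction of statuses")
        ax.set_title(scen)
        ax.set_ylim(0, 1)
    axes.ravel()[0].legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_concordance_curve(results: pd.DataFrame, path=None):
    """Informative data points vs. concordance, one dot per method setting;
    ``results`` is a dual-evaluation result table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for method, marker in (("umc", "o"), ("msn", "s")):
        sub = results[results["method"] == method]
        if sub.empty:
            continue
        ax.plot(sub["concordance_pct"], sub["informative_points"], marker=marker,
                linestyle="-", label=method.upper())
        for _, row in sub.iterrows():
            ax.annotate(f"{row['threshold']:g}", (row["concordance_pct"], row["informative_points"]),
                        textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_xlabel("concordance between platforms (%)")
    ax.set_ylabel("informative data points")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
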