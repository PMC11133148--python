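"""Distribution and conditional-median plots of simulated fit indices."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["gof_violins", "median_trace"]


def gof_violins(records: pd.DataFrame, gof: str, by: str, ax=None):
    """Violin plot of one index grouped by a design characteristic.

    The black trace connects the group medians.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    groups = [(k, g[gof].dropna().to_numpy()) for k, g in records.groupby(by, dropna=False)]
    data = [v for _, v in groups if v.size]
    labels = [str(k) for k, v in groups if v.size]
    ax.violinplot(data, showmedians=False, showextrema=False)
    medians = [np.median(v) for v in data]
    ax.plot(range(1, len(data) + 1), medians, color="black", marker="o", lw=1.2)
    ax.set_xticks(range(1, len(data) + 1), labels)
    ax.set_xlabel(by)
    ax.set_ylabel(gof)
    return ax


def median_trace(records: pd.DataFrame, gof: str, x: str = "estimator", hue: str | None = None, ax=None):
    """Medians of one index across estimators, one line per ``hue`` level."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    order = [e for e in ("ML", "MLR", "DWLS", "WLSMV") if e in set(records[x])] or sorted(
        set(records[x])
    )
    if hue is None:
        med = records.groupby(x)[gof].median().reindex(order)
        ax.plot(order, med.to_numpy(), marker="o")
    else:
        for level, g in records.groupby(hue, dropna=False):
            med = g.groupby(x)[gof].median().reindex(order)
            ax.plot(order, med.to_numpy(), marker="o", label=str(level))
        ax.legend(title=hue, fontsize=8)
    ax.set_xlabel(x)
    ax.set_ylabel(f"median {gof}")
    return ax
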