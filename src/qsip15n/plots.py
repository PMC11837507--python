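"""Optional matplotlib summaries of enrichment results (cosmetic).

Zeros are displayed at a configurable floor on log axes; the underlying
data are never altered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def rate_distributions(eaf: pd.DataFrame, metric: str = "eaf", log_floor: float = 1e-4, ax=None):
    """Kernel-density summary of genus-median rates per (site, method), log10 x."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    med = eaf.groupby(["site", "method", "genus"])[metric].median().reset_index()
    for (site, method), grp in med.groupby(["site", "method"]):
        v = np.log10(np.maximum(grp[metric].to_numpy(), log_floor))
        if np.ptp(v) == 0:
            continue
        grid = np.linspace(v.min() - 0.5, v.max() + 0.5, 200)
        ax.plot(grid, gaussian_kde(v)(grid), label=f"{site} {method}")
    ax.set_xlabel(f"log10 {metric}")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    return ax


def method_scatter(medians: pd.DataFrame, fit=None, ax=None):
    """Genus medians, field vs lab, with the 1:1 line and optional PB fit."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    x, y = medians["lab"].to_numpy(), medians["field"].to_numpy()
    ax.scatter(x, y, s=10, alpha=0.6)
    lim = [0, max(x.max(), y.max()) * 1.05]
    ax.plot(lim, lim, "k--", lw=1, label="1:1")
    if fit is not None:
        xs = np.array(lim)
        ax.plot(xs, fit.intercept + fit.slope * xs, "r-", lw=1.5,
                label=f"PB slope {fit.slope:.2f}")
    ax.set_xlabel("lab")
    ax.set_ylabel("field")
    ax.legend(fontsize=8)
    return ax
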