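"""Matplotlib views of the package's result objects.

All functions take/return Axes and never call ``plt.show()``; figures
are the caller's to save.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import DiversityProfile, profiles_to_frame


def plot_correlation_heatmap(values: pd.DataFrame, status: pd.DataFrame,
                             scheme=None, ax=None):
    """Position x substrate heatmap of correlation coefficients.

    ``ok`` cells are colored on a diverging scale over [-1, 1];
    conserved/insufficient cells render neutral (masked), not as 0.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.5 * values.shape[1],
                                      1 + 0.35 * values.shape[0]))
    data = np.ma.masked_invalid(values.to_numpy(dtype=float))
    im = ax.imshow(data, cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(values.shape[1]), values.columns, rotation=90)
    labels = [
        f"{scheme.cluster_of(p)} {p}" if scheme is not None else str(p)
        for p in values.index
    ]
    ax.set_yticks(range(values.shape[0]), labels)
    for i, p in enumerate(values.index):
        for j, s in enumerate(values.columns):
            if status.loc[p, s] == "conserved":
                ax.text(j, i, "·", ha="center", va="center")
    ax.figure.colorbar(im, ax=ax, label="r (property vs log10 activity)")
    return ax


def plot_diversity_profiles(profiles: list[DiversityProfile], clade: str, ax=None):
    """Stacked residue-frequency bars per position for one clade."""
    import matplotlib.pyplot as plt

    frame = profiles_to_frame(profiles)
    frame = frame[frame["clade"] == clade]
    if frame.empty:
        raise ValueError(f"no profiles for clade {clade!r}")
    if ax is None:
        _, ax = plt.subplots()
    pivot = frame.pivot(index="position", columns="residue", values="frequency").fillna(0.0)
    bottom = np.zeros(len(pivot))
    for residue in pivot.columns:
        ax.bar([str(p) for p in pivot.index], pivot[residue], bottom=bottom, label=residue)
        bottom += pivot[residue].to_numpy()
    ax.set_xlabel("template position")
    ax.set_ylabel("residue frequency")
    ax.set_title(f"clade {clade}")
    ax.legend(fontsize="small", ncols=2)
    return ax


def plot_combined_regression(regression, states, scale, logact, ax=None):
    """Scatter of combined property vs log10 activity with the fitted line."""
    import matplotlib.pyplot as plt

    from .profiles import aggregate_property

    if ax is None:
        _, ax = plt.subplots()
    combined = aggregate_property(states, scale, regression.positions, "sum")
    sub = logact[logact["substrate"] == regression.substrate]
    xs, ys, labels = [], [], []
    for _, row in sub.iterrows():
        enzyme = row["enzyme"]
        if enzyme in combined.index and np.isfinite(combined[enzyme]):
            xs.append(combined[enzyme])
            ys.append(row["value"])
            labels.append(enzyme)
    ax.scatter(xs, ys)
    for x, y, lab in zip(xs, ys, labels):
        ax.annotate(lab, (x, y), fontsize="x-small")
    if regression.status == "ok":
        grid = np.linspace(min(xs), max(xs), 50)
        ax.plot(grid, regression.predict(grid),
                label=f"r = {regression.r:.2f}, slope = {regression.slope:.3g}")
        ax.legend()
    ax.set_xlabel(f"combined {scale.name} over positions {list(regression.positions)} ({scale.units})")
    ax.set_ylabel("log10 activity (1/s)")
    return ax
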