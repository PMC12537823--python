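"""Display helpers: annual trend panels and the grid-cell change heatmap.

Plots are presentation-only; every number they draw is computed by the
analysis modules. The change heatmap uses a signed log10 transform so that
order-of-magnitude gains and losses get comparable visual weight.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trends import loess_smooth


def trend_panels(yearly_metrics: pd.DataFrame, loess_span: float = 0.3, ax=None):
    """Line panels of specimen count, unique species and grid extent per year."""
    import matplotlib.pyplot as plt

    metrics = ["specimen_count", "unique_species", "grid_extent"]
    labels = ["Specimens / yr", "Unique species / yr", "1-degree cells / yr"]
    if ax is None:
        _, ax = plt.subplots(1, 3, figsize=(13, 3.6), sharex=True)
    for a, metric, label in zip(ax, metrics, labels):
        series = yearly_metrics[metric].astype(float)
        a.plot(series.index, series, lw=0.8, alpha=0.55, color="grey")
        if len(series) >= 5:
            a.plot(series.index, loess_smooth(series, span=loess_span), lw=1.8)
        a.set_ylabel(label)
        a.set_xlabel("Collection year")
    return ax


def signed_log10(x: np.ndarray) -> np.ndarray:
    """sign(x) * log10(1 + |x|): a symmetric display transform for deltas."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.log10(1.0 + np.abs(x))


def change_heatmap(grid_change: pd.DataFrame, ax=None):
    """Diverging world heatmap of per-cell mean-annual-count change."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 5))
    grid = np.full((180, 360), np.nan)
    rows = (grid_change["lat_index"].to_numpy() + 90).astype(int)
    cols = (grid_change["lon_index"].to_numpy() + 180).astype(int)
    grid[rows, cols] = signed_log10(grid_change["delta"].to_numpy())
    vmax = np.nanmax(np.abs(grid)) if np.isfinite(grid).any() else 1.0
    im = ax.imshow(
        grid,
        origin="lower",
        extent=(-180, 180, -90, 90),
        cmap="RdBu",
        vmin=-vmax,
        vmax=vmax,
        interpolation="nearest",
    )
    ax.set_xlabel("Longitude")
    ax.set_ylabel("Latitude")
    plt.colorbar(im, ax=ax, label="signed log10 change in mean annual count")
    return ax


def forecast_ribbons(forecast_table: pd.DataFrame, observed: pd.Series = None, ax=None):
    """Mean forecast per collection year with its 95% ribbon at one horizon."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    last = forecast_table.groupby("collection_year").tail(1).sort_values("collection_year")
    ax.plot(last["collection_year"], last["mean_floored"], color="black", label="forecast")
    ax.fill_between(
        last["collection_year"],
        np.maximum(last["lower95"], 0),
        last["upper95"],
        color="grey",
        alpha=0.4,
        label="95% interval",
    )
    if observed is not None:
        ax.plot(observed.index, observed, color="firebrick", label="last snapshot")
    ax.set_xlabel("Collection year")
    ax.set_ylabel("Records")
    ax.legend()
    return ax
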