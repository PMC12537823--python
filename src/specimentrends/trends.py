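"""Yearly collecting-trend metrics: counts, species richness, spatial extent.

The three annual series the analysis tracks are (i) the number of specimen
records per collection year, (ii) the number of unique species represented
per year, and (iii) the spatial extent of collecting, measured as the number
of distinct 1-degree latitude-longitude grid cells with at least one record
that year. Peak collecting periods are identified as the maximal w-year
moving average (w = 5 by default, windows labelled by their inclusive year
span), and declines are expressed as the percentage drop of a recent-period
mean relative to that peak. LOESS smooths are display-only and never feed
peaks, declines or forecasts.

The model-style entry point is :class:`CollectingTrendModel`, whose ``fit()``
returns a :class:`TrendResults` carrying the yearly metrics table, the peak
window and the decline percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from . import io as _io

#: Total number of 1-degree cells on the globe.
N_GRID_CELLS = 180 * 360


@dataclass(frozen=True)
class PeakWindow:
    """A w-year window of maximal mean annual count.

    ``end_year`` is inclusive (``end_year = start_year + w - 1``) and
    ``window_mean`` is the arithmetic mean of the zero-filled annual series
    over the window.
    """

    start_year: int
    end_year: int
    window_mean: float

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.start_year}-{self.end_year} (mean {self.window_mean:,.1f}/yr)"


def _zero_filled(series: pd.Series, span: tuple[int, int] | None = None) -> pd.Series:
    """Reindex an annual series onto a contiguous year range, filling gaps with 0."""
    if len(series) == 0 and span is None:
        return series.astype(float)
    lo = span[0] if span else int(series.index.min())
    hi = span[1] if span else int(series.index.max())
    years = pd.RangeIndex(lo, hi + 1, name="year")
    return series.reindex(years, fill_value=0).astype(float)


def yearly_counts(
    records: pd.DataFrame, span: tuple[int, int] | None = None
) -> pd.Series:
    """Number of records per collection year.

    With ``span`` given, years inside the span with no records are reported
    as zero; otherwise only observed years appear.
    """
    counts = records.groupby(records["year"].astype(int)).size()
    counts.index.name = "year"
    if span is not None:
        counts = _zero_filled(counts, span).astype(int)
    return counts.sort_index()


def unique_species_per_year(
    records: pd.DataFrame, span: tuple[int, int] | None = None
) -> pd.Series:
    """Distinct species per collection year (exact string match after trim)."""
    uniq = records.groupby(records["year"].astype(int))["species"].nunique()
    uniq.index.name = "year"
    if span is not None:
        uniq = _zero_filled(uniq, span).astype(int)
    return uniq.sort_index()


def grid_index(latitude, longitude):
    """Map coordinates to 1-degree grid-cell indices.

    Cells are half-open floor cells ``[d, d+1)``; the poles/antimeridian are
    clamped so +90 maps to row 89 and +180 to column 179, giving every valid
    point exactly one of the 64,800 cells. Accepts scalars or arrays.
    """
    lat = np.asarray(latitude, dtype=float)
    lon = np.asarray(longitude, dtype=float)
    if np.any((lat < -90) | (lat > 90)) or np.any((lon < -180) | (lon > 180)):
        raise DataError("coordinates outside [-90, 90] x [-180, 180]")
    lat_idx = np.clip(np.floor(lat), -90, 89).astype(int)
    lon_idx = np.clip(np.floor(lon), -180, 179).astype(int)
    if lat_idx.ndim == 0:
        return int(lat_idx), int(lon_idx)
    return lat_idx, lon_idx


def spatial_extent_per_year(
    records: pd.DataFrame, span: tuple[int, int] | None = None
) -> pd.Series:
    """Number of distinct occupied 1-degree cells per collection year.

    Expects spatially filtered records (coordinates present and in range).
    """
    if len(records) == 0:
        return _zero_filled(pd.Series(dtype=int), span).astype(int)
    lat_idx, lon_idx = grid_index(
        records["latitude"].to_numpy(), records["longitude"].to_numpy()
    )
    cells = pd.DataFrame(
        {"year": records["year"].astype(int).to_numpy(), "lat": lat_idx, "lon": lon_idx}
    )
    extent = cells.drop_duplicates().groupby("year").size()
    extent.index.name = "year"
    if span is not None:
        extent = _zero_filled(extent, span).astype(int)
    return extent.sort_index()


def moving_average(series: pd.Series, w: int = 5) -> pd.DataFrame:
    """All w-year moving-average windows of a zero-filled annual series.

    Returns one row per fully covered window with columns ``start_year``,
    ``end_year`` (inclusive) and ``window_mean``. A series shorter than ``w``
    yields an empty frame.
    """
    if w < 1:
        raise ConfigurationError(f"window length must be >= 1, got {w}")
    filled = _zero_filled(series)
    if len(filled) < w:
        return pd.DataFrame(columns=["start_year", "end_year", "window_mean"])
    means = filled.rolling(w).mean().dropna()
    start = means.index.to_numpy() - (w - 1)
    return pd.DataFrame(
        {
            "start_year": start.astype(int),
            "end_year": means.index.to_numpy().astype(int),
            "window_mean": means.to_numpy(),
        }
    ).reset_index(drop=True)


def find_peak_window(series: pd.Series, w: int = 5) -> PeakWindow:
    """The w-year window with the maximal mean; ties go to the earliest window."""
    windows = moving_average(series, w)
    if len(windows) == 0:
        raise DataError(f"series too short for a {w}-year window")
    best = windows.loc[windows["window_mean"].idxmax()]  # idxmax: first maximum
    return PeakWindow(int(best.start_year), int(best.end_year), float(best.window_mean))


def period_mean(series: pd.Series, start_year: int, end_year: int) -> float:
    """Mean annual count over an inclusive year span, missing years as zero."""
    if start_year > end_year:
        raise ConfigurationError("start_year must not exceed end_year")
    years = range(start_year, end_year + 1)
    vals = series.reindex(years, fill_value=0).astype(float)
    return float(vals.mean())


def decline_percent(recent_mean: float, peak_mean: float) -> float:
    """Percentage reduction of a recent mean relative to a peak mean.

    ``100 * (1 - recent_mean / peak_mean)``; negative values indicate growth.
    Returned unrounded so that ``decline_percent(a, b) + 100*a/b == 100``
    holds exactly; report to one decimal place.
    """
    if peak_mean <= 0:
        raise DataError(f"peak mean must be positive, got {peak_mean}")
    return 100.0 * (1.0 - recent_mean / peak_mean)


def grid_change_map(
    records: pd.DataFrame,
    recent_period: tuple[int, int] = (2010, 2019),
    reference_period: tuple[int, int] = (1970, 2009),
) -> pd.DataFrame:
    """Per-cell change in mean annual specimen count between two periods.

    For every 1-degree cell occupied in either period, computes the mean
    annual count over the recent period and over the reference period
    (dividing by the full period length in years, so years without records
    count as zeros) and their difference ``delta = mean_recent -
    mean_reference``. Cells unoccupied in both periods are omitted.
    """
    r0, r1 = recent_period
    f0, f1 = reference_period
    if r0 > r1 or f0 > f1:
        raise ConfigurationError("period start must not exceed period end")
    if max(r0, f0) <= min(r1, f1):
        raise ConfigurationError(
            f"recent {recent_period} and reference {reference_period} periods overlap"
        )
    lat_idx, lon_idx = grid_index(
        records["latitude"].to_numpy(), records["longitude"].to_numpy()
    )
    df = pd.DataFrame(
        {
            "lat_index": lat_idx,
            "lon_index": lon_idx,
            "year": records["year"].astype(int).to_numpy(),
        }
    )
    recent = df[df["year"].between(r0, r1)].groupby(["lat_index", "lon_index"]).size()
    refer = df[df["year"].between(f0, f1)].groupby(["lat_index", "lon_index"]).size()
    cells = recent.index.union(refer.index)
    out = pd.DataFrame(index=cells)
    out["mean_recent"] = recent.reindex(cells, fill_value=0) / (r1 - r0 + 1)
    out["mean_reference"] = refer.reindex(cells, fill_value=0) / (f1 - f0 + 1)
    out["delta"] = out["mean_recent"] - out["mean_reference"]
    return out.reset_index()


def loess_smooth(
    series: pd.Series, span: float = 0.3, degree: int = 2
) -> pd.Series:
    """Locally weighted polynomial (LOESS) smooth of an annual series.

    Tricube-weighted least squares of the given local ``degree`` fitted at
    each observed year over the nearest ``ceil(span * n)`` points. Intended
    for display only — peaks, declines and forecasts are computed on the raw
    series.
    """
    if not 0 < span <= 1:
        raise ConfigurationError(f"span must be in (0, 1], got {span}")
    if len(series) < 5:
        raise DataError("loess_smooth needs at least 5 points")
    x = series.index.to_numpy(dtype=float)
    y = series.to_numpy(dtype=float)
    n = len(x)
    k = max(int(np.ceil(span * n)), degree + 1)
    k = min(k, n)
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = y[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 1e-12, None)
        coeffs = np.polyfit(x[idx] - x[i], y[idx], deg=degree, w=np.sqrt(w))
        fitted[i] = coeffs[-1]
    return pd.Series(fitted, index=series.index, name=series.name)


def compute_yearly_metrics(
    records: pd.DataFrame, span: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Tidy per-year table of specimen_count, unique_species and grid_extent.

    ``records`` must already be validity-filtered; the spatial-extent column
    uses the spatially filtered subset internally.
    """
    counts = yearly_counts(records, span)
    species = unique_species_per_year(records, span)
    extent = spatial_extent_per_year(_io.filter_spatial(records), span)
    out = pd.DataFrame(
        {
            "specimen_count": counts,
            "unique_species": species,
            "grid_extent": extent,
        }
    ).fillna(0)
    out.index.name = "year"
    return out.astype(int)


class CollectingTrendModel:
    """Trend analysis of a validity-filtered occurrence table.

    Parameters
    ----------
    records
        Canonical occurrence DataFrame (see :mod:`specimentrends.io`),
        already validity-filtered.
    span
        Analysis year span, inclusive; defaults to the focal period
        1950-2019.
    """

    def __init__(self, records: pd.DataFrame, span: tuple[int, int] = (1950, 2019)):
        self.records = records
        self.span = span

    @classmethod
    def from_dataframe(cls, records, span=(1950, 2019)) -> "CollectingTrendModel":
        return cls(records, span)

    def fit(
        self,
        window: int = 5,
        recent_period: tuple[int, int] = (2010, 2019),
        reference_period: tuple[int, int] = (1970, 2009),
    ) -> "TrendResults":
        """Compute yearly metrics, the peak window and the decline percentage."""
        in_span = self.records[
            self.records["year"].astype(int).between(*self.span)
        ]
        metrics = compute_yearly_metrics(in_span, self.span)
        counts = metrics["specimen_count"]
        peak = find_peak_window(counts, window)
        recent = period_mean(counts, *recent_period)
        decline = decline_percent(recent, peak.window_mean)
        return TrendResults(
            model=self,
            yearly_metrics=metrics,
            peak_window=peak,
            recent_period=recent_period,
            recent_mean=recent,
            decline=decline,
            reference_period=reference_period,
        )


@dataclass
class TrendResults:
    """Results of :meth:`CollectingTrendModel.fit`."""

    model: CollectingTrendModel
    yearly_metrics: pd.DataFrame
    peak_window: PeakWindow
    recent_period: tuple[int, int]
    recent_mean: float
    decline: float
    reference_period: tuple[int, int]

    def grid_change_map(self) -> pd.DataFrame:
        spatial = _io.filter_spatial(self.model.records)
        return grid_change_map(spatial, self.recent_period, self.reference_period)

    def loess(self, metric: str = "specimen_count", span: float = 0.3) -> pd.Series:
        return loess_smooth(self.yearly_metrics[metric].astype(float), span=span)

    def summary(self) -> str:
        m = self.yearly_metrics
        lines = [
            "Collecting trend summary",
            "=" * 24,
            f"analysis span          {self.model.span[0]}-{self.model.span[1]}",
            f"records in span        {int(m['specimen_count'].sum()):,}",
            f"peak {self.peak_window.end_year - self.peak_window.start_year + 1}-year window      "
            f"{self.peak_window.start_year}-{self.peak_window.end_year}",
            f"peak window mean       {self.peak_window.window_mean:,.1f} specimens/yr",
            f"recent period          {self.recent_period[0]}-{self.recent_period[1]}",
            f"recent mean            {self.recent_mean:,.1f} specimens/yr",
            f"decline vs peak        {self.decline:.1f}%",
        ]
        return "\n".join(lines)
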