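"""Per-collection-year ARIMA forecasting of database-snapshot accrual.

Aggregated occurrence databases lack accession dates, so the timeline from
field collection to database appearance is observed only indirectly: across
successive historical snapshots of the database, the record count for a
fixed collection year grows as institutions digitise backlogs and join the
aggregator (and occasionally shrinks when records are withdrawn). Each
collection year therefore yields a short time series of counts indexed by
snapshot time, and an ARIMA(p, d, q) model fitted to that series forecasts
how the year's count will evolve.

Following standard practice for short annual series, differencing is fixed
(d = 1 by default, selected by RMSPE validation; no seasonal differencing)
and the AR and MA orders are chosen by exhaustive search over a capped grid
(p, q <= 2 by default), minimising the small-sample corrected Akaike
criterion AICc. Prediction intervals are normal-theory 95% bands. Estimation
is delegated to :class:`statsmodels.tsa.arima.model.ARIMA`; order selection,
AICc and validation are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.arima.model import ARIMA

from .errors import ConfigurationError, DataError

#: Two-sided 95% normal quantile used for prediction intervals.
Z95 = 1.959964


@dataclass
class SnapshotSeries:
    """Record counts for one collection year across database snapshots."""

    collection_year: int
    times: np.ndarray  # strictly increasing snapshot years
    counts: np.ndarray  # aligned counts; may decrease (record withdrawals)
    interpolated: np.ndarray = field(default=None)  # mask of imputed points

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.times), dtype=bool)
        if np.any(np.diff(self.times) <= 0):
            raise DataError("snapshot times must be strictly increasing")
        if len(self.times) != len(self.counts):
            raise DataError("times and counts must be aligned")


@dataclass(frozen=True)
class ArimaSpec:
    """Non-seasonal ARIMA order; seasonal differencing is always zero."""

    p: int
    d: int
    q: int

    @property
    def order(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)


def build_snapshot_series(
    observations: pd.DataFrame,
    collection_year_range: tuple[int, int] = (1950, 2019),
) -> dict[int, SnapshotSeries]:
    """Aggregate snapshot observations into one series per collection year.

    Institutions are summed within each (snapshot, collection year). The
    snapshot grid is the union of observed snapshot times; a collection
    year's missing snapshots are imputed as zero before its first non-zero
    observation (the year had not yet appeared in the database), linearly
    interpolated between observations, and held at the last observed value
    after the final observation. Imputed points are marked in the series'
    ``interpolated`` mask.
    """
    y0, y1 = collection_year_range
    if y0 > y1:
        raise ConfigurationError("empty collection-year range")
    times = np.sort(observations["snapshot_time"].unique())
    if len(times) < 2:
        raise DataError("need observations from at least two snapshots")
    totals = (
        observations.groupby(["collection_year", "snapshot_time"])["count"]
        .sum()
        .unstack("snapshot_time")
        .reindex(columns=times)
    )
    series: dict[int, SnapshotSeries] = {}
    for year in range(y0, y1 + 1):
        if year not in totals.index:
            continue
        row = totals.loc[year]
        observed = row.notna().to_numpy()
        vals = row.to_numpy(dtype=float)
        nonzero = np.flatnonzero(observed & (vals > 0))
        first = nonzero[0] if len(nonzero) else len(vals)
        filled = pd.Series(vals).copy()
        filled.iloc[:first] = filled.iloc[:first].fillna(0.0)
        filled = filled.interpolate(method="linear", limit_area="inside")
        filled = filled.ffill().fillna(0.0)
        series[year] = SnapshotSeries(
            collection_year=year,
            times=times,
            counts=filled.to_numpy(),
            interpolated=~observed,
        )
    return series


def aicc(log_likelihood: float, n_params: int, n_obs: int) -> float:
    """Small-sample corrected Akaike information criterion.

    ``-2 llf + 2 k + 2 k (k + 1) / (n - k - 1)``. Returns NaN (an undefined
    marker, excluded from model selection) when ``n_obs <= n_params + 1``.
    """
    if n_obs <= n_params + 1:
        return float("nan")
    k = n_params
    return -2.0 * log_likelihood + 2 * k + 2 * k * (k + 1) / (n_obs - k - 1)


@dataclass
class ArimaFit:
    """A fitted per-collection-year ARIMA model."""

    spec: ArimaSpec
    aicc: float
    result: object  # statsmodels ARIMAResults
    series: SnapshotSeries
    fallback: bool = False  # True when no grid candidate converged


def _try_fit(y: np.ndarray, spec: ArimaSpec):
    """Fit one candidate order; return (result, aicc) or None on failure."""
    trend = "c" if spec.d == 0 else "n"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ARIMA(y, order=spec.order, trend=trend)
            res = model.fit()
    except Exception:
        return None
    if not (np.all(np.isfinite(res.params)) and np.isfinite(res.llf)):
        return None
    value = aicc(res.llf, len(res.params), len(y) - spec.d)
    if not np.isfinite(value):
        return None
    return res, value


def fit_arima(
    series: SnapshotSeries,
    d: int = 1,
    max_p: int = 2,
    max_q: int = 2,
    orders: list[tuple[int, int, int]] | None = None,
) -> ArimaFit:
    """Fit an ARIMA model, selecting (p, q) by exhaustive AICc grid search.

    All candidates with ``p <= max_p`` and ``q <= max_q`` at the fixed ``d``
    are estimated by maximum likelihood; the converged candidate with the
    smallest AICc wins (ties break toward fewer parameters, then lower p).
    Passing explicit ``orders`` restricts the candidate set. If nothing
    converges, falls back to ARIMA(0, d, 0) with a warning.
    """
    y = series.counts
    if len(y) < d + 3:
        raise DataError(
            f"series for {series.collection_year} too short "
            f"({len(y)} points) for d={d}"
        )
    if orders is None:
        candidates = [
            ArimaSpec(p, d, q) for p in range(max_p + 1) for q in range(max_q + 1)
        ]
    else:
        candidates = [ArimaSpec(*o) for o in orders]
    candidates.sort(key=lambda s: (s.p + s.q, s.p, s.q))
    best = None
    for spec in candidates:
        fit = _try_fit(y, spec)
        if fit is None:
            continue
        res, value = fit
        if best is None or value < best.aicc - 1e-12:
            best = ArimaFit(spec=spec, aicc=value, result=res, series=series)
    if best is not None:
        return best
    warnings.warn(
        f"no ARIMA candidate converged for collection year "
        f"{series.collection_year}; falling back to (0,{d},0)"
    )
    spec = ArimaSpec(0, d, 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = ARIMA(y, order=spec.order, trend="n" if d else "c").fit()
    value = aicc(res.llf, len(res.params), len(y) - d)
    return ArimaFit(spec=spec, aicc=value, result=res, series=series, fallback=True)


@dataclass
class ForecastResult:
    """Mean forecast and 95% interval per horizon for one collection year."""

    collection_year: int
    times: np.ndarray  # forecast snapshot times
    mean: np.ndarray
    se: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    spec: ArimaSpec
    aicc: float

    @property
    def mean_floored(self) -> np.ndarray:
        """Display values with negative means floored at zero."""
        return np.maximum(self.mean, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "collection_year": self.collection_year,
                "horizon_time": self.times,
                "mean": self.mean,
                "mean_floored": self.mean_floored,
                "lower95": self.lower95,
                "upper95": self.upper95,
                "p": self.spec.p,
                "d": self.spec.d,
                "q": self.spec.q,
                "aicc": self.aicc,
            }
        )


def forecast(fit: ArimaFit, h: int) -> ForecastResult:
    """Forecast ``h`` steps ahead with normal-theory 95% intervals.

    Negative means are reported as computed; ``mean_floored`` provides the
    zero-floored display values.
    """
    if h < 1:
        raise ConfigurationError(f"horizon must be >= 1, got {h}")
    pred = fit.result.get_forecast(h)
    mean = np.asarray(pred.predicted_mean, dtype=float)
    se = np.asarray(pred.se_mean, dtype=float)
    step = int(np.median(np.diff(fit.series.times))) if len(fit.series.times) > 1 else 1
    start = fit.series.times[-1]
    times = start + step * np.arange(1, h + 1)
    return ForecastResult(
        collection_year=fit.series.collection_year,
        times=times,
        mean=mean,
        se=se,
        lower95=mean - Z95 * se,
        upper95=mean + Z95 * se,
        spec=fit.spec,
        aicc=fit.aicc,
    )


def rmspe(observed, predicted) -> float:
    """Root mean squared prediction error between two aligned vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise DataError("observed and predicted must be non-empty and aligned")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


@dataclass
class ValidationReport:
    """Per-differencing-order RMSPE over held-out snapshots."""

    table: pd.DataFrame  # columns: d, horizon, rmspe, n_series
    winning_d: int
    n_skipped: int

    def summary(self) -> str:
        lines = ["In-sample forecast validation", "=" * 29]
        lines.append(self.table.to_string(index=False))
        lines.append(f"winning d (lowest mean RMSPE): {self.winning_d}")
        if self.n_skipped:
            lines.append(f"series skipped (too short): {self.n_skipped}")
        return "\n".join(lines)


def validate_in_sample(
    series_map: dict[int, SnapshotSeries],
    train_cutoff: int,
    horizons: list[int],
    d_options: tuple[int, ...] = (0, 1, 2),
    max_p: int = 2,
    max_q: int = 2,
) -> ValidationReport:
    """Compare differencing orders by held-out forecast error.

    For each candidate ``d``, per-collection-year models are fitted on the
    snapshots up to ``train_cutoff`` (inclusive) and used to forecast the
    snapshots ``horizon`` years ahead of the cutoff; RMSPE is pooled across
    collection years per horizon. The winning ``d`` minimises the mean RMSPE
    across horizons. The cutoff is always explicit — with so few snapshots
    the train/test split materially changes the answer.
    """
    if not horizons:
        raise ConfigurationError("at least one validation horizon required")
    rows = []
    n_skipped = 0
    errors: dict[tuple[int, int], list[float]] = {
        (d, h): [] for d in d_options for h in horizons
    }
    for year, series in sorted(series_map.items()):
        train_mask = series.times <= train_cutoff
        n_train = int(train_mask.sum())
        if n_train < 4:
            n_skipped += 1
            continue
        train = SnapshotSeries(
            collection_year=year,
            times=series.times[train_mask],
            counts=series.counts[train_mask],
        )
        time_index = {t: i for i, t in enumerate(series.times)}
        max_h = max(horizons)
        for d in d_options:
            if len(train.counts) < d + 3:
                continue
            fit = fit_arima(train, d=d, max_p=max_p, max_q=max_q)
            fc = forecast(fit, max_h)
            for h in horizons:
                target = train_cutoff + h
                if target not in time_index:
                    continue
                obs = series.counts[time_index[target]]
                pred = fc.mean[h - 1]
                errors[(d, h)].append((obs - pred) ** 2)
    for (d, h), sq in sorted(errors.items()):
        rows.append(
            {
                "d": d,
                "horizon": h,
                "rmspe": float(np.sqrt(np.mean(sq))) if sq else float("nan"),
                "n_series": len(sq),
            }
        )
    table = pd.DataFrame(rows)
    mean_by_d = table.groupby("d")["rmspe"].mean()
    winning_d = int(mean_by_d.idxmin())
    return ValidationReport(table=table, winning_d=winning_d, n_skipped=n_skipped)


def forecast_decline(
    forecasts: dict[int, ForecastResult],
    peak_window,
    recent_period: tuple[int, int],
    horizon_time: int,
) -> float:
    """Projected decline percentage at a future snapshot time.

    Averages the forecast mean counts at ``horizon_time`` over the recent
    collection years and over the peak-window collection years, and returns
    ``decline_percent(recent, peak)``.
    """
    from .trends import decline_percent

    peak_years = list(peak_window.years)
    recent_years = list(range(recent_period[0], recent_period[1] + 1))
    missing = [y for y in peak_years + recent_years if y not in forecasts]
    if missing:
        raise DataError(f"forecasts missing for collection years {missing}")

    def value_at(fr: ForecastResult) -> float:
        idx = np.where(fr.times == horizon_time)[0]
        if len(idx) == 0:
            raise DataError(
                f"forecast for {fr.collection_year} does not reach {horizon_time}"
            )
        return float(fr.mean[idx[0]])

    recent = np.mean([value_at(forecasts[y]) for y in recent_years])
    peak = np.mean([value_at(forecasts[y]) for y in peak_years])
    return decline_percent(recent, peak)


class SnapshotAccrualModel:
    """Per-collection-year ARIMA models over a snapshot observation table."""

    def __init__(
        self,
        observations: pd.DataFrame,
        collection_year_range: tuple[int, int] = (1950, 2019),
    ):
        self.observations = observations
        self.collection_year_range = collection_year_range
        self.series = build_snapshot_series(observations, collection_year_range)

    def fit(self, d: int = 1, max_p: int = 2, max_q: int = 2):
        fits = {
            year: fit_arima(s, d=d, max_p=max_p, max_q=max_q)
            for year, s in sorted(self.series.items())
        }
        return SnapshotForecastResults(model=self, d=d, fits=fits)

    def validate(self, train_cutoff: int, horizons, d_options=(0, 1, 2), **kw):
        return validate_in_sample(
            self.series, train_cutoff, list(horizons), tuple(d_options), **kw
        )


@dataclass
class SnapshotForecastResults:
    """Fitted accrual models for every collection year."""

    model: SnapshotAccrualModel
    d: int
    fits: dict[int, ArimaFit]

    def forecast(self, h: int) -> dict[int, ForecastResult]:
        return {year: forecast(fit, h) for year, fit in self.fits.items()}

    def forecast_table(self, h: int) -> pd.DataFrame:
        return pd.concat(
            [fr.to_frame() for fr in self.forecast(h).values()], ignore_index=True
        )

    def decline(self, peak_window, recent_period, horizon_time: int) -> float:
        last = max(t for f in self.fits.values() for t in f.series.times)
        h = horizon_time - last
        return forecast_decline(self.forecast(h), peak_window, recent_period, horizon_time)

    def summary(self) -> str:
        specs = pd.Series(
            [f"({f.spec.p},{f.spec.d},{f.spec.q})" for f in self.fits.values()]
        ).value_counts()
        lines = [
            "Snapshot accrual forecasts",
            "=" * 26,
            f"collection years       {min(self.fits)}-{max(self.fits)} "
            f"({len(self.fits)} series)",
            f"differencing order d   {self.d}",
            "selected orders:",
        ]
        for spec, n in specs.items():
            lines.append(f"  {spec}: {n}")
        n_fallback = sum(f.fallback for f in self.fits.values())
        if n_fallback:
            lines.append(f"fallback (0,d,0) fits: {n_fallback}")
        return "\n".join(lines)
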