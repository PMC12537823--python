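"""Seeded synthetic occurrence and snapshot data with known ground truth.

Real inputs for this kind of analysis are multi-gigabyte aggregator
downloads; the generator here produces structurally similar data at desk
scale so that every pipeline stage can be exercised against a known answer:

* **Collecting effort** follows a unimodal piecewise-exponential curve —
  exponential rise to a peak year, exponential fall after it — which is the
  qualitative rise-peak-decline shape the trend analysis must detect. The
  curve is the ground truth for peak-window and decline recovery tests.
* **Institutions** get log-normal size scales and a home coordinate;
  per-institution-year record counts are Poisson(scale x effort).
* **Species** are drawn from a log-series abundance distribution, giving
  realistic dominance/rarity structure in the unique-species counts.
* **Coordinates** are bivariate normal around the institution's home
  (clipped to valid ranges), producing spatial clustering.
* **Anomalies** are injected multiplicative spikes in chosen
  institution-years — the ground truth for filter recall/precision.
* **Snapshots** emulate accrual into the aggregated database: a record
  collected in year ``y`` by institution ``i`` first appears at
  ``max(onboarding_i, y + lag)`` with a geometric databasing lag, and
  optional removal events drop a fraction of present records at a snapshot.
  The per-collection-year totals are the known asymptotes that forecasts
  should approach.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
scenario config: same config and seed, byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .trends import PeakWindow, decline_percent, find_peak_window, period_mean


@dataclass(frozen=True)
class SnapshotModel:
    """Accrual mechanics for snapshot simulation."""

    snapshot_years: tuple[int, int] = (2007, 2023)  # inclusive, annual
    onboarding_span: tuple[int, int] = (1990, 2015)  # uniform per institution
    p_lag: float = 0.5  # geometric databasing-lag parameter (support 0, 1, ...)
    removals: tuple[tuple[int, float], ...] = ()  # (snapshot year, fraction)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic study scenario.

    Defaults describe a mid-sized realistic scenario: 20 institutions with
    log-normal size scales, a 300-species log-series pool, effort peaking in
    1980 with a gentle multi-decade rise and fall (roughly halving over
    ~35 years, comparable to the declines the analysis targets), and ~45k
    expected records over 1950-2019.
    """

    seed: int = 0
    n_institutions: int = 20
    institution_scale_logmean: float = float(np.log(30.0))
    institution_scale_logsd: float = 1.0
    n_species: int = 300
    logseries_p: float = 0.995  # log-series shape for abundance weights
    year_span: tuple[int, int] = (1950, 2019)
    peak_year: int = 1980
    rise_rate: float = 0.03
    fall_rate: float = 0.02
    amplitude: float = 1.0  # effort multiplier at the peak year
    home_lat_range: tuple[float, float] = (-60.0, 70.0)
    spatial_sd: float = 5.0  # degrees around each institution's home
    taxon_group: str = "GroupA"
    anomalies: tuple[tuple[str, int, float], ...] = ()  # (institution, year, mult)
    recent_period: tuple[int, int] = (2010, 2019)
    window: int = 5
    snapshot_model: SnapshotModel = field(default_factory=SnapshotModel)

    def with_(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Deterministic truths of a scenario, for recovery experiments."""

    expected_yearly: pd.Series  # E[count] per year from the effort curve
    true_peak: PeakWindow
    true_decline: float  # percent, from the expected series
    anomaly_keys: list[tuple[str, int]]
    asymptotes: pd.Series | None = None  # per-collection-year final counts


def simulate_effort_curve(
    peak_year: int,
    rise_rate: float,
    fall_rate: float,
    amplitude: float,
    year_span: tuple[int, int],
) -> pd.Series:
    """Unimodal piecewise-exponential collecting-effort curve.

    ``amplitude * exp(rise_rate * (y - peak_year))`` up to the peak year and
    ``amplitude * exp(-fall_rate * (y - peak_year))`` after it; the maximum
    is exactly at ``peak_year`` (when it lies inside the span).
    """
    if rise_rate <= 0 or fall_rate <= 0 or amplitude < 0:
        raise ConfigurationError("rates must be positive and amplitude non-negative")
    years = np.arange(year_span[0], year_span[1] + 1)
    delta = years - peak_year
    intensity = np.where(
        delta <= 0,
        amplitude * np.exp(rise_rate * delta),
        amplitude * np.exp(-fall_rate * delta),
    )
    return pd.Series(intensity, index=pd.Index(years, name="year"))


def _species_pool(config: ScenarioConfig, rng: np.random.Generator):
    names = np.array([f"Genus species{i:04d}" for i in range(config.n_species)])
    abundances = stats.logser.rvs(
        config.logseries_p, size=config.n_species, random_state=rng
    ).astype(float)
    weights = abundances / abundances.sum()
    return names, weights


def expected_yearly_counts(config: ScenarioConfig, scales: np.ndarray) -> pd.Series:
    """E[records per year] given realised institution scales."""
    effort = simulate_effort_curve(
        config.peak_year,
        config.rise_rate,
        config.fall_rate,
        config.amplitude,
        config.year_span,
    )
    return effort * scales.sum()


def _ground_truth_from_expectation(
    config: ScenarioConfig, expected: pd.Series
) -> GroundTruth:
    peak = find_peak_window(expected, config.window)
    recent = period_mean(expected, *config.recent_period)
    decline = (
        decline_percent(recent, peak.window_mean)
        if peak.window_mean > 0
        else float("nan")
    )
    return GroundTruth(
        expected_yearly=expected,
        true_peak=peak,
        true_decline=decline,
        anomaly_keys=[(inst, year) for inst, year, _ in config.anomalies],
    )


def simulate_records(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a full synthetic occurrence table plus its ground truth.

    Per (institution, year) the record count is Poisson(scale_i x
    effort(year)); species come from the abundance-weighted pool and
    coordinates from a bivariate normal around the institution's home.
    Configured anomalies are injected afterwards as multiplicative spikes.
    """
    if config.n_institutions < 1 or config.n_species < 1:
        raise ConfigurationError("need at least one institution and one species")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    years = np.arange(config.year_span[0], config.year_span[1] + 1)
    effort = simulate_effort_curve(
        config.peak_year,
        config.rise_rate,
        config.fall_rate,
        config.amplitude,
        config.year_span,
    ).to_numpy()
    scales = np.exp(
        rng.normal(
            config.institution_scale_logmean,
            config.institution_scale_logsd,
            config.n_institutions,
        )
    )
    inst_names = np.array([f"INST{i:03d}" for i in range(config.n_institutions)])
    home_lat = rng.uniform(*config.home_lat_range, config.n_institutions)
    home_lon = rng.uniform(-175.0, 175.0, config.n_institutions)
    species, weights = _species_pool(config, rng)

    counts = rng.poisson(np.outer(scales, effort))  # (inst, year)
    inst_idx = np.repeat(
        np.arange(config.n_institutions), counts.sum(axis=1)
    )
    year_col = np.concatenate(
        [np.repeat(years, counts[i]) for i in range(config.n_institutions)]
    )
    n = len(year_col)
    lat = np.clip(rng.normal(home_lat[inst_idx], config.spatial_sd), -90, 90)
    lon = np.clip(rng.normal(home_lon[inst_idx], config.spatial_sd), -180, 180)
    records = pd.DataFrame(
        {
            "species": pd.array(rng.choice(species, size=n, p=weights), dtype="string"),
            "year": pd.array(year_col, dtype="Int64"),
            "latitude": lat,
            "longitude": lon,
            "institution": pd.array(inst_names[inst_idx], dtype="string"),
            "taxon_group": pd.array([config.taxon_group] * n, dtype="string"),
            "basis_of_record": pd.array(["PreservedSpecimen"] * n, dtype="string"),
        }
    )
    truth = _ground_truth_from_expectation(
        config, expected_yearly_counts(config, scales)
    )
    for inst, year, mult in config.anomalies:
        records = inject_anomaly(records, inst, year, mult)
    return records.reset_index(drop=True), truth


def inject_anomaly(
    records: pd.DataFrame, institution: str, year: int, multiplier: float
) -> pd.DataFrame:
    """Spike one institution-year by replicating its records.

    The cell's record count becomes ``round(multiplier * original)``; rows
    are replicated cyclically, emulating bulk duplication uploads.
    """
    if multiplier <= 1:
        raise ConfigurationError("anomaly multiplier must exceed 1")
    mask = (records["institution"] == institution) & (
        records["year"].astype("Int64") == year
    )
    base = records.loc[mask.fillna(False)]
    n = len(base)
    if n == 0:
        raise DataError(f"no records for institution-year ({institution}, {year})")
    target = int(round(multiplier * n))
    reps = np.resize(base.index.to_numpy(), target - n)
    extra = records.loc[reps]
    return pd.concat([records, extra], ignore_index=True)


def simulate_snapshots(
    records: pd.DataFrame,
    snapshot_model: SnapshotModel | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate the accrual of records across database snapshots.

    Each record first appears at ``max(onboarding year of its institution,
    collection year + geometric lag)``; snapshot counts are cumulative
    appearances minus any configured removal events. Returns the snapshot
    observation table (snapshot_time, collection_year, count aggregated over
    institutions) and the per-collection-year asymptotes (final totals after
    removals).
    """
    model = snapshot_model or SnapshotModel()
    rng = np.random.default_rng(seed) if rng is None else rng
    s0, s1 = model.snapshot_years
    if s1 <= s0:
        raise ConfigurationError("snapshot range must cover at least two time points")
    times = np.arange(s0, s1 + 1)
    inst = records["institution"].fillna("<none>")
    inst_names, inst_idx = np.unique(inst.to_numpy(), return_inverse=True)
    onboard = rng.integers(
        model.onboarding_span[0], model.onboarding_span[1] + 1, len(inst_names)
    )
    lag = rng.geometric(model.p_lag, len(records)) - 1  # support 0, 1, 2, ...
    years = records["year"].astype(int).to_numpy()
    appearance = np.maximum(onboard[inst_idx], years + lag)
    removed_at = np.full(len(records), np.iinfo(np.int64).max)
    for t, frac in sorted(model.removals):
        present = (appearance <= t) & (removed_at > t)
        idx = np.flatnonzero(present)
        n_drop = int(round(frac * len(idx)))
        if n_drop:
            drop = rng.choice(idx, size=n_drop, replace=False)
            removed_at[drop] = t
    rows = []
    for t in times:
        present = (appearance <= t) & (removed_at > t)
        per_year = pd.Series(years[present]).value_counts().sort_index()
        for y, c in per_year.items():
            rows.append((int(t), int(y), int(c)))
    obs = pd.DataFrame(rows, columns=["snapshot_time", "collection_year", "count"])
    obs["institution"] = pd.NA
    final = (appearance <= times[-1] + 10**6) & (removed_at > times[-1])
    asymptotes = (
        pd.Series(years[final]).value_counts().sort_index().rename("asymptote")
    )
    asymptotes.index.name = "collection_year"
    return obs, asymptotes


def simulate_random_walk_series(
    n: int,
    start: float,
    drift: float,
    sigma: float,
    rng: np.random.Generator,
    first_time: int = 2007,
):
    """A random-walk-with-drift snapshot series (validation test bed)."""
    from .forecast import SnapshotSeries

    steps = rng.normal(drift, sigma, n - 1)
    counts = np.maximum(start + np.concatenate([[0.0], np.cumsum(steps)]), 0.0)
    return SnapshotSeries(
        collection_year=first_time,
        times=np.arange(first_time, first_time + n),
        counts=counts,
    )
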