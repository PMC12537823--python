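"""Institution-year anomaly detection on log-transformed yearly counts.

Aggregated occurrence databases occasionally contain implausibly large
per-institution spikes — bulk duplications or mis-attributed uploads — that
dominate yearly totals and distort global trend estimates. The screen here
works on the (institution, collection-year) count matrix:

1. log-transform the yearly counts (natural log) to stabilise variance;
2. for each institution, compute the mean and standard deviation of its
   log counts across years; likewise across institutions within each year;
3. flag an institution-year whose log count exceeds ``k`` standard
   deviations above the mean *both* within its institution and across
   institutions in that year (one-sided: only high outliers);
4. report the flagged cells with their z-scores and the linear-scale
   departure as a diagnostic for inspection;
5. remove all records belonging to flagged institution-years.

Standard deviations use the n-1 denominator and a z-score is undefined
(never flagged) when its comparison group has fewer than ``min_group``
members or zero spread. Records without an institution code are pooled
under a reserved label and exempt from flagging — they have no comparison
group. Filtering is single-pass: z-scores are not recomputed after removal.

``k`` defaults to 3.0 for contemporary records; the snapshot presets use the
more conservative 3.1 (Plantae, Chordata) and 3.6 (Arthropoda) log-SDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Reserved pool for records lacking an institution code; never flagged.
MISSING_INSTITUTION = "<no-institution>"

#: Named threshold presets (log-scale SDs).
THRESHOLD_PRESETS = {
    "contemporary": 3.0,
    "snapshot-chordata": 3.1,
    "snapshot-plantae": 3.1,
    "snapshot-arthropoda": 3.6,
}


def institution_year_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Record counts per (institution, year), with natural-log counts.

    Records with a missing institution are pooled under
    :data:`MISSING_INSTITUTION`. Counts conserve the total number of input
    records.
    """
    inst = records["institution"].fillna(MISSING_INSTITUTION)
    grouped = (
        records.assign(institution=inst)
        .groupby(["institution", "year"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    grouped["year"] = grouped["year"].astype(int)
    grouped["log_count"] = np.log(grouped["count"].astype(float))
    return grouped


def _group_z(values: pd.Series, group: pd.Series, min_group: int) -> pd.Series:
    """Z-score of each value against its group's mean/SD (n-1), NaN if undefined."""
    g = values.groupby(group)
    mean = g.transform("mean")
    sd = g.transform("std")  # pandas std: ddof=1
    size = g.transform("size")
    z = (values - mean) / sd
    z[(size < min_group) | (sd == 0) | sd.isna()] = np.nan
    return z


def zscores(counts: pd.DataFrame, min_group: int = 3) -> pd.DataFrame:
    """Within-institution and across-institution log-scale z-scores.

    For each institution-year entry, ``z_within`` compares its log count to
    all years of the same institution and ``z_across`` to all institutions in
    the same collection year; ``linear_departure`` is the linear-scale
    z-score across institutions in the year, a diagnostic only. Undefined
    scores (group smaller than ``min_group`` or zero SD) are NaN. The pooled
    missing-institution label gets NaN z-scores throughout.
    """
    out = counts.copy()
    out["z_within"] = _group_z(out["log_count"], out["institution"], min_group)
    out["z_across"] = _group_z(out["log_count"], out["year"], min_group)
    out["linear_departure"] = _group_z(
        out["count"].astype(float), out["year"], 2
    )
    exempt = out["institution"] == MISSING_INSTITUTION
    out.loc[exempt, ["z_within", "z_across", "linear_departure"]] = np.nan
    out["flagged"] = False
    return out


def linear_scale_departure(count: float, year_counts) -> float:
    """Linear-scale SDs of ``count`` above the cross-institution mean for a year.

    Diagnostic only — flagging always happens on the log scale. Returns NaN
    when fewer than two institutions or zero spread.
    """
    arr = np.asarray(year_counts, dtype=float)
    if arr.size < 2:
        return float("nan")
    sd = arr.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((count - arr.mean()) / sd)


def flag_anomalies(flags: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Set ``flagged`` where both z-scores exceed the threshold ``k``.

    Conjunctive and one-sided: an entry is anomalous only when its log count
    sits more than ``k`` SDs above the mean both within its institution and
    across institutions in its year; undefined z-scores never flag.
    """
    if not k > 0:
        raise ConfigurationError(f"threshold k must be positive, got {k}")
    out = flags.copy()
    out["flagged"] = (out["z_within"] > k) & (out["z_across"] > k)
    out["flagged"] = out["flagged"].fillna(False).astype(bool)
    return out


def remove_anomalies(
    records: pd.DataFrame, flags: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop all records belonging to flagged institution-years.

    Returns ``(cleaned, report)`` where the report lists each removed
    institution-year with its count, both z-scores and the linear-scale
    departure. Cleaned + removed record counts equal the input count.
    """
    flagged = flags.loc[
        flags["flagged"],
        ["institution", "year", "count", "z_within", "z_across", "linear_departure"],
    ].reset_index(drop=True)
    if len(flagged) == 0:
        return records, flagged
    inst = records["institution"].fillna(MISSING_INSTITUTION)
    key = pd.MultiIndex.from_arrays([inst, records["year"].astype(int)])
    bad = pd.MultiIndex.from_frame(flagged[["institution", "year"]])
    cleaned = records.loc[~key.isin(bad)]
    return cleaned, flagged


class InstitutionAnomalyModel:
    """Anomaly screen over an occurrence table or a prepared count table.

    Build from raw records with :meth:`from_records` (counts are derived) or
    directly from an (institution, year, count) table with
    :meth:`from_counts`; ``fit(k)`` computes both z-score families and the
    flag set.
    """

    def __init__(self, counts: pd.DataFrame, min_group: int = 3):
        self.counts = counts
        self.min_group = min_group

    @classmethod
    def from_records(cls, records: pd.DataFrame, min_group: int = 3):
        return cls(institution_year_counts(records), min_group=min_group)

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, min_group: int = 3):
        counts = counts.copy()
        if "log_count" not in counts.columns:
            counts["log_count"] = np.log(counts["count"].astype(float))
        return cls(counts, min_group=min_group)

    def fit(self, k: float | str = 3.0) -> "AnomalyResults":
        """Score and flag; ``k`` may be a number or a preset name."""
        if isinstance(k, str):
            try:
                k = THRESHOLD_PRESETS[k]
            except KeyError:
                raise ConfigurationError(
                    f"unknown threshold preset {k!r}; options: "
                    f"{sorted(THRESHOLD_PRESETS)}"
                ) from None
        scored = flag_anomalies(zscores(self.counts, self.min_group), k)
        return AnomalyResults(model=self, k=float(k), flags=scored)


@dataclass
class AnomalyResults:
    """Scored and flagged institution-year table from the anomaly screen."""

    model: InstitutionAnomalyModel
    k: float
    flags: pd.DataFrame

    @property
    def flagged(self) -> pd.DataFrame:
        return self.flags.loc[self.flags["flagged"]]

    def apply(self, records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Remove records in flagged institution-years; returns (cleaned, report)."""
        return remove_anomalies(records, self.flags)

    def summary(self) -> str:
        n = len(self.flags)
        f = self.flagged
        lines = [
            "Institution-year anomaly screen",
            "=" * 31,
            f"threshold k            {self.k} log-scale SDs (one-sided, conjunctive)",
            f"institution-years      {n:,}",
            f"flagged                {len(f):,}",
            f"records in flags       {int(f['count'].sum()):,}",
        ]
        if len(f):
            lines.append("")
            lines.append(
                f.to_string(
                    index=False,
                    columns=[
                        "institution",
                        "year",
                        "count",
                        "z_within",
                        "z_across",
                        "linear_departure",
                    ],
                    float_format=lambda v: f"{v:.2f}",
                )
            )
        return "\n".join(lines)
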