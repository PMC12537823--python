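"""Stage orchestration: read -> filter -> clean -> metrics / forecasts.

Each run writes tidy CSV outputs plus a machine-readable provenance record
(`run_log.json`) with the config hash, seed, package versions and the record
count at every stage, so that conservation can be audited after the fact.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import pandas as pd

from . import __version__, io as _io
from .anomaly import THRESHOLD_PRESETS, InstitutionAnomalyModel
from .config import PipelineConfig
from .forecast import SnapshotAccrualModel
from .trends import CollectingTrendModel

logger = logging.getLogger(__name__)


def _provenance(config: PipelineConfig, stage_counts: dict, extra: dict | None = None):
    import numpy, scipy, statsmodels

    record = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stage_counts": stage_counts,
        "versions": {
            "specimentrends": __version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "config": config.to_dict(),
    }
    if extra:
        record.update(extra)
    return record


def _resolve_k(config: PipelineConfig) -> float:
    if config.taxon_preset is not None:
        return THRESHOLD_PRESETS[config.taxon_preset]
    return config.anomaly_k


def run_trends(config: PipelineConfig) -> dict:
    """Execute the occurrence-trend stage chain and write its outputs.

    Returns the provenance record (also written to ``run_log.json``).
    Outputs: ``yearly_metrics.csv``, ``peak_decline.csv``,
    ``anomaly_report.csv``, ``grid_change.csv``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dialect = _io.Dialect(delimiter=config.delimiter)
    records = _io.read_occurrences(config.occurrence_path, dialect)
    stage_counts = {"read": len(records)}

    valid = _io.filter_valid(records, basis=config.basis_filter)
    stage_counts["valid"] = len(valid)

    k = _resolve_k(config)
    screened = InstitutionAnomalyModel.from_records(valid).fit(k)
    cleaned, removal_report = screened.apply(valid)
    stage_counts["cleaned"] = len(cleaned)
    stage_counts["removed_by_anomaly_filter"] = int(removal_report["count"].sum())
    removal_report.to_csv(out / "anomaly_report.csv", index=False)

    results = CollectingTrendModel(cleaned, span=config.analysis_span).fit(
        window=config.window,
        recent_period=config.recent_period,
        reference_period=config.reference_period,
    )
    stage_counts["in_span"] = int(results.yearly_metrics["specimen_count"].sum())
    results.yearly_metrics.to_csv(out / "yearly_metrics.csv")

    coverage = _io.coverage_summary(cleaned)
    peak = results.peak_window
    pd.DataFrame(
        [
            {
                "peak_start_year": peak.start_year,
                "peak_end_year": peak.end_year,
                "peak_window_mean": peak.window_mean,
                "recent_start_year": config.recent_period[0],
                "recent_end_year": config.recent_period[1],
                "recent_mean": results.recent_mean,
                "decline_percent": round(results.decline, 1),
                **coverage,
            }
        ]
    ).to_csv(out / "peak_decline.csv", index=False)

    results.grid_change_map().to_csv(out / "grid_change.csv", index=False)

    provenance = _provenance(
        config, stage_counts, {"summary": results.summary(), "anomaly_k": k}
    )
    (out / "run_log.json").write_text(json.dumps(provenance, indent=2, default=str))
    logger.info("trends run complete: %s", stage_counts)
    return provenance


def run_forecast(config: PipelineConfig) -> dict:
    """Execute the snapshot-forecast stage chain and write its outputs.

    Outputs: ``forecasts.csv`` and, when a validation cutoff is configured,
    ``validation.csv``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    observations = _io.read_snapshots(config.snapshot_path)
    stage_counts = {"snapshot_rows": len(observations)}

    model = SnapshotAccrualModel(observations, config.collection_year_range)
    stage_counts["series_built"] = len(model.series)

    extra: dict = {}
    if config.validation_cutoff is not None:
        report = model.validate(
            config.validation_cutoff,
            config.validation_horizons,
            config.d_options,
            max_p=config.max_p,
            max_q=config.max_q,
        )
        report.table.to_csv(out / "validation.csv", index=False)
        extra["validation_winning_d"] = report.winning_d
        extra["validation_skipped"] = report.n_skipped

    results = model.fit(d=config.forecast_d, max_p=config.max_p, max_q=config.max_q)
    table = results.forecast_table(config.horizon)
    table.to_csv(out / "forecasts.csv", index=False)
    stage_counts["series_forecast"] = table["collection_year"].nunique()

    provenance = _provenance(config, stage_counts, extra)
    (out / "run_log.json").write_text(json.dumps(provenance, indent=2, default=str))
    logger.info("forecast run complete: %s", stage_counts)
    return provenance
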