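"""Pipeline configuration: one serialisable object for a full run."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    """Everything a trends or forecast run needs, in one round-trippable object."""

    occurrence_path: str | None = None
    snapshot_path: str | None = None
    output_dir: str = "outputs"
    delimiter: str = "\t"
    basis_filter: str | None = "PreservedSpecimen"
    taxon_preset: str | None = None  # named anomaly-threshold preset
    anomaly_k: float = 3.0
    analysis_span: tuple[int, int] = (1950, 2019)
    window: int = 5
    recent_period: tuple[int, int] = (2010, 2019)
    reference_period: tuple[int, int] = (1970, 2009)
    forecast_d: int = 1
    max_p: int = 2
    max_q: int = 2
    horizon: int = 10
    validation_cutoff: int | None = None
    validation_horizons: tuple[int, ...] = (5, 10, 15)
    d_options: tuple[int, ...] = (0, 1, 2)
    collection_year_range: tuple[int, int] = (1950, 2019)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.analysis_span
        for name in ("recent_period", "reference_period"):
            p0, p1 = getattr(self, name)
            if p0 > p1:
                raise ConfigurationError(f"{name} start exceeds end: {(p0, p1)}")
            if p0 < lo or p1 > hi:
                raise ConfigurationError(
                    f"{name} {(p0, p1)} outside analysis span {self.analysis_span}"
                )
        r0, r1 = self.recent_period
        f0, f1 = self.reference_period
        if max(r0, f0) <= min(r1, f1):
            raise ConfigurationError(
                "recent and reference periods overlap: "
                f"{self.recent_period} vs {self.reference_period}"
            )
        if self.window < 1:
            raise ConfigurationError("window length must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load YAML or JSON config; keyword overrides win over file values."""
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in (
            "analysis_span",
            "recent_period",
            "reference_period",
            "validation_horizons",
            "d_options",
            "collection_year_range",
        ):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path: str | Path) -> None:
        # tuples -> lists so the dump stays plain YAML
        data = json.loads(json.dumps(self.to_dict(), default=str))
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
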