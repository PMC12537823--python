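import numpy as np
import pandas as pd
import pytest


def make_records(rows):
    """Build a canonical occurrence DataFrame from (species, year, lat, lon,
    institution) tuples; None becomes a missing value."""
    cols = ["species", "year", "latitude", "longitude", "institution"]
    df = pd.DataFrame(rows, columns=cols)
    out = pd.DataFrame(
        {
            "species": pd.array(df["species"], dtype="string"),
            "year": pd.array(df["year"], dtype="Int64"),
            "latitude": pd.to_numeric(df["latitude"]),
            "longitude": pd.to_numeric(df["longitude"]),
            "institution": pd.array(df["institution"], dtype="string"),
            "taxon_group": pd.array(["GroupA"] * len(df), dtype="string"),
            "basis_of_record": pd.array(["PreservedSpecimen"] * len(df), dtype="string"),
        }
    )
    return out


@pytest.fixture
def records_factory():
    return make_records


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def occurrence_tsv(tmp_path):
    """Write a GBIF-header TSV and return its path."""

    def _write(rows, header=None, name="occ.tsv"):
        header = header or [
            "species",
            "year",
            "decimalLatitude",
            "decimalLongitude",
            "institutionCode",
            "basisOfRecord",
        ]
        lines = ["\t".join(header)]
        for row in rows:
            lines.append("\t".join("" if v is None else str(v) for v in row))
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
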