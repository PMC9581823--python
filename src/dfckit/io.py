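"""Readers and writers for the pipeline's tabular formats.

Formats are deliberately plain: CSV for region tables and cohort manifests,
TSV (one row per volume, one column per region) for time series. The
time-series writer uses ``%.17g`` so float64 values round-trip exactly.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CohortTable, RegionTable, TimeSeriesMatrix, ValidationError

_FIXTURE_NAME = "aal90_yeo7.csv"


def default_region_table() -> RegionTable:
    """The bundled 90-region AAL parcellation with Yeo-7 derived labels.

    78 cortical regions carry DMN / FPN / OTHER_CORTICAL labels; the 12
    subcortical regions (hippocampus, amygdala, caudate, putamen, pallidum,
    thalamus, bilaterally) are labelled SUBCORTICAL. The DMN/FPN assignment
    follows the published AAL-to-Yeo correspondence and is shipped as an
    editable CSV, not hard-coded.
    """
    ref = importlib.resources.files("dfckit") / "data" / _FIXTURE_NAME
    with importlib.resources.as_file(ref) as path:
        return read_region_table(path)


def read_region_table(path: str | Path) -> RegionTable:
    """Read and validate a region table CSV (``region_id,name,cortical,network``)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"cannot parse region table {path}: {exc}") from exc
    if "cortical" in df.columns:
        df["cortical"] = df["cortical"].map(_parse_bool)
    return RegionTable(df)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "t", "yes"):
        return True
    if text in ("false", "0", "f", "no"):
        return False
    raise ValidationError(f"cannot parse boolean value {value!r}")


def write_region_table(table: RegionTable, path: str | Path) -> None:
    df = table.df.copy()
    df["cortical"] = np.where(df["cortical"], "true", "false")
    df.to_csv(path, index=False)


def read_timeseries(
    path: str | Path, region_table: RegionTable, tr_seconds: float
) -> TimeSeriesMatrix:
    """Read a volumes-by-regions TSV and return a regions-by-volumes matrix.

    The header row must contain exactly the region names of ``region_table``;
    columns are reordered to table order before transposing.
    """
    try:
        # round_trip parsing so %.17g-formatted values reload bit-identically
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise ValidationError(f"cannot parse time series {path}: {exc}") from exc
    expected = region_table.names
    missing = [name for name in expected if name not in df.columns]
    if missing:
        raise ValidationError(f"time series {path} missing region column(s): {missing}")
    extra = [c for c in df.columns if c not in expected]
    if extra:
        raise ValidationError(f"time series {path} has unknown column(s): {extra}")
    if len(df) < 2:
        raise ValidationError(f"time series {path} has fewer than 2 volumes")
    values = df.loc[:, expected].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"time series {path} contains non-numeric or non-finite cells")
    return TimeSeriesMatrix(
        data=values.T, tr_seconds=tr_seconds, region_ids=list(region_table.region_ids)
    )


def write_timeseries(
    ts: TimeSeriesMatrix, path: str | Path, region_names: list[str] | None = None
) -> None:
    """Write a TSV with one row per volume; values formatted to round-trip."""
    names = region_names if region_names is not None else [f"R{i}" for i in ts.region_ids]
    if len(names) != ts.n_regions:
        raise ValidationError("region_names length must match the number of regions")
    with open(path, "w") as handle:
        handle.write("\t".join(names) + "\n")
        for vol in ts.data.T:
            handle.write("\t".join(format(v, ".17g") for v in vol) + "\n")


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate a cohort manifest CSV."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError("no participants: manifest file is empty") from exc
    except Exception as exc:
        raise ValidationError(f"cannot parse cohort manifest {path}: {exc}") from exc
    if len(df) == 0:
        raise ValidationError("no participants in cohort manifest")
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.df.to_csv(path, index=False)
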