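"""Shared data containers for the dFC pipeline.

Conventions used throughout the package:

* region ids are 1-based and contiguous, matching the AAL numbering;
* time-series matrices are stored regions x volumes (one row per region);
* volume indices in user-facing output are 1-based;
* group labels are canonicalized to ``BCC_PLUS`` / ``BCC_MINUS`` / ``NC``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

GROUPS = ("BCC_PLUS", "BCC_MINUS", "NC")

NETWORKS = ("DMN", "FPN", "OTHER_CORTICAL", "SUBCORTICAL")
CORTICAL_NETWORKS = ("DMN", "FPN", "OTHER_CORTICAL")

#: Cognitive tests handled by the normative-change pipeline. HVLT_IR is the
#: Hopkins Verbal Learning Test-Revised immediate recall (words; higher is
#: better); TMTB is Trail Making Test part B (seconds; higher is worse).
TESTS = ("HVLT_IR", "TMTB")
HIGHER_IS_BETTER = {"HVLT_IR": True, "TMTB": False}

#: Manifest column pairs (baseline, follow-up) for each test's raw scores.
TEST_COLUMNS = {"HVLT_IR": ("hvlt_bl", "hvlt_fu"), "TMTB": ("tmtb_bl", "tmtb_fu")}

#: dFC summary measures and their manifest column pairs.
DFC_MEASURES = ("DMN_dFC", "FPN_dFC", "WB_dFC")
DFC_COLUMNS = {
    "DMN_dFC": ("dmn_dfc_bl", "dmn_dfc_fu"),
    "FPN_dFC": ("fpn_dfc_bl", "fpn_dfc_fu"),
    "WB_dFC": ("wb_dfc_bl", "wb_dfc_fu"),
}


class ValidationError(ValueError):
    """Raised when an input table or matrix violates a structural invariant."""


def normalize_group(label: str) -> str:
    """Canonicalize a cohort group label (case-insensitive).

    Accepts the canonical names plus common manifest spellings such as
    ``bcc+``, ``BCC-`` or ``nc``.
    """
    key = str(label).strip().upper().replace(" ", "")
    aliases = {
        "BCC+": "BCC_PLUS",
        "BCC_PLUS": "BCC_PLUS",
        "BCCPLUS": "BCC_PLUS",
        "BCC-": "BCC_MINUS",
        "BCC_MINUS": "BCC_MINUS",
        "BCCMINUS": "BCC_MINUS",
        "NC": "NC",
    }
    if key not in aliases:
        raise ValidationError(f"unknown group label: {label!r}")
    return aliases[key]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in volumes.

    The study configuration is a 28-volume window advanced by 5 volumes,
    which at TR = 2.1 s corresponds to a 58.8 s window shifted by 10.5 s.
    """

    length_volumes: int = 28
    step_volumes: int = 5

    def __post_init__(self) -> None:
        if not (isinstance(self.length_volumes, (int, np.integer)) and self.length_volumes >= 2):
            raise ValidationError("window length must be an integer >= 2 volumes")
        if not (isinstance(self.step_volumes, (int, np.integer)) and self.step_volumes >= 1):
            raise ValidationError("window step must be an integer >= 1 volume")

    def length_seconds(self, tr_seconds: float) -> float:
        return self.length_volumes * tr_seconds

    def step_seconds(self, tr_seconds: float) -> float:
        return self.step_volumes * tr_seconds


class RegionTable:
    """Parcellation metadata: region ids, names, cortical flags, networks.

    Wraps a DataFrame with columns ``region_id, name, cortical, network`` and
    enforces: unique contiguous 1..N ids, network labels drawn from
    ``NETWORKS``, and the cortical/network consistency rule (a region carries
    a cortical network label iff it is cortical).
    """

    REQUIRED_COLUMNS = ("region_id", "name", "cortical", "network")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"region table missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED_COLUMNS)].copy()
        df["region_id"] = df["region_id"].astype(int)
        df["name"] = df["name"].astype(str)
        df["cortical"] = df["cortical"].astype(bool)
        df["network"] = df["network"].astype(str)
        self._validate(df)
        self.df = df.reset_index(drop=True)

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        ids = df["region_id"].to_numpy()
        dup = df.loc[df["region_id"].duplicated(), "region_id"].tolist()
        if dup:
            raise ValidationError(f"duplicate region_id(s): {sorted(set(dup))}")
        if not np.array_equal(np.sort(ids), np.arange(1, len(ids) + 1)):
            raise ValidationError("region_ids must be contiguous 1..N")
        for _, row in df.iterrows():
            if row["network"] not in NETWORKS:
                raise ValidationError(
                    f"region {row['region_id']} ({row['name']}): unknown network "
                    f"{row['network']!r}"
                )
            is_cortical_label = row["network"] in CORTICAL_NETWORKS
            if is_cortical_label != bool(row["cortical"]):
                raise ValidationError(
                    f"region {row['region_id']} ({row['name']}): network "
                    f"{row['network']!r} inconsistent with cortical={row['cortical']}"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_regions(self) -> int:
        return len(self.df)

    @property
    def names(self) -> list[str]:
        return self.df["name"].tolist()

    @property
    def region_ids(self) -> np.ndarray:
        return self.df["region_id"].to_numpy()

    def members(self, network: str) -> np.ndarray:
        """0-based row indices of regions assigned to ``network``."""
        if network not in NETWORKS:
            raise ValidationError(f"unknown network {network!r}")
        return np.flatnonzero((self.df["network"] == network).to_numpy())

    @property
    def n_cortical(self) -> int:
        return int(self.df["cortical"].sum())


@dataclass
class TimeSeriesMatrix:
    """One participant-timepoint BOLD block: regions x volumes.

    ``data`` holds one row per region in region-table order; ``tr_seconds``
    is the volume-to-volume sampling interval.
    """

    data: np.ndarray
    tr_seconds: float
    region_ids: Sequence[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("time series must be a 2-D regions x volumes matrix")
        if self.data.shape[1] < 2:
            raise ValidationError("time series must have at least 2 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if not len(self.region_ids):
            self.region_ids = list(range(1, self.data.shape[0] + 1))
        if len(self.region_ids) != self.data.shape[0]:
            raise ValidationError("region_ids length must match the number of rows")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_volumes * self.tr_seconds


class CohortTable:
    """Participant manifest: group, demographics, scores, dFC summaries.

    One row per participant. ``group`` is canonicalized on construction.
    Cognitive and dFC columns may be absent or NaN; each analysis selects its
    own complete cases.
    """

    REQUIRED_COLUMNS = ("participant_id", "group", "age", "iq")
    OPTIONAL_COLUMNS = (
        "hvlt_bl", "hvlt_fu", "tmtb_bl", "tmtb_fu",
        "motion_bl", "motion_fu", "ts_bl_path", "ts_fu_path",
        "dmn_dfc_bl", "dmn_dfc_fu", "fpn_dfc_bl", "fpn_dfc_fu",
        "wb_dfc_bl", "wb_dfc_fu",
    )

    def __init__(self, df: pd.DataFrame):
        if len(df) == 0:
            raise ValidationError("no participants in cohort table")
        missing = [c for c in self.REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        df = df.copy()
        df["participant_id"] = df["participant_id"].astype(str)
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        if dup:
            raise ValidationError(f"duplicate participant_id(s): {sorted(set(dup))}")
        df["group"] = df["group"].map(normalize_group)
        df["age"] = df["age"].astype(float)
        df["iq"] = df["iq"].astype(float)
        if (df["age"] < 0).any():
            bad = df.loc[df["age"] < 0, "participant_id"].tolist()
            raise ValidationError(f"negative age for participant(s): {bad}")
        for col in self.OPTIONAL_COLUMNS:
            if col in df.columns and col not in ("ts_bl_path", "ts_fu_path"):
                df[col] = pd.to_numeric(df[col], errors="raise")
        dfc_cols = [c for c in df.columns if c.endswith(("_dfc_bl", "_dfc_fu"))]
        for col in dfc_cols:
            vals = df[col].dropna()
            if (vals < 0).any():
                raise ValidationError(f"negative dFC values in column {col}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def group_sizes(self) -> dict[str, int]:
        counts = self.df["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def subset(self, group: str) -> pd.DataFrame:
        return self.df[self.df["group"] == normalize_group(group)]


@dataclass(frozen=True)
class ModelResult:
    """One row of an ANOVA/ANCOVA table: term, F, df, p, significance flag."""

    term: str
    f_value: float
    df_num: int
    df_den: int
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if self.f_value < 0:
            raise ValidationError("F statistic must be non-negative")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value must lie in [0, 1]")
        if self.df_num < 1 or self.df_den < 1:
            raise ValidationError("degrees of freedom must be positive integers")


def results_to_frame(results: Sequence[ModelResult]) -> pd.DataFrame:
    """Assemble ModelResult rows into a tidy ANOVA table."""
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "F": [r.f_value for r in results],
            "df_num": [r.df_num for r in results],
            "df_den": [r.df_den for r in results],
            "p": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
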