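"""Synthetic cohorts: BOLD-like time series plus demographics and cognition.

The generator emulates the measured inputs of the study design — three
groups (chemotherapy-treated and untreated breast-cancer patients, no-cancer
controls) scanned and tested at baseline and follow-up — so that every
pipeline stage runs without any real data.

Signal model (one participant-timepoint): each of three latent network
drivers (DMN, FPN, other) is a unit-variance AR(1) process sharing a common
global AR(1) component (inter-network coupling), so that between-network
connections carry signal too; region r tracks its network's driver with a
slowly varying coupling

    w_r(t) = w0 + a * sin(2*pi*t / P_r + phi_r)

and region series  w_r(t)*s_net(t) + sqrt(1 - w_r(t)^2)*eps_r(t)  with AR(1)
noise eps_r, standardized per region. The modulation depth ``a`` is the
dynamic ground truth: a = 0 is a genuinely static (stationarity-null)
cohort, larger ``a`` produces more window-to-window connectivity variance.

Cognition model: follow-up z = group intercept + group slope x (standardized
true change in modulation depth) + age and IQ terms + noise; baseline z is
drawn around a group mean. Trail-making times are emitted on the seconds
scale (higher = worse) so the standardization sign-flip is exercised.

All randomness derives from one master seed: demographics and cognition use
spawn key (0,); the time series of participant i at timepoint t uses spawn
key (1, i, t).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GROUPS, CohortTable, RegionTable, TimeSeriesMatrix, ValidationError
from .io import default_region_table, write_timeseries

_TIMEPOINTS = ("bl", "fu")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for the synthetic cohort.

    Group sizes, scan geometry (180 volumes at TR = 2.1 s, 90 regions) and
    the age/IQ scales (roughly Normal(50, 9) years and Normal(104, 13)
    points) follow the cohort being emulated. The cognitive model defaults
    to the full null: equal intercepts, zero slopes, zero covariate effects.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"BCC_PLUS": 34, "BCC_MINUS": 32, "NC": 35}
    )
    n_regions: int = 90
    n_volumes: int = 180
    tr_seconds: float = 2.1
    ar_coefficient: float = 0.3
    base_coupling: float = 0.5
    #: group -> (baseline, follow-up) modulation depth
    modulation_depth: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {g: (0.2, 0.2) for g in GROUPS}
    )
    #: per-participant-timepoint jitter of the depth (gives the cognition
    #: model an identifiable within-group predictor)
    modulation_depth_sd: float = 0.05
    modulation_period_range: tuple[int, int] = (40, 80)
    #: correlation of each network driver with a shared global driver; gives
    #: between-network connections a non-zero stationary correlation, so
    #: member-to-rest dFC summaries respond to coupling modulation (a strong
    #: global component, as in rsfMRI without global-signal regression)
    inter_network_coupling: float = 0.85
    # cognitive model (z-score units)
    baseline_mean: dict[str, float] = field(default_factory=lambda: {g: 0.0 for g in GROUPS})
    baseline_sd: float = 1.0
    followup_intercept: dict[str, float] = field(
        default_factory=lambda: {g: 0.0 for g in GROUPS}
    )
    #: group -> slope of follow-up z on the standardized dFC-change predictor
    slope: dict[str, float] = field(default_factory=lambda: {g: 0.0 for g in GROUPS})
    beta_age: float = 0.0
    beta_iq: float = 0.0
    cognitive_noise_sd: float = 1.0
    # demographics
    age_mean: float = 50.0
    age_sd: float = 9.0
    iq_mean: float = 104.0
    iq_sd: float = 13.0
    # raw-score scales used to de-standardize the cognition model
    hvlt_mean: float = 26.0
    hvlt_sd: float = 4.5
    tmtb_mean: float = 75.0
    tmtb_sd: float = 25.0
    # score-level dFC measurement model (used by simulate_cohort_scores)
    dfc_base: float = 0.2
    dfc_gain: float = 0.3
    dfc_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_coupling < 1.0):
            raise ValidationError("base_coupling must lie in [0, 1)")
        for g, (a_bl, a_fu) in self.modulation_depth.items():
            for a in (a_bl, a_fu):
                if a < 0 or self.base_coupling + a > 1.0:
                    raise ValidationError(
                        f"modulation depth {a} for {g} violates coupling headroom "
                        f"(need 0 <= a <= {1.0 - self.base_coupling:.3f})"
                    )
        for name in ("baseline_sd", "age_sd", "iq_sd", "hvlt_sd", "tmtb_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("modulation_depth_sd", "cognitive_noise_sd", "dfc_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if any(n < 2 for n in self.n_per_group.values()):
            raise ValidationError("need at least 2 participants per group")
        if not (-1.0 < self.ar_coefficient < 1.0):
            raise ValidationError("ar_coefficient must lie in (-1, 1)")
        if not (0.0 <= self.inter_network_coupling < 1.0):
            raise ValidationError("inter_network_coupling must lie in [0, 1)")

    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """Full-null configuration: static group/time/slope structure."""
        return cls(**overrides)

    @classmethod
    def sign_reversal(cls, beta: float = 0.8, **overrides) -> "SimulationConfig":
        """Opposite-sign dFC-cognition slopes: positive for untreated
        patients, negative for the chemotherapy and control groups."""
        slopes = {"BCC_PLUS": -beta, "BCC_MINUS": beta, "NC": -beta}
        return cls(slope=slopes, **overrides)

    def with_depth(self, depth: float) -> "SimulationConfig":
        """Same config with one uniform modulation depth everywhere."""
        return replace(self, modulation_depth={g: (depth, depth) for g in GROUPS})


def synthetic_region_table(n_regions: int) -> RegionTable:
    """Small all-cortical parcellation for reduced-scale simulations:
    roughly 30% DMN, 20% FPN, rest other."""
    n_dmn = max(1, round(0.3 * n_regions))
    n_fpn = max(1, round(0.2 * n_regions))
    networks = (
        ["DMN"] * n_dmn
        + ["FPN"] * n_fpn
        + ["OTHER_CORTICAL"] * (n_regions - n_dmn - n_fpn)
    )
    return RegionTable(
        pd.DataFrame(
            {
                "region_id": np.arange(1, n_regions + 1),
                "name": [f"Region_{i}" for i in range(1, n_regions + 1)],
                "cortical": True,
                "network": networks,
            }
        )
    )


def _region_table_for(config: SimulationConfig, region_table: RegionTable | None) -> RegionTable:
    if region_table is not None:
        if region_table.n_regions != config.n_regions:
            raise ValidationError("region table size does not match config.n_regions")
        return region_table
    if config.n_regions == 90:
        return default_region_table()
    return synthetic_region_table(config.n_regions)


def _ar1(rng: np.random.Generator, n: int, coeff: float) -> np.ndarray:
    """Unit-marginal-variance AR(1) series."""
    innov_sd = np.sqrt(1.0 - coeff**2)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    shocks = rng.standard_normal(n - 1) * innov_sd
    for t in range(1, n):
        x[t] = coeff * x[t - 1] + shocks[t - 1]
    return x


def simulate_timeseries(
    config: SimulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    depth: float | None = None,
    region_table: RegionTable | None = None,
) -> TimeSeriesMatrix:
    """One synthetic region-by-volume BOLD block at modulation depth ``depth``."""
    if rng is None:
        rng = np.random.default_rng(seed)
    a = depth if depth is not None else config.modulation_depth[GROUPS[0]][0]
    w0 = config.base_coupling
    if a < 0 or w0 + a > 1.0:
        raise ValidationError("modulation depth violates coupling headroom")
    table = _region_table_for(config, region_table)
    T = config.n_volumes
    c = config.inter_network_coupling
    shared = _ar1(rng, T, config.ar_coefficient)
    latent = {
        net: c * shared + np.sqrt(1.0 - c**2) * _ar1(rng, T, config.ar_coefficient)
        for net in ("DMN", "FPN", "OTHER")
    }
    net_of = {
        "DMN": "DMN",
        "FPN": "FPN",
        "OTHER_CORTICAL": "OTHER",
        "SUBCORTICAL": "OTHER",
    }
    tau = np.arange(T)
    lo, hi = config.modulation_period_range
    data = np.empty((table.n_regions, T))
    for r, network in enumerate(table.df["network"]):
        period = rng.uniform(lo, hi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        w = w0 + a * np.sin(2.0 * np.pi * tau / period + phase)
        noise = _ar1(rng, T, config.ar_coefficient)
        series = w * latent[net_of[network]] + np.sqrt(1.0 - w**2) * noise
        data[r] = (series - series.mean()) / series.std()
    return TimeSeriesMatrix(
        data=data, tr_seconds=config.tr_seconds, region_ids=list(table.region_ids)
    )


@dataclass
class SimulatedCohort:
    """Synthetic cohort bundle: manifest, ground truth, optional time series."""

    cohort: CohortTable
    ground_truth: pd.DataFrame
    timeseries: dict[tuple[str, str], TimeSeriesMatrix] = field(default_factory=dict)
    region_table: RegionTable | None = None


def _draw_participants(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0
    for g in GROUPS:
        for _ in range(config.n_per_group.get(g, 0)):
            idx += 1
            rows.append(
                {
                    "participant_id": f"P{idx:03d}",
                    "group": g,
                    "age": rng.normal(config.age_mean, config.age_sd),
                    "iq": rng.normal(config.iq_mean, config.iq_sd),
                }
            )
    df = pd.DataFrame(rows)
    df["age"] = df["age"].clip(lower=18.0)
    return df


def _draw_depths(
    config: SimulationConfig, groups: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    a_max = 1.0 - config.base_coupling
    out = []
    for tp_index in range(2):
        base = np.array([config.modulation_depth[g][tp_index] for g in groups])
        jitter = rng.normal(0.0, config.modulation_depth_sd, size=len(groups))
        out.append(np.clip(base + jitter, 0.0, a_max))
    return out[0], out[1]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _cognitive_scores(
    config: SimulationConfig,
    df: pd.DataFrame,
    proxy: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Raw HVLT-R and TMT-B scores from the z-scale cognition model."""
    groups = df["group"].to_numpy()
    age_c = df["age"].to_numpy() - config.age_mean
    iq_c = df["iq"].to_numpy() - config.iq_mean
    intercept = np.array([config.followup_intercept[g] for g in groups])
    slope = np.array([config.slope[g] for g in groups])
    bl_mean = np.array([config.baseline_mean[g] for g in groups])
    n = len(df)
    out = {}
    for test, (mean, sd, sign) in {
        "hvlt": (config.hvlt_mean, config.hvlt_sd, 1.0),
        "tmtb": (config.tmtb_mean, config.tmtb_sd, -1.0),
    }.items():
        z_bl = bl_mean + config.baseline_sd * rng.standard_normal(n)
        z_fu = (
            intercept
            + slope * proxy
            + config.beta_age * age_c
            + config.beta_iq * iq_c
            + config.cognitive_noise_sd * rng.standard_normal(n)
        )
        out[f"{test}_bl"] = mean + sign * sd * z_bl
        out[f"{test}_fu"] = mean + sign * sd * z_fu
    return pd.DataFrame(out, index=df.index)


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    region_table: RegionTable | None = None,
    keep_timeseries: bool = True,
) -> SimulatedCohort:
    """Full synthetic cohort with BOLD time series at both timepoints.

    Cognition is coupled to the standardized *true* change in modulation
    depth; the dFC change the pipeline measures from the series is a noisy
    proxy of it, so estimated slopes are honestly attenuated.
    """
    table = _region_table_for(config, region_table)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    df = _draw_participants(config, rng)
    a_bl, a_fu = _draw_depths(config, df["group"].to_numpy(), rng)
    proxy = _standardize(a_fu - a_bl)
    scores = _cognitive_scores(config, df, proxy, rng)
    df = pd.concat([df, scores], axis=1)

    timeseries: dict[tuple[str, str], TimeSeriesMatrix] = {}
    paths: dict[str, list[str]] = {"ts_bl_path": [], "ts_fu_path": []}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i, row in df.iterrows():
        for tp_index, (tp, depths) in enumerate(zip(_TIMEPOINTS, (a_bl, a_fu))):
            ts_rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(1, i, tp_index))
            )
            ts = simulate_timeseries(
                config, rng=ts_rng, depth=float(depths[i]), region_table=table
            )
            if keep_timeseries:
                timeseries[(row["participant_id"], tp)] = ts
            if out_path is not None:
                fname = f"{row['participant_id']}_{tp}.tsv"
                write_timeseries(ts, out_path / fname, region_names=table.names)
                paths[f"ts_{tp}_path"].append(fname)
    if out_path is not None:
        df["ts_bl_path"] = paths["ts_bl_path"]
        df["ts_fu_path"] = paths["ts_fu_path"]

    ground_truth = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "group": df["group"],
            "depth_bl": a_bl,
            "depth_fu": a_fu,
            "delta_depth": a_fu - a_bl,
            "proxy": proxy,
            "slope": [config.slope[g] for g in df["group"]],
        }
    )
    cohort = CohortTable(df)
    if out_path is not None:
        cohort.df.to_csv(out_path / "manifest.csv", index=False)
        ground_truth.to_csv(out_path / "ground_truth.csv", index=False)
    return SimulatedCohort(
        cohort=cohort, ground_truth=ground_truth, timeseries=timeseries, region_table=table
    )


def simulate_cohort_scores(config: SimulationConfig, seed: int | None = None) -> SimulatedCohort:
    """Score-level cohort without BOLD simulation (for calibration studies).

    dFC summary columns are generated directly from the measurement model
    ``dfc = dfc_base + dfc_gain * depth + noise`` and cognition is coupled to
    the standardized generated dFC change (DMN change for memory, FPN change
    for trail-making), so the regression ground truth is exact. Much faster
    than the full generator; used for type-I and power studies.
    """
    use_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(use_seed, spawn_key=(0,)))
    df = _draw_participants(config, rng)
    groups = df["group"].to_numpy()
    a_bl, a_fu = _draw_depths(config, groups, rng)
    n = len(df)
    dfc_cols = {}
    for prefix in ("dmn", "fpn", "wb"):
        for tp, depth in (("bl", a_bl), ("fu", a_fu)):
            vals = (
                config.dfc_base
                + config.dfc_gain * depth
                + config.dfc_noise_sd * rng.standard_normal(n)
            )
            dfc_cols[f"{prefix}_dfc_{tp}"] = np.clip(vals, 0.0, None)
    dfc = pd.DataFrame(dfc_cols, index=df.index)

    age_c = df["age"].to_numpy() - config.age_mean
    iq_c = df["iq"].to_numpy() - config.iq_mean
    intercept = np.array([config.followup_intercept[g] for g in groups])
    slope = np.array([config.slope[g] for g in groups])
    bl_mean = np.array([config.baseline_mean[g] for g in groups])
    scores = {}
    for test, (mean, sd, sign, measure) in {
        "hvlt": (config.hvlt_mean, config.hvlt_sd, 1.0, "dmn"),
        "tmtb": (config.tmtb_mean, config.tmtb_sd, -1.0, "fpn"),
    }.items():
        proxy = _standardize(
            dfc[f"{measure}_dfc_fu"].to_numpy() - dfc[f"{measure}_dfc_bl"].to_numpy()
        )
        z_bl = bl_mean + config.baseline_sd * rng.standard_normal(n)
        z_fu = (
            intercept
            + slope * proxy
            + config.beta_age * age_c
            + config.beta_iq * iq_c
            + config.cognitive_noise_sd * rng.standard_normal(n)
        )
        scores[f"{test}_bl"] = mean + sign * sd * z_bl
        scores[f"{test}_fu"] = mean + sign * sd * z_fu
    df = pd.concat([df, pd.DataFrame(scores, index=df.index), dfc], axis=1)
    ground_truth = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "group": groups,
            "depth_bl": a_bl,
            "depth_fu": a_fu,
            "slope": [config.slope[g] for g in groups],
        }
    )
    return SimulatedCohort(cohort=CohortTable(df), ground_truth=ground_truth)
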