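"""Normative standardization and regression-based change scores.

Raw neuropsychological scores are converted to z-scores anchored on the
no-cancer control (NC) group's baseline mean and SD; Trail Making Test B
times are sign-flipped at standardization so that lower z uniformly means
worse performance. Follow-up performance is then corrected for baseline by
an ordinary least-squares prediction (baseline z, age, premorbid IQ) fitted
in the norm group only; the residual (observed minus predicted follow-up z)
is the change score analysed downstream with one-way ANOVAs and pooled-SD
effect sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import (
    GROUPS,
    HIGHER_IS_BETTER,
    TEST_COLUMNS,
    TESTS,
    CohortTable,
    ModelResult,
    ValidationError,
    normalize_group,
    results_to_frame,
)

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class NormModel:
    """Norm-group anchors and prediction coefficients for one test.

    ``mean``/``sd`` are the norm group's baseline raw moments (z anchors);
    ``coefficients`` are the OLS coefficients (intercept, baseline z, age,
    IQ) predicting follow-up z, estimated in the norm group.
    """

    test: str
    mean: float
    sd: float
    coefficients: tuple[float, float, float, float]
    n_norm: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValidationError("norm SD must be positive")
        if not all(math.isfinite(c) for c in self.coefficients):
            raise ValidationError("non-finite norm regression coefficients")
        if self.n_norm <= 4:
            raise ValidationError("norm group must exceed the number of parameters (4)")

    def predict_followup_z(self, baseline_z, age, iq):
        b0, b1, b2, b3 = self.coefficients
        return b0 + b1 * np.asarray(baseline_z) + b2 * np.asarray(age) + b3 * np.asarray(iq)


def zscore(raw, test: str, norm: NormModel):
    """Standardize a raw score on the norm anchors; lower z = worse.

    HVLT_IR (words recalled, higher better): z = (raw - mean) / sd.
    TMTB (seconds, higher worse): z = -(raw - mean) / sd.
    """
    if test not in TESTS:
        raise ValidationError(f"unknown test label {test!r}")
    z = (np.asarray(raw, dtype=float) - norm.mean) / norm.sd
    return z if HIGHER_IS_BETTER[test] else -z


def fit_norm_regression(cohort: CohortTable, test: str, norm_group: str = "NC") -> NormModel:
    """Fit the normative prediction model in the norm group.

    Anchors (baseline mean/SD) and the OLS regression of follow-up z on
    (baseline z, age, IQ) both use the norm group's complete cases only.
    """
    if test not in TESTS:
        raise ValidationError(f"unknown test label {test!r}")
    bl_col, fu_col = TEST_COLUMNS[test]
    norm_df = cohort.subset(norm_group)
    complete = norm_df.dropna(subset=[bl_col, fu_col, "age", "iq"])
    n = len(complete)
    if n <= 4:
        raise ValidationError(
            f"norm group has {n} complete cases for {test}; need more than 4"
        )
    mean = float(complete[bl_col].mean())
    sd = float(complete[bl_col].std(ddof=1))
    if sd <= 0:
        raise ValidationError(f"zero baseline variance in the norm group for {test}")
    sign = 1.0 if HIGHER_IS_BETTER[test] else -1.0
    bl_z = sign * (complete[bl_col].to_numpy() - mean) / sd
    fu_z = sign * (complete[fu_col].to_numpy() - mean) / sd
    X = sm.add_constant(
        np.column_stack([bl_z, complete["age"].to_numpy(), complete["iq"].to_numpy()])
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(f"rank-deficient norm regression design for {test}")
    fit = sm.OLS(fu_z, X).fit()
    return NormModel(
        test=test, mean=mean, sd=sd, coefficients=tuple(float(b) for b in fit.params), n_norm=n
    )


def residual_scores(cohort: CohortTable, norm: NormModel, test: str) -> pd.DataFrame:
    """Observed minus predicted follow-up z for every complete case, all groups.

    Participants missing any of baseline, follow-up, age or IQ are excluded
    with a log entry. Columns: participant_id, group, baseline_z, followup_z,
    predicted_z, residual.
    """
    if test != norm.test:
        raise ValidationError(f"norm model is for {norm.test}, not {test}")
    bl_col, fu_col = TEST_COLUMNS[test]
    needed = [bl_col, fu_col, "age", "iq"]
    df = cohort.df
    incomplete = df[df[needed].isna().any(axis=1)] if set(needed) <= set(df.columns) else df
    if set(needed) - set(df.columns):
        raise ValidationError(f"cohort lacks columns for {test}: {set(needed) - set(df.columns)}")
    for pid in incomplete["participant_id"]:
        logger.info("residual_scores(%s): excluding %s (missing data)", test, pid)
    complete = df.dropna(subset=needed)
    baseline_z = zscore(complete[bl_col].to_numpy(), test, norm)
    followup_z = zscore(complete[fu_col].to_numpy(), test, norm)
    predicted = norm.predict_followup_z(
        baseline_z, complete["age"].to_numpy(), complete["iq"].to_numpy()
    )
    return pd.DataFrame(
        {
            "participant_id": complete["participant_id"].to_numpy(),
            "group": complete["group"].to_numpy(),
            "baseline_z": baseline_z,
            "followup_z": followup_z,
            "predicted_z": predicted,
            "residual": followup_z - predicted,
        }
    )


def oneway_anova(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    term: str = "group",
    alpha: float = DEFAULT_ALPHA,
) -> ModelResult:
    """One-way between-groups ANOVA (F, (k-1, n-k) df, two-sided p)."""
    values = list(groups.values()) if isinstance(groups, dict) else list(groups)
    values = [np.asarray(v, dtype=float) for v in values]
    if len(values) < 2:
        raise ValidationError("one-way ANOVA needs at least 2 groups")
    for i, v in enumerate(values):
        if v.size < 2:
            raise ValidationError(f"group {i} has fewer than 2 values")
    k = len(values)
    n = sum(v.size for v in values)
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0:  # all values identical: no variance to partition
        f_value, p_value = 0.0, 1.0
    else:
        f_value, p_value = stats.f_oneway(*values)
        if not np.isfinite(f_value):
            raise ValidationError("zero within-group variance; F undefined")
        f_value = float(max(f_value, 0.0))
        p_value = float(p_value)
    return ModelResult(
        term=term,
        f_value=f_value,
        df_num=k - 1,
        df_den=n - k,
        p_value=p_value,
        significant=p_value < alpha,
    )


def pooled_effect_size(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Standardized mean difference: (mean1 - mean2) / pooled SD.

    Pooled SD = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2)).
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("effect size requires n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("effect size requires positive SDs")
    pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return (mean1 - mean2) / pooled


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (reporting convention for effect sizes)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


class NormativeChangeModel:
    """Normative-change analysis of one cognitive test across a cohort.

    Fits the norm-group anchors and prediction regression, then computes
    residual change scores for all groups. ``fit()`` returns a
    :class:`NormativeChangeResults` with the group comparison (one-way ANOVA)
    and pooled-SD effect sizes.
    """

    def __init__(
        self,
        cohort: CohortTable,
        test: str,
        norm_group: str = "NC",
        alpha: float = DEFAULT_ALPHA,
    ):
        self.cohort = cohort
        self.test = test
        self.norm_group = normalize_group(norm_group)
        self.alpha = alpha

    def fit(self) -> "NormativeChangeResults":
        norm = fit_norm_regression(self.cohort, self.test, norm_group=self.norm_group)
        residuals = residual_scores(self.cohort, norm, self.test)
        return NormativeChangeResults(
            model=self, norm_model=norm, residuals=residuals, alpha=self.alpha
        )


class NormativeChangeResults:
    """Residual change scores plus group-level comparisons for one test."""

    def __init__(
        self,
        model: NormativeChangeModel,
        norm_model: NormModel,
        residuals: pd.DataFrame,
        alpha: float,
    ):
        self.model = model
        self.norm_model = norm_model
        self.residuals = residuals
        self.alpha = alpha

    def group_stats(self) -> pd.DataFrame:
        """Mean, SD and n of residual change scores per group."""
        rows = []
        for g in GROUPS:
            vals = self.residuals.loc[self.residuals["group"] == g, "residual"]
            if len(vals):
                rows.append(
                    {"group": g, "mean": vals.mean(), "sd": vals.std(ddof=1), "n": len(vals)}
                )
        return pd.DataFrame(rows)

    def anova(self) -> ModelResult:
        """One-way ANOVA on the residual change scores across groups."""
        grouped = {
            g: self.residuals.loc[self.residuals["group"] == g, "residual"].to_numpy()
            for g in GROUPS
            if (self.residuals["group"] == g).sum() >= 2
        }
        return oneway_anova(grouped, term=f"group ({self.model.test})", alpha=self.alpha)

    def effect_sizes(self, reference: str = "BCC_PLUS") -> pd.DataFrame:
        """Pooled-SD effect sizes of the reference group against each other group."""
        reference = normalize_group(reference)
        st = self.group_stats().set_index("group")
        if reference not in st.index:
            raise ValidationError(f"reference group {reference} absent from results")
        rows = []
        for other in GROUPS:
            if other == reference or other not in st.index:
                continue
            es = pooled_effect_size(
                st.loc[reference, "mean"], st.loc[reference, "sd"], int(st.loc[reference, "n"]),
                st.loc[other, "mean"], st.loc[other, "sd"], int(st.loc[other, "n"]),
            )
            rows.append(
                {
                    "comparison": f"{reference} vs {other}",
                    "effect_size": es,
                    "effect_size_2dp": round_half_away(es, 2),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        anova = self.anova()
        lines = [
            f"Normative change scores: {self.model.test}",
            f"  norm group: {self.model.norm_group} (n = {self.norm_model.n_norm}), "
            f"anchors mean = {self.norm_model.mean:.3f}, sd = {self.norm_model.sd:.3f}",
            "",
            self.group_stats().to_string(index=False),
            "",
            results_to_frame([anova]).to_string(index=False),
            "",
            self.effect_sizes().to_string(index=False),
        ]
        return "\n".join(lines)
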