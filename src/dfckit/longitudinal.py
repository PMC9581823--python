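"""Two-timepoint repeated-measures models linking dFC change to cognition.

With exactly two within-subject levels (baseline, follow-up) a repeated-
measures model splits exactly into two orthogonal one-observation-per-subject
blocks:

* between-subject effects are tested on per-subject *means* across time;
* effects involving time are tested on per-subject *differences*
  (follow-up minus baseline), where the time main effect is the intercept
  of the difference model.

Both blocks use the same between-subject design: sum-to-zero (effect) coded
group, a grand-mean-centered continuous dFC-change predictor, their
interaction, and centered age / premorbid-IQ covariates. Each term receives
a Type-III-style F-test (full model vs the model without that term), which
matches full-factorial ANCOVA output for unbalanced groups. The significance
threshold defaults to alpha = 0.01.

``MixedRMAnova`` is the covariate-free special case used for the
group-by-time analysis of the dFC summary measures themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    DFC_COLUMNS,
    GROUPS,
    TEST_COLUMNS,
    TESTS,
    CohortTable,
    ModelResult,
    ValidationError,
    results_to_frame,
)
from .cognition import DEFAULT_ALPHA, HIGHER_IS_BETTER

logger = logging.getLogger(__name__)

#: Default network-to-test pairing: DMN dynamics for memory, FPN for
#: executive function.
DEFAULT_PREDICTOR = {"HVLT_IR": "DMN_dFC", "TMTB": "FPN_dFC"}


def delta_scores(cohort: CohortTable, measure: str) -> pd.DataFrame:
    """Follow-up minus baseline per participant for one dFC measure.

    Participants missing either timepoint are excluded with a log entry.
    """
    if measure not in DFC_COLUMNS:
        raise ValidationError(f"unknown dFC measure {measure!r}")
    bl_col, fu_col = DFC_COLUMNS[measure]
    df = cohort.df
    if bl_col not in df.columns or fu_col not in df.columns:
        raise ValidationError(f"cohort lacks columns {bl_col}/{fu_col}")
    missing = df[df[[bl_col, fu_col]].isna().any(axis=1)]
    for pid in missing["participant_id"]:
        logger.info("delta_scores(%s): excluding %s (missing timepoint)", measure, pid)
    complete = df.dropna(subset=[bl_col, fu_col])
    return pd.DataFrame(
        {
            "participant_id": complete["participant_id"].to_numpy(),
            "group": complete["group"].to_numpy(),
            "measure": measure,
            "delta": (complete[fu_col] - complete[bl_col]).to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# design-matrix helpers


def _effect_code(groups: np.ndarray) -> np.ndarray:
    """Sum-to-zero coding over GROUPS: k-1 columns, last level coded -1."""
    n = len(groups)
    out = np.zeros((n, len(GROUPS) - 1))
    for j, level in enumerate(GROUPS[:-1]):
        out[:, j] = np.where(groups == level, 1.0, 0.0)
    out[groups == GROUPS[-1], :] = -1.0
    return out


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _type3_tests(
    y: np.ndarray,
    blocks: dict[str, np.ndarray],
    alpha: float,
    intercept_term: str | None = None,
) -> list[ModelResult]:
    """Full-vs-reduced F-test for every design block (and optionally the intercept).

    ``blocks`` maps term name -> column block. The full design is the
    intercept plus all blocks; each term is tested by refitting without its
    columns. A block that does not reduce the design rank when dropped is
    collinear and raises an error naming the term.
    """
    n = y.shape[0]
    intercept = np.ones((n, 1))
    parts = [intercept] + [blocks[name] for name in blocks]
    X_full = np.hstack(parts)
    rank_full = np.linalg.matrix_rank(X_full)
    df_den = n - rank_full
    if df_den < 1:
        raise ValidationError("no residual degrees of freedom")
    sse_full = _sse(X_full, y)

    # column offsets of each block within X_full
    offsets: dict[str, slice] = {}
    start = 1
    for name in blocks:
        width = blocks[name].shape[1]
        offsets[name] = slice(start, start + width)
        start += width

    if rank_full < X_full.shape[1]:
        for name in blocks:
            X_r = np.delete(X_full, np.r_[offsets[name]], axis=1)
            if np.linalg.matrix_rank(X_r) == rank_full:
                raise ValidationError(f"rank-deficient design: term {name!r} is collinear")
        raise ValidationError("rank-deficient design matrix")

    results = []
    test_items: list[tuple[str, np.ndarray]] = []
    if intercept_term is not None:
        test_items.append((intercept_term, np.array([0])))
    test_items += [(name, np.r_[offsets[name]]) for name in blocks]

    # relative tolerance for a numerically zero sum of squares
    tol = 1e-12 * max(1.0, float(y @ y))
    for term, cols in test_items:
        X_r = np.delete(X_full, cols, axis=1)
        sse_r = _sse(X_r, y)
        q = len(cols)
        numerator = max(sse_r - sse_full, 0.0)
        if sse_full <= tol:
            if numerator <= tol:  # degenerate flat response: nothing to explain
                f_value, p_value = 0.0, 1.0
            else:
                raise ValidationError(
                    f"zero residual variance: term {term!r} fits the response exactly"
                )
        else:
            f_value = (numerator / q) / (sse_full / df_den)
            p_value = float(stats.f.sf(f_value, q, df_den))
        results.append(
            ModelResult(
                term=term,
                f_value=float(f_value),
                df_num=q,
                df_den=df_den,
                p_value=p_value,
                significant=p_value < alpha,
            )
        )
    return results


def _rm_fit(
    y_baseline: np.ndarray,
    y_followup: np.ndarray,
    between_blocks: dict[str, np.ndarray],
    alpha: float,
) -> list[ModelResult]:
    """Mean/difference decomposition of a two-timepoint repeated-measures model.

    Between-subject terms keep their names; within-subject copies of each
    term are prefixed ``time:`` and the time main effect is the intercept of
    the difference block.
    """
    y_mean = (y_baseline + y_followup) / 2.0
    y_diff = y_followup - y_baseline
    between = _type3_tests(y_mean, between_blocks, alpha)
    within_blocks = {f"time:{name}": cols for name, cols in between_blocks.items()}
    within = _type3_tests(y_diff, within_blocks, alpha, intercept_term="time")
    return between + within


# ---------------------------------------------------------------------------
# models


class MixedRMAnova:
    """Group (between) x time (within) repeated-measures ANOVA on a dFC measure."""

    def __init__(self, cohort: CohortTable, measure: str, alpha: float = DEFAULT_ALPHA):
        if measure not in DFC_COLUMNS:
            raise ValidationError(f"unknown dFC measure {measure!r}")
        self.cohort = cohort
        self.measure = measure
        self.alpha = alpha

    def fit(self) -> "RMResults":
        bl_col, fu_col = DFC_COLUMNS[self.measure]
        df = self.cohort.df.dropna(subset=[bl_col, fu_col])
        for g in GROUPS:
            if (df["group"] == g).sum() < 3:
                raise ValidationError(f"group {g} has fewer than 3 complete cases")
        groups = df["group"].to_numpy()
        blocks = {"group": _effect_code(groups)}
        results = _rm_fit(
            df[bl_col].to_numpy(float), df[fu_col].to_numpy(float), blocks, self.alpha
        )
        return RMResults(results=results, n_subjects=len(df), dependent=self.measure)


@dataclass(frozen=True)
class AncovaSpec:
    """Specification of the three-way full-factorial repeated-measures ANCOVA.

    ``dependent`` is a cognitive test (two timepoints); ``predictor`` the
    dFC-change measure entering as a continuous between-subject variable that
    may interact with group and time; age and IQ enter as centered covariates.
    """

    dependent: str = "HVLT_IR"
    predictor: str | None = None
    covariates: tuple[str, ...] = ("age", "iq")
    alpha: float = DEFAULT_ALPHA
    #: drop the continuous predictor entirely (reduces the model to the
    #: group-by-time mixed ANOVA plus any covariates)
    include_predictor: bool = True

    def __post_init__(self) -> None:
        if self.dependent not in TESTS:
            raise ValidationError(f"unknown dependent test {self.dependent!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.predictor is None:
            object.__setattr__(self, "predictor", DEFAULT_PREDICTOR[self.dependent])
        if self.predictor not in DFC_COLUMNS:
            raise ValidationError(f"unknown predictor measure {self.predictor!r}")
        for cov in self.covariates:
            if cov not in ("age", "iq"):
                raise ValidationError(f"unknown covariate {cov!r}")


class RepeatedMeasuresANCOVA:
    """Cognition over time as a function of group and dFC change.

    The dependent scores are standardized on the NC baseline (TMT-B
    sign-flipped so lower z = worse) before fitting; F statistics are
    invariant to this affine step but slope signs become comparable across
    tests. ``fit()`` returns an :class:`RMAncovaResults`.
    """

    def __init__(self, cohort: CohortTable, spec: AncovaSpec | None = None):
        self.cohort = cohort
        self.spec = spec if spec is not None else AncovaSpec()

    def _standardized_scores(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        test = self.spec.dependent
        bl_col, fu_col = TEST_COLUMNS[test]
        nc_bl = self.cohort.subset("NC")[bl_col].dropna()
        if len(nc_bl) < 2 or nc_bl.std(ddof=1) == 0:
            raise ValidationError("cannot anchor z-scores: degenerate NC baseline")
        sign = 1.0 if HIGHER_IS_BETTER[test] else -1.0
        mean, sd = float(nc_bl.mean()), float(nc_bl.std(ddof=1))
        z_bl = sign * (df[bl_col].to_numpy(float) - mean) / sd
        z_fu = sign * (df[fu_col].to_numpy(float) - mean) / sd
        return z_bl, z_fu

    def fit(self) -> "RMAncovaResults":
        spec = self.spec
        t_bl, t_fu = TEST_COLUMNS[spec.dependent]
        d_bl, d_fu = DFC_COLUMNS[spec.predictor]
        needed = [t_bl, t_fu, *spec.covariates]
        if spec.include_predictor:
            needed += [d_bl, d_fu]
        df = self.cohort.df
        missing_cols = [c for c in needed if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"cohort lacks columns: {missing_cols}")
        dropped = df[df[needed].isna().any(axis=1)]
        for pid in dropped["participant_id"]:
            logger.info("rm_ancova: excluding %s (incomplete case)", pid)
        df = df.dropna(subset=needed)
        for g in GROUPS:
            if (df["group"] == g).sum() < 3:
                raise ValidationError(f"group {g} has fewer than 3 complete cases")

        groups = df["group"].to_numpy()
        g_code = _effect_code(groups)
        blocks: dict[str, np.ndarray] = {"group": g_code}
        if spec.include_predictor:
            delta = (df[d_fu] - df[d_bl]).to_numpy(float)
            if np.std(delta) == 0:
                raise ValidationError("rank-deficient design: term 'delta_dfc' is constant")
            delta_c = delta - delta.mean()
            blocks["delta_dfc"] = delta_c[:, None]
            blocks["group:delta_dfc"] = g_code * delta_c[:, None]
        else:
            delta = np.full(len(df), np.nan)
        for cov in spec.covariates:
            vals = df[cov].to_numpy(float)
            blocks[cov] = (vals - vals.mean())[:, None]

        z_bl, z_fu = self._standardized_scores(df)
        results = _rm_fit(z_bl, z_fu, blocks, spec.alpha)
        return RMAncovaResults(
            results=results,
            n_subjects=len(df),
            spec=spec,
            frame=pd.DataFrame(
                {
                    "participant_id": df["participant_id"].to_numpy(),
                    "group": groups,
                    "delta_dfc": delta,
                    "z_baseline": z_bl,
                    "z_followup": z_fu,
                }
            ),
        )


class RMResults:
    """ANOVA table from a fitted two-timepoint repeated-measures model."""

    def __init__(self, results: list[ModelResult], n_subjects: int, dependent: str):
        self.results = results
        self.n_subjects = n_subjects
        self.dependent = dependent

    @property
    def anova_table(self) -> pd.DataFrame:
        return results_to_frame(self.results)

    def term(self, name: str) -> ModelResult:
        for r in self.results:
            if r.term == name:
                return r
        raise KeyError(f"no term {name!r} in results")

    def summary(self) -> str:
        header = f"Repeated-measures model: {self.dependent} (n = {self.n_subjects})"
        return header + "\n" + self.anova_table.to_string(index=False)


class RMAncovaResults(RMResults):
    """ANCOVA table plus per-group slope diagnostics and plotting."""

    def __init__(self, results, n_subjects, spec: AncovaSpec, frame: pd.DataFrame):
        super().__init__(results, n_subjects, dependent=spec.dependent)
        self.spec = spec
        self.frame = frame

    def group_slopes(self) -> pd.DataFrame:
        """Per-group OLS slope of cognitive change (z) on dFC change.

        The sign pattern across groups visualizes the inhomogeneity of
        regression slopes that the group x delta-dFC interaction tests.
        """
        rows = []
        if not np.isfinite(self.frame["delta_dfc"]).any():
            return pd.DataFrame(columns=["group", "slope", "intercept", "n"])
        for g in GROUPS:
            sub = self.frame[self.frame["group"] == g]
            if len(sub) < 3:
                continue
            x = sub["delta_dfc"].to_numpy()
            y = (sub["z_followup"] - sub["z_baseline"]).to_numpy()
            slope, intercept = np.polyfit(x, y, 1)
            rows.append({"group": g, "slope": slope, "intercept": intercept, "n": len(sub)})
        return pd.DataFrame(rows)

    def plot_association(self, ax=None):
        """Scatter of cognitive change vs dFC change with per-group fits."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        slopes = self.group_slopes().set_index("group")
        for g in GROUPS:
            sub = self.frame[self.frame["group"] == g]
            if not len(sub):
                continue
            x = sub["delta_dfc"].to_numpy()
            y = (sub["z_followup"] - sub["z_baseline"]).to_numpy()
            pts = ax.plot(x, y, "o", alpha=0.6, label=g)[0]
            if g in slopes.index:
                grid = np.linspace(x.min(), x.max(), 20)
                ax.plot(
                    grid,
                    slopes.loc[g, "intercept"] + slopes.loc[g, "slope"] * grid,
                    "-",
                    color=pts.get_color(),
                )
        ax.set_xlabel(f"change in {self.spec.predictor}")
        ax.set_ylabel(f"change in {self.spec.dependent} (z)")
        ax.legend()
        return ax

    def summary(self) -> str:
        header = (
            f"Repeated-measures ANCOVA: {self.spec.dependent} ~ group x time x "
            f"delta {self.spec.predictor} + {' + '.join(self.spec.covariates)} "
            f"(n = {self.n_subjects}, alpha = {self.spec.alpha})"
        )
        return (
            header
            + "\n"
            + self.anova_table.to_string(index=False)
            + "\n\nPer-group slopes (cognitive change on dFC change):\n"
            + self.group_slopes().to_string(index=False)
        )


# ---------------------------------------------------------------------------
# spec-surface functions


def mixed_anova_dfc(cohort: CohortTable, measure: str, alpha: float = DEFAULT_ALPHA):
    """Group / time / group-by-time effects on one dFC summary measure."""
    return MixedRMAnova(cohort, measure, alpha=alpha).fit().results


def rm_ancova(cohort: CohortTable, spec: AncovaSpec | None = None):
    """Three-way full-factorial repeated-measures ANCOVA; see AncovaSpec."""
    return RepeatedMeasuresANCOVA(cohort, spec).fit().results
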