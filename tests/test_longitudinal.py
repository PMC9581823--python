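import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dfckit as dk
from dfckit.datatypes import ValidationError
from dfckit.longitudinal import _effect_code


def _cohort_from(df):
    return dk.CohortTable(pd.DataFrame(df))


@pytest.fixture
def balanced_fixture():
    """12-subject balanced cohort with random dFC values at both timepoints."""
    rng = np.random.default_rng(21)
    n = 12
    return _cohort_from(
        {
            "participant_id": [f"S{i}" for i in range(n)],
            "group": np.repeat(["BCC_PLUS", "BCC_MINUS", "NC"], 4),
            "age": rng.normal(50, 9, n),
            "iq": rng.normal(104, 13, n),
            "dmn_dfc_bl": np.abs(rng.normal(0.3, 0.05, n)),
            "dmn_dfc_fu": np.abs(rng.normal(0.3, 0.05, n)),
        }
    )


class TestDeltaScores:
    def test_direct_subtraction(self, tiny_cohort_frame):
        cohort = dk.CohortTable(tiny_cohort_frame)
        deltas = dk.delta_scores(cohort, "DMN_dFC")
        assert deltas.loc[0, "delta"] == pytest.approx(0.35 - 0.30, abs=1e-12)

    def test_identical_timepoints(self, tiny_cohort_frame):
        tiny_cohort_frame["dmn_dfc_fu"] = tiny_cohort_frame["dmn_dfc_bl"]
        deltas = dk.delta_scores(dk.CohortTable(tiny_cohort_frame), "DMN_dFC")
        assert (deltas["delta"] == 0).all()

    def test_antisymmetry_under_timepoint_swap(self, tiny_cohort_frame):
        cohort = dk.CohortTable(tiny_cohort_frame)
        swapped_frame = tiny_cohort_frame.rename(
            columns={"dmn_dfc_bl": "dmn_dfc_fu", "dmn_dfc_fu": "dmn_dfc_bl"}
        )
        swapped = dk.CohortTable(swapped_frame)
        np.testing.assert_allclose(
            dk.delta_scores(cohort, "DMN_dFC")["delta"],
            -dk.delta_scores(swapped, "DMN_dFC")["delta"],
        )

    def test_missing_timepoint_excluded(self, tiny_cohort_frame, caplog):
        tiny_cohort_frame.loc[2, "dmn_dfc_fu"] = np.nan
        with caplog.at_level("INFO"):
            deltas = dk.delta_scores(dk.CohortTable(tiny_cohort_frame), "DMN_dFC")
        assert len(deltas) == 5 and "S2" in caplog.text


class TestMixedAnova:
    def test_flat_cohort_all_f_zero(self):
        n = 12
        cohort = _cohort_from(
            {
                "participant_id": [f"S{i}" for i in range(n)],
                "group": np.repeat(["BCC_PLUS", "BCC_MINUS", "NC"], 4),
                "age": 50.0,
                "iq": 100.0,
                "dmn_dfc_bl": 0.3,
                "dmn_dfc_fu": 0.3,
            }
        )
        results = dk.mixed_anova_dfc(cohort, "DMN_dFC")
        assert all(r.f_value == 0.0 and not r.significant for r in results)

    def test_pure_time_shift_detected(self):
        # uniform increase in modulation depth over time, no group structure
        cfg = dk.SimulationConfig(
            n_per_group={"BCC_PLUS": 30, "BCC_MINUS": 30, "NC": 30},
            modulation_depth={g: (0.1, 0.3) for g in dk.GROUPS},
            seed=31,
        )
        cohort = dk.simulate_cohort_scores(cfg).cohort
        results = {r.term: r for r in dk.mixed_anova_dfc(cohort, "DMN_dFC")}
        assert results["time"].significant
        assert not results["group"].significant
        assert not results["time:group"].significant

    def test_matches_long_format_glm_oracle(self, balanced_fixture):
        mine = {r.term: r for r in dk.mixed_anova_dfc(balanced_fixture, "DMN_dFC")}
        df = balanced_fixture.df
        y_bl = df["dmn_dfc_bl"].to_numpy()
        y_fu = df["dmn_dfc_fu"].to_numpy()
        n = len(df)

        # group: one-way ANOVA on subject means, explicit sums of squares
        means = (y_bl + y_fu) / 2
        grand = means.mean()
        ss_between = sum(
            (df["group"] == g).sum() * (means[df["group"] == g].mean() - grand) ** 2
            for g in dk.GROUPS
        )
        ss_within = sum(
            ((means[df["group"] == g] - means[df["group"] == g].mean()) ** 2).sum()
            for g in dk.GROUPS
        )
        f_group = (ss_between / 2) / (ss_within / (n - 3))
        assert mine["group"].f_value == pytest.approx(f_group, abs=1e-8)

        # time and time:group: long-format GLM with subject indicators
        y_long = np.concatenate([y_bl, y_fu])
        subj = np.vstack([np.eye(n), np.eye(n)])
        time_code = np.concatenate([-0.5 * np.ones(n), 0.5 * np.ones(n)])
        g_long = np.vstack([_effect_code(df["group"].to_numpy())] * 2)
        X_full = np.column_stack([subj, time_code, time_code[:, None] * g_long])

        def sse(X):
            beta, *_ = np.linalg.lstsq(X, y_long, rcond=None)
            r = y_long - X @ beta
            return float(r @ r)

        sse_full = sse(X_full)
        df_den = 2 * n - np.linalg.matrix_rank(X_full)
        for term, cols, q in (("time", [n], 1), ("time:group", [n + 1, n + 2], 2)):
            sse_r = sse(np.delete(X_full, cols, axis=1))
            f_oracle = ((sse_r - sse_full) / q) / (sse_full / df_den)
            assert mine[term].f_value == pytest.approx(f_oracle, abs=1e-8)
            assert mine[term].df_den == df_den

    def test_matches_pingouin(self, balanced_fixture):
        pg = pytest.importorskip("pingouin")
        df = balanced_fixture.df
        long = pd.DataFrame(
            {
                "id": np.tile(df["participant_id"], 2),
                "group": np.tile(df["group"], 2),
                "time": np.repeat(["bl", "fu"], len(df)),
                "y": np.concatenate([df["dmn_dfc_bl"], df["dmn_dfc_fu"]]),
            }
        )
        table = pg.mixed_anova(
            data=long, dv="y", within="time", subject="id", between="group"
        ).set_index("Source")
        mine = {r.term: r for r in dk.mixed_anova_dfc(balanced_fixture, "DMN_dFC")}
        assert mine["group"].f_value == pytest.approx(table.loc["group", "F"], abs=1e-8)
        assert mine["time"].f_value == pytest.approx(table.loc["time", "F"], abs=1e-8)
        assert mine["time:group"].f_value == pytest.approx(
            table.loc["Interaction", "F"], abs=1e-8
        )

    def test_small_group_error(self, tiny_cohort_frame):
        with pytest.raises(ValidationError, match="fewer than 3"):
            dk.mixed_anova_dfc(dk.CohortTable(tiny_cohort_frame), "DMN_dFC")


class TestRMAncova:
    def test_between_and_within_match_statsmodels_type3(self, reversal_cohort):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        from dfckit.datatypes import TEST_COLUMNS, DFC_COLUMNS
        from dfckit.longitudinal import RepeatedMeasuresANCOVA

        fitted = RepeatedMeasuresANCOVA(reversal_cohort).fit()
        mine = {r.term: r for r in fitted.results}

        df = reversal_cohort.df
        # the engine standardizes scores on NC baseline; reproduce that here
        nc = df[df["group"] == "NC"]["hvlt_bl"]
        z_bl = (df["hvlt_bl"] - nc.mean()) / nc.std(ddof=1)
        z_fu = (df["hvlt_fu"] - nc.mean()) / nc.std(ddof=1)
        delta = df["dmn_dfc_fu"] - df["dmn_dfc_bl"]
        frame = pd.DataFrame(
            {
                "mean_score": (z_bl + z_fu) / 2,
                "diff_score": z_fu - z_bl,
                "group": df["group"],
                "delta": delta - delta.mean(),
                "age": df["age"] - df["age"].mean(),
                "iq": df["iq"] - df["iq"].mean(),
            }
        )
        formula = "{dv} ~ C(group, Sum) * delta + age + iq"
        oracle_between = anova_lm(
            smf.ols(formula.format(dv="mean_score"), data=frame).fit(), typ=3
        )
        oracle_within = anova_lm(
            smf.ols(formula.format(dv="diff_score"), data=frame).fit(), typ=3
        )
        pairs = [
            ("group", "C(group, Sum)", oracle_between),
            ("delta_dfc", "delta", oracle_between),
            ("group:delta_dfc", "C(group, Sum):delta", oracle_between),
            ("age", "age", oracle_between),
            ("iq", "iq", oracle_between),
            ("time", "Intercept", oracle_within),
            ("time:group", "C(group, Sum)", oracle_within),
            ("time:delta_dfc", "delta", oracle_within),
            ("time:group:delta_dfc", "C(group, Sum):delta", oracle_within),
            ("time:age", "age", oracle_within),
            ("time:iq", "iq", oracle_within),
        ]
        for term, oracle_term, oracle in pairs:
            assert mine[term].f_value == pytest.approx(
                oracle.loc[oracle_term, "F"], abs=1e-8
            ), term

    def test_error_df_at_study_size(self, reversal_cohort):
        results = dk.rm_ancova(reversal_cohort)
        # n=101 complete cases, 8 between-design parameters -> 93 residual df
        assert all(r.df_den == 93 for r in results)

    def test_reduces_to_mixed_anova_without_predictor(self, balanced_fixture):
        # alias the cognitive columns to the dFC values: the reduced ANCOVA
        # must reproduce the mixed ANOVA F values (z-scoring is affine)
        df = balanced_fixture.df.copy()
        df["hvlt_bl"] = df["dmn_dfc_bl"]
        df["hvlt_fu"] = df["dmn_dfc_fu"]
        cohort = dk.CohortTable(df)
        spec = dk.AncovaSpec(dependent="HVLT_IR", covariates=(), include_predictor=False)
        reduced = {r.term: r for r in dk.rm_ancova(cohort, spec)}
        mixed = {r.term: r for r in dk.mixed_anova_dfc(cohort, "DMN_dFC")}
        for term in ("group", "time", "time:group"):
            assert reduced[term].f_value == pytest.approx(mixed[term].f_value, abs=1e-8)
            assert reduced[term].df_den == mixed[term].df_den

    def test_permutation_invariance(self, reversal_cohort):
        shuffled = dk.CohortTable(
            reversal_cohort.df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        )
        a = dk.results_to_frame(dk.rm_ancova(reversal_cohort))
        b = dk.results_to_frame(dk.rm_ancova(shuffled))
        pd.testing.assert_frame_equal(a, b)

    def test_invariant_to_affine_covariate_rescaling(self, reversal_cohort):
        rescaled_df = reversal_cohort.df.copy()
        rescaled_df["age"] = 12.0 * rescaled_df["age"] - 100.0
        rescaled_df["iq"] = -0.5 * rescaled_df["iq"] + 3.0
        rescaled = dk.CohortTable(rescaled_df)
        a = dk.rm_ancova(reversal_cohort)
        b = dk.rm_ancova(rescaled)
        for ra, rb in zip(a, b):
            assert ra.f_value == pytest.approx(rb.f_value, rel=1e-8)

    def test_constant_predictor_named_in_error(self, balanced_fixture):
        df = balanced_fixture.df.copy()
        df["hvlt_bl"], df["hvlt_fu"] = 20.0 + df["dmn_dfc_bl"], 20.0 + df["dmn_dfc_fu"]
        df["dmn_dfc_fu"] = df["dmn_dfc_bl"] + 0.05  # constant delta
        with pytest.raises(ValidationError, match="delta_dfc"):
            dk.rm_ancova(dk.CohortTable(df))

    def test_slope_sign_reversal_recovered(self, reversal_cohort):
        from dfckit.longitudinal import RepeatedMeasuresANCOVA

        fitted = RepeatedMeasuresANCOVA(reversal_cohort).fit()
        # slope heterogeneity loads on the interaction, not the main effect
        # (detection rates at alpha=0.01 are covered by the power test)
        interaction = fitted.term("group:delta_dfc")
        assert interaction.f_value > fitted.term("group").f_value
        slopes = fitted.group_slopes().set_index("group")["slope"]
        assert slopes["BCC_MINUS"] > 0
        assert slopes["BCC_PLUS"] < 0 and slopes["NC"] < 0

    def test_default_predictor_pairing(self):
        assert dk.AncovaSpec(dependent="HVLT_IR").predictor == "DMN_dFC"
        assert dk.AncovaSpec(dependent="TMTB").predictor == "FPN_dFC"
        with pytest.raises(ValidationError):
            dk.AncovaSpec(dependent="HVLT_IR", alpha=1.5)

    def test_summary_and_plot(self, reversal_cohort):
        import matplotlib

        matplotlib.use("Agg")
        from dfckit.longitudinal import RepeatedMeasuresANCOVA

        fitted = RepeatedMeasuresANCOVA(reversal_cohort).fit()
        text = fitted.summary()
        assert "group:delta_dfc" in text and "slopes" in text.lower()
        ax = fitted.plot_association()
        assert ax.get_xlabel().startswith("change in")
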