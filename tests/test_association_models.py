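"""GEE / logistic / linear / tertile models: identities and edge cases."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import merge_embryo_oocyte
from ovoscore.association_models import (
    DegenerateOutcomeError,
    ModelSpec,
    TertileResult,
    assign_tertiles,
    fit_gee_binary,
    fit_gee_ordinal,
    fit_mean_grade_linear,
    fit_pregnancy_logistic,
    or_to_percent,
    tertile_implantation,
)
from ovoscore.oocyte_scoring import ValidationError
from ovoscore.synthetic_data import CohortConfig, generate_cohort


class TestGeeBinary:
    def test_independence_equals_plain_logistic(self, default_merged):
        """GEE point estimates with independence working correlation equal
        the ordinary logistic MLE (robust SEs differ)."""
        fit = fit_gee_binary(default_merged, ModelSpec(
            outcome="eight_cell", predictors=["tos"],
            working_correlation="independence"))
        mle = sm.Logit(default_merged["eight_cell"],
                       sm.add_constant(default_merged["tos"].astype(float))
                       ).fit(disp=0)
        assert fit.term("tos")["estimate"] == pytest.approx(
            mle.params["tos"], abs=1e-6)
        assert fit.extras["intercept"] == pytest.approx(
            mle.params["const"], abs=1e-6)

    def test_singleton_clusters_degenerate_to_logistic(self, default_merged):
        """With every cluster of size 1, exchangeable GEE is plain logistic."""
        df = default_merged.copy()
        df["patient_id"] = np.arange(len(df)).astype(str)
        fit = fit_gee_binary(df, ModelSpec(
            outcome="eight_cell", predictors=["tos"],
            working_correlation="exchangeable"))
        mle = sm.Logit(df["eight_cell"],
                       sm.add_constant(df["tos"].astype(float))).fit(disp=0)
        assert fit.term("tos")["estimate"] == pytest.approx(
            mle.params["tos"], abs=1e-6)

    def test_constant_outcome_raises(self, default_merged):
        df = default_merged.assign(eight_cell=1)
        with pytest.raises(DegenerateOutcomeError):
            fit_gee_binary(df, ModelSpec(outcome="eight_cell", predictors=["tos"]))

    def test_categorical_reference_is_worst_level(self, default_merged):
        fit = fit_gee_binary(default_merged, ModelSpec(
            outcome="eight_cell", predictors=["morphology_score"],
            categorical=["morphology_score"]))
        levels = set(fit.terms["level"])
        assert levels == {0, 1}  # both ORs relative to the -1 reference

    def test_recoding_reference_changes_or_by_exact_ratio(self, default_merged):
        spec_m1 = ModelSpec(outcome="eight_cell", predictors=["morphology_score"],
                            categorical=["morphology_score"],
                            working_correlation="independence")
        fit_m1 = fit_gee_binary(default_merged, spec_m1)
        fit_0 = fit_gee_binary(default_merged, ModelSpec(
            outcome="eight_cell", predictors=["morphology_score"],
            categorical=["morphology_score"], reference_level=0,
            working_correlation="independence"))
        or_1_vs_m1 = fit_m1.term("morphology_score", 1)["or"]
        or_0_vs_m1 = fit_m1.term("morphology_score", 0)["or"]
        or_1_vs_0 = fit_0.term("morphology_score", 1)["or"]
        assert or_1_vs_0 == pytest.approx(or_1_vs_m1 / or_0_vs_m1, rel=1e-5)

    def test_or_and_ci_consistency(self, default_merged):
        fit = fit_gee_binary(default_merged, ModelSpec(
            outcome="eight_cell", predictors=["tos"], adjust_age=True))
        row = fit.term("tos")
        assert row["or"] == pytest.approx(np.exp(row["estimate"]))
        assert row["ci_low"] < row["estimate"] < row["ci_high"]
        assert row["or"] > 0
        assert 0 < row["p"] <= 1
        assert fit.adjustment == "age"
        assert fit.n_clusters == default_merged["patient_id"].nunique()


class TestGeeOrdinal:
    def test_two_level_collapse_matches_binary(self, default_merged):
        """Proportional-odds with two grade levels is binary logistic."""
        df = default_merged.assign(grade2=(default_merged["grade"] >= 4).astype(int))
        ordinal = fit_gee_ordinal(df, ModelSpec(outcome="grade2", predictors=["tos"]))
        binary = fit_gee_binary(df, ModelSpec(
            outcome="grade2", predictors=["tos"],
            working_correlation="independence"))
        assert ordinal.term("tos")["estimate"] == pytest.approx(
            binary.term("tos")["estimate"], abs=1e-6)

    def test_single_level_grade_raises(self, default_merged):
        df = default_merged.assign(grade=3)
        with pytest.raises(DegenerateOutcomeError):
            fit_gee_ordinal(df, ModelSpec(outcome="grade", predictors=["tos"]))

    def test_constant_predictor_yields_null_slope(self, default_merged):
        df = default_merged.assign(flat=1.0)
        fit = fit_gee_ordinal(df, ModelSpec(outcome="grade", predictors=["flat"]))
        row = fit.term("flat")
        assert row["estimate"] == pytest.approx(0.0, abs=1e-6)
        assert not np.isfinite(row["se"])  # unidentifiable: infinite SE


class TestPregnancyLogistic:
    def test_null_data_covers_one(self, rng):
        n = 5000
        cycles = pd.DataFrame({
            "patient_id": np.arange(n).astype(str),
            "ptos": rng.normal(size=n), "age": rng.normal(36, 5, n),
            "pregnancy": rng.integers(0, 2, n),
        })
        fit = fit_pregnancy_logistic(cycles)
        row = fit.term("ptos")
        assert np.exp(row["ci_low"]) <= 1.0 <= np.exp(row["ci_high"])

    def test_restricted_subset(self, default_cohort):
        fit = fit_pregnancy_logistic(default_cohort.cycles, adjust_age=True,
                                     eight_cell_transfers_only=True)
        assert fit.extras["subset"] == "eight_cell_transfers"
        assert fit.n_obs == int(
            default_cohort.cycles["all_transferred_eight_cell"].sum())

    def test_missing_restriction_column_rejected(self, default_cohort):
        cycles = default_cohort.cycles.drop(columns=["all_transferred_eight_cell"])
        with pytest.raises(ValidationError):
            fit_pregnancy_logistic(cycles, eight_cell_transfers_only=True)

    def test_or_to_percent_phrasing(self):
        assert or_to_percent(1.12) == "+12% odds per point"
        assert or_to_percent(0.8) == "-20% odds per point"


class TestMeanGradeLinear:
    def test_identity_construction_recovers_slope_one(self, rng):
        n = 200
        cycles = pd.DataFrame({
            "patient_id": np.arange(n).astype(str),
            "ptos": rng.normal(size=n), "age": rng.normal(36, 5, n),
        })
        cycles["mean_grade_available"] = cycles["ptos"]
        fit = fit_mean_grade_linear(cycles)
        assert fit.term("ptos")["estimate"] == pytest.approx(1.0, abs=1e-10)
        assert fit.extras["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_permuted_ptos_covers_zero(self, default_cohort, rng):
        cycles = default_cohort.cycles.copy()
        cycles["ptos"] = rng.permutation(cycles["ptos"].to_numpy())
        fit = fit_mean_grade_linear(cycles)
        row = fit.term("ptos")
        assert row["ci_low"] <= 0.0 <= row["ci_high"]

    def test_positive_link_in_default_cohort(self):
        c = generate_cohort(CohortConfig(n_patients=500, seed=21))
        fit = fit_mean_grade_linear(c.cycles)
        row = fit.term("ptos")
        assert row["estimate"] > 0
        assert row["p"] < 0.05

    def test_too_few_cycles_rejected(self):
        cycles = pd.DataFrame({"patient_id": ["a"], "ptos": [1.0],
                               "age": [35.0], "mean_grade_available": [4.0]})
        with pytest.raises(ValidationError):
            fit_mean_grade_linear(cycles)


class TestTertiles:
    def test_nine_distinct_cycles_split_three_three_three(self):
        cycles = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(9)],
            "ptos": np.linspace(-3, 3, 9), "age": 35.0,
            "sacs": [0, 0, 0, 0, 1, 0, 1, 2, 2],
            "n_transferred": 2,
        })
        res = tertile_implantation(cycles)
        assert list(res.rates["n_cycles"]) == [3, 3, 3]

    def test_tertile_labels_monotone_in_ptos(self, default_cohort):
        cycles = default_cohort.cycles
        labels = assign_tertiles(cycles)
        by_label = cycles.groupby(labels)["ptos"]
        assert by_label.max()[1] <= by_label.min()[2]
        assert by_label.max()[2] <= by_label.min()[3]

    def test_all_zero_sacs_flagged_degenerate(self):
        cycles = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(6)],
            "ptos": np.arange(6.0), "age": 35.0,
            "sacs": 0, "n_transferred": 2,
        })
        res = tertile_implantation(cycles)
        assert isinstance(res, TertileResult)
        assert res.degenerate
        assert res.p_overall == 1.0
        assert (res.rates["implantation_rate"] == 0).all()

    def test_strong_link_puts_top_tertile_first(self):
        c = generate_cohort(CohortConfig(n_patients=300, seed=13,
                                         or_ptos_pregnancy=3.0))
        res = tertile_implantation(c.cycles)
        rates = res.rates["implantation_rate"].to_numpy()
        assert rates[2] == rates.max()
        assert res.p_overall < 0.05

    def test_quantile_mode_available(self, default_cohort):
        labels = assign_tertiles(default_cohort.cycles, mode="quantile")
        assert set(labels) <= {1, 2, 3}

    def test_too_few_cycles_rejected(self, default_cohort):
        with pytest.raises(ValidationError):
            tertile_implantation(default_cohort.cycles.head(2))


def test_multivariate_six_characteristic_model_runs(default_merged):
    cols = ["morphology_score", "size_score", "cytoplasm_score",
            "pvs_score", "zp_score", "pb_score"]
    fit = fit_gee_binary(default_merged, ModelSpec(
        outcome="eight_cell", predictors=cols, categorical=cols,
        adjust_age=True))
    assert set(fit.terms["term"]) == set(cols) | {"age"}
    assert fit.converged
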