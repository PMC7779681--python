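"""Imputation, knee selection, binning, cross-cohort matching, denoisers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from koaprog.cohort import Cohort, CovariateSchema
from koaprog.preprocess import (
    BinningScheme,
    ImputationError,
    OutOfRangeError,
    age_binning,
    bin_variable,
    bmi_binning,
    fit_denoiser,
    impute_predictive_mean,
    match_impute_cross_cohort,
    select_index_knee,
)
from koaprog.synthetic import inject_missingness


class TestBinning:
    @pytest.mark.parametrize(
        "value,label",
        [(27.4, "overweight"), (22.0, "normal"), (15.0, "underweight"),
         (36.0, "obese"), (47.0, "morbidly_obese")],
    )
    def test_bmi_scheme(self, value, label):
        assert bin_variable(pd.Series([value]), bmi_binning())[0] == label

    @pytest.mark.parametrize("value,label", [(72, "70-74"), (45, "45-49"), (79.9, "75-79")])
    def test_age_scheme(self, value, label):
        assert bin_variable(pd.Series([value]), age_binning())[0] == label

    def test_empty_series(self):
        out = bin_variable(pd.Series([], dtype=float), bmi_binning())
        assert len(out) == 0

    def test_out_of_range_lists_rows(self):
        with pytest.raises(OutOfRangeError, match="rows"):
            bin_variable(pd.Series([22.0, 5.0]), bmi_binning())

    @given(st.lists(st.floats(min_value=45, max_value=79.99), min_size=1, max_size=50))
    @settings(max_examples=25, deadline=None)
    def test_partition_property(self, values):
        # every in-range value maps to exactly one label; counts sum to n
        out = bin_variable(pd.Series(values), age_binning())
        assert out.notna().all()
        assert out.value_counts().sum() == len(values)

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            BinningScheme("x", [1, 1, 2], ["a", "b"], "a")
        with pytest.raises(ValueError):
            BinningScheme("x", [1, 2, 3], ["a", "b"], "zz")


class TestSelectIndexKnee:
    @pytest.mark.parametrize(
        "left,right,expected",
        [(2, 3, "right"), (4, 0, "left"), (2, 2, "right"), (0, 0, "right")],
    )
    def test_higher_grade_wins_tie_to_right(self, left, right, expected):
        assert select_index_knee(left, right) == expected

    def test_invalid_grade(self):
        with pytest.raises(ValueError):
            select_index_knee(5, 2)


class TestPredictiveMeanImputation:
    def test_complete_cohort_unchanged(self, small_cohort):
        out = impute_predictive_mean(small_cohort, k_donors=5, seed=1)
        assert out.data.equals(small_cohort.data)

    def test_single_missing_cell_matches_bruteforce_nearest_donor(self):
        rng = np.random.default_rng(2)
        n = 60
        x = rng.normal(size=n)
        y = 2 * x + rng.normal(0, 0.1, size=n)
        df = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)], "visit": 0, "kl": 1.0,
             "x": x, "y": y}
        )
        df.loc[7, "y"] = np.nan
        schema = {"x": CovariateSchema("x", "continuous"), "y": CovariateSchema("y", "continuous")}
        out = impute_predictive_mean(Cohort(df, schema), k_donors=1, seed=0)
        # brute-force oracle: OLS of y on (1, x) over observed rows, then
        # the observed y whose prediction is nearest row 7's prediction
        obs = df["y"].notna()
        X = np.column_stack([np.ones(obs.sum()), x[obs]])
        beta, *_ = np.linalg.lstsq(X, df.loc[obs, "y"], rcond=None)
        pred = beta[0] + beta[1] * x
        donor = np.argmin(np.abs(pred[obs.to_numpy()] - pred[7]))
        expected = df.loc[obs, "y"].to_numpy()[donor]
        assert out.data.loc[7, "y"] == expected

    def test_imputed_values_stay_in_observed_support(self, small_cohort):
        holey = inject_missingness(small_cohort, 0.15, seed=9)
        out = impute_predictive_mean(holey, k_donors=5, seed=9)
        assert not out.data[out.covariates].isna().any().any()
        for c in out.covariates:
            observed = set(holey.data[c].dropna())
            assert set(out.data[c]) <= observed

    def test_ordinal_cells_get_modal_donor(self, small_cohort):
        holey = inject_missingness(small_cohort, 0.2, seed=13)
        out = impute_predictive_mean(holey, k_donors=5, seed=13)
        for c in out.ordinal_covariates():
            levels = set(small_cohort.schema[c].levels)
            assert set(out.data[c].unique()) <= levels

    def test_fully_missing_covariate_named_in_error(self, small_cohort):
        broken = small_cohort.copy()
        broken.data["pain"] = np.nan
        with pytest.raises(ImputationError, match="pain"):
            impute_predictive_mean(broken)

    def test_mean_method_fills_with_prediction(self, small_cohort):
        holey = inject_missingness(small_cohort, 0.1, seed=17)
        out = impute_predictive_mean(holey, k_donors=5, seed=17, method="mean")
        assert not out.data[out.covariates].isna().any().any()


class TestCrossCohortMatching:
    def _pair(self):
        target = Cohort(
            pd.DataFrame(
                {"patient_id": ["A", "B", "C"], "visit": 0, "kl": 1.0,
                 "age_bin": ["50-54", "55-59", "60-64"],
                 "bmi_bin": ["normal", "normal", "obese"]}
            ),
            {},
        )
        donor = Cohort(
            pd.DataFrame(
                {"patient_id": [f"D{i}" for i in range(5)], "visit": 0, "kl": 0.0,
                 "age_bin": ["50-54", "55-59", "55-59", "55-59", "70-74"],
                 "bmi_bin": ["normal"] * 5,
                 "pulse": [61.0, 1.0, 2.0, 3.0, 99.0]}
            ),
            {"pulse": CovariateSchema("pulse", "continuous")},
        )
        return target, donor

    def test_single_match_copies_multiple_matches_average(self, caplog):
        target, donor = self._pair()
        out = match_impute_cross_cohort(target, donor, new_vars=["pulse"])
        vals = out.data.set_index("patient_id")["pulse"]
        assert vals["A"] == 61.0  # unique match copied verbatim
        assert vals["B"] == 2.0  # mean of 1, 2, 3
        assert np.isnan(vals["C"])  # no (60-64, obese) donor

    def test_unmatched_patient_logged(self, caplog):
        target, donor = self._pair()
        with caplog.at_level("WARNING"):
            match_impute_cross_cohort(target, donor, new_vars=["pulse"])
        assert any("C" in rec.getMessage() for rec in caplog.records)

    def test_idempotent_for_fixed_donor(self):
        target, donor = self._pair()
        once = match_impute_cross_cohort(target, donor, new_vars=["pulse"])
        twice = match_impute_cross_cohort(once, donor, new_vars=["pulse"])
        assert once.data["pulse"].equals(twice.data["pulse"])

    def test_unknown_new_var_rejected(self):
        target, donor = self._pair()
        with pytest.raises(ValueError, match="ghost"):
            match_impute_cross_cohort(target, donor, new_vars=["ghost"])


class TestDenoisers:
    def test_pca_full_rank_reconstructs_exactly(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 4)) @ rng.normal(size=(4, 4))
        model = fit_denoiser(X, "pca", latent_dim=3)
        # rank-3 signal embedded in 4 columns
        X3 = X.copy()
        X3[:, 3] = X3[:, :3].sum(axis=1)
        m3 = fit_denoiser(X3, "pca", latent_dim=3)
        assert m3.reconstruction_error(X3) < 1e-20
        assert model.latent_dim == 3

    def test_pca_aligns_with_varying_column(self):
        # one column constant: the single component must load on the other
        X = np.column_stack([np.linspace(-2, 2, 30), np.full(30, 7.0)])
        model = fit_denoiser(X, "pca", latent_dim=1)
        assert abs(abs(model.components_[0, 0]) - 1.0) < 1e-12
        assert abs(model.components_[0, 1]) < 1e-12
        assert model.reconstruction_error(X) < 1e-20

    def test_pca_error_monotone_in_latent_dim(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 6))
        errs = [fit_denoiser(X, "pca", latent_dim=k).reconstruction_error(X)
                for k in range(1, 6)]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_autoencoder_descends(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 5)) @ rng.normal(size=(5, 5))
        model = fit_denoiser(X, "autoencoder", latent_dim=2, seed=1, epochs=200)
        assert model.history[-1] <= model.history[0]
        assert np.isfinite(model.history).all()

    def test_latent_dim_bounds(self):
        X = np.random.default_rng(6).normal(size=(20, 3))
        with pytest.raises(ValueError):
            fit_denoiser(X, "pca", latent_dim=3)
        with pytest.raises(ValueError):
            fit_denoiser(np.where(X > 2, np.nan, X), "pca", latent_dim=1)
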