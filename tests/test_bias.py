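"""Bias-model fitting, inversion, and CV selection."""

import numpy as np
import pandas as pd
import pytest

from brainpad.bias import (
    BiasModelFit,
    BiasModelSpec,
    CorrectionError,
    FitError,
    MARGINAL_LEVEL,
    aggregate_slices,
    correct_ages,
    fit_bias_model,
    naive_correct,
    select_bias_model_cv,
)
from brainpad.cohort import build_cohort, generate_predictions, generate_null_predictions
from brainpad.splits import StrataSpec, make_cv_folds, stratified_split
from conftest import homogeneous_config, noiseless_config


def records_from(ages, preds, modality="MPRAGE", scanner="Aera"):
    n = len(ages)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(n)],
            "age": ages,
            "sex": ["F"] * n,
            "modality": modality if isinstance(modality, list) else [modality] * n,
            "scanner": [scanner] * n,
            "repetition": [1] * n,
            "brain_age_pred": preds,
        }
    )


class TestAggregateSlices:
    def test_identical_values(self):
        assert aggregate_slices([50.0] * 80) == 50.0

    def test_odd_length_median(self):
        assert aggregate_slices([40, 50, 60]) == 50.0

    def test_even_length_midpoint(self):
        assert aggregate_slices([40, 50, 60, 70]) == 55.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_slices([])

    def test_noisy_slices_concentrate(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(50, 5, size=80)
        assert abs(aggregate_slices(vals) - 50) < 3 * 5 / np.sqrt(80)


class TestFitBiasModel:
    def test_collinear_points_give_printed_line(self):
        rec = records_from([20.0, 50.0, 80.0], [29.2, 50.2, 71.2])
        fit = fit_bias_model(rec, BiasModelSpec("marginal"))
        a, b = fit.coefficients[MARGINAL_LEVEL]
        assert a == pytest.approx(15.2, abs=1e-10)
        assert b == pytest.approx(0.7, abs=1e-12)

    def test_identity_predictions(self):
        ages = np.linspace(20, 80, 7)
        fit = fit_bias_model(records_from(ages, ages), BiasModelSpec("marginal"))
        a, b = fit.coefficients[MARGINAL_LEVEL]
        assert a == pytest.approx(0.0, abs=1e-10)
        assert b == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations(self, seed):
        """OLS and group-WLS coefficients equal the normal-equation solutions
        computed independently on tiny instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        ages = rng.uniform(20, 90, n)
        preds = rng.normal(15 + 0.7 * ages, 5)
        mods = list(rng.choice(["A", "B"], size=n))
        rec = records_from(ages, preds, modality=mods)

        fit = fit_bias_model(rec, BiasModelSpec("marginal"))
        X = np.column_stack([np.ones(n), ages])
        beta = np.linalg.solve(X.T @ X, X.T @ preds)
        np.testing.assert_allclose(
            fit.coefficients[MARGINAL_LEVEL], beta, rtol=1e-9
        )

        wspec = BiasModelSpec("marginal", "WLS", "modality")
        wfit = fit_bias_model(rec, wspec)
        counts = pd.Series(mods).value_counts()
        w = np.array([1.0 / counts[m] for m in mods])
        Xw = X * w[:, None]
        beta_w = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (preds * w))
        np.testing.assert_allclose(
            wfit.coefficients[MARGINAL_LEVEL], beta_w, rtol=1e-8
        )

    def test_by_modality_levels_and_coefficient_count(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(20, 90, 40)
        mods = ["A"] * 20 + ["B"] * 20
        rec = records_from(ages, 10 + 0.5 * ages, modality=mods)
        fit = fit_bias_model(rec, BiasModelSpec("by_modality"))
        assert set(fit.coefficients) == {"A", "B"}
        assert fit.n_coefficients == 4

    def test_small_level_flagged_unfittable(self):
        ages = np.array([20.0, 40, 60, 80, 30])
        mods = ["A", "A", "A", "A", "B"]
        rec = records_from(ages, 10 + ages, modality=mods)
        fit = fit_bias_model(rec, BiasModelSpec("by_modality"))
        assert fit.unfittable == ["B"]
        assert set(fit.coefficients) == {"A"}

    def test_zero_age_variance_raises(self):
        rec = records_from([50.0, 50.0, 50.0], [48.0, 52.0, 50.0])
        with pytest.raises(FitError):
            fit_bias_model(rec, BiasModelSpec("marginal"))

    def test_parameter_recovery_at_study_scale(self):
        """A bias-estimation-sized sample (186 participants, ~841 scans,
        noise on) recovers the generating intercept and slope within a
        generous sampling interval."""
        cfg = homogeneous_config(seed=77)
        cohort = generate_predictions(build_cohort(cfg), cfg)
        fit = fit_bias_model(cohort, BiasModelSpec("marginal"))
        a, b = fit.coefficients[MARGINAL_LEVEL]
        assert a == pytest.approx(15.2, abs=3.0)
        assert b == pytest.approx(0.7, abs=0.06)


class TestCorrectAges:
    def test_point_inversions(self):
        fit = BiasModelFit(BiasModelSpec("marginal"),
                           {MARGINAL_LEVEL: (15.2, 0.7)})
        rec = records_from([50.0, 50.0], [15.2, 50.2])
        out = correct_ages(rec, fit)
        assert out[0] == pytest.approx(0.0)
        assert out[1] == pytest.approx(50.0)

    def test_unseen_level_uses_mean_coefficients(self):
        fit = BiasModelFit(BiasModelSpec("by_modality"),
                           {"A": (10.0, 0.5), "B": (20.0, 0.9)})
        rec = records_from([40.0], [29.0], modality=["C"])
        assert correct_ages(rec, fit)[0] == pytest.approx(20.0)

    def test_zero_slope_rejected(self):
        fit = BiasModelFit(BiasModelSpec("marginal"), {MARGINAL_LEVEL: (10.0, 0.0)})
        with pytest.raises(CorrectionError):
            correct_ages(records_from([40.0], [29.0]), fit)

    def test_inverse_identity_on_noiseless_cohort(self, noiseless_cohort):
        cohort, cfg = noiseless_cohort
        fit = fit_bias_model(cohort, BiasModelSpec("marginal"))
        corrected = correct_ages(cohort, fit)
        np.testing.assert_allclose(corrected, cohort["age"], atol=1e-9)

    def test_variance_law_and_correlation_preservation(self, homogeneous_cohort):
        """var(corrected) = var(uncorrected) / slope^2 and the corrected/age
        correlation equals the uncorrected one (affine invariance)."""
        cohort, _ = homogeneous_cohort
        fit = fit_bias_model(cohort, BiasModelSpec("marginal"))
        _, slope = fit.coefficients[MARGINAL_LEVEL]
        corrected = correct_ages(cohort, fit)
        preds = cohort["brain_age_pred"].to_numpy()
        assert np.var(corrected) == pytest.approx(np.var(preds) / slope**2)
        r_raw = np.corrcoef(preds, cohort["age"])[0, 1]
        r_cor = np.corrcoef(corrected, cohort["age"])[0, 1]
        assert r_cor == pytest.approx(r_raw, abs=1e-12)


class TestNaiveCorrect:
    def test_on_line_returns_chronological_age(self):
        ages = np.linspace(20, 80, 5)
        rec = records_from(ages, 15.2 + 0.7 * ages)
        fit = fit_bias_model(rec, BiasModelSpec("marginal"))
        np.testing.assert_allclose(naive_correct(rec, fit), ages)

    def test_same_sample_gives_orthogonal_residuals(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(20, 90, 200)
        preds = rng.normal(15 + 0.7 * ages, 6)
        rec = records_from(ages, preds)
        fit = fit_bias_model(rec, BiasModelSpec("marginal"))
        corrected = naive_correct(rec, fit)
        resid = corrected - ages  # = OLS residuals of preds ~ age
        assert abs(np.cov(resid, ages)[0, 1]) < 1e-8

    def test_null_inflation_with_out_of_sample_coefficients(self):
        """With no age signal at all, the age-dependent correction still
        produces a corrected-age/age correlation of at least ~0.87."""
        cfg = homogeneous_config(
            n_participants=1000, modalities=("MPRAGE",),
            repetitions={1: 1.0}, null_mode=True, seed=55,
        )
        cohort = generate_null_predictions(build_cohort(cfg), cfg)
        a_half = cohort.iloc[:500]
        b_half = cohort.iloc[500:]
        fit = fit_bias_model(a_half, BiasModelSpec("marginal"))
        corrected = naive_correct(b_half, fit)
        r = np.corrcoef(corrected, b_half["age"])[0, 1]
        assert r >= 0.87
        # the inverse correction has no such inflation pathway: it is an
        # affine map of the (null) predictions, so |corr| stays near zero
        inv = correct_ages(b_half, fit) if fit.coefficients[MARGINAL_LEVEL][1] != 0 else None
        if inv is not None:
            assert abs(np.corrcoef(inv, b_half["age"])[0, 1]) < 0.2


@pytest.fixture(scope="module")
def train_setup():
    cfg = homogeneous_config(n_participants=300, seed=91)
    cohort = generate_predictions(build_cohort(cfg), cfg)
    strata = StrataSpec(forced_test_modalities=(), forced_test_scanners=())
    a = stratified_split(cohort, (1.0, 0.0, 0.0), strata, seed=1)
    a = make_cv_folds(a, cohort, k=3, strata=strata, seed=2)
    return cohort, a


class TestSelectBiasModel:

    def test_single_candidate_selected(self, train_setup):
        cohort, a = train_setup
        res = select_bias_model_cv(cohort, [BiasModelSpec("marginal")], a.table)
        assert res.selected.form == "marginal"

    def test_tie_breaks_toward_fewest_coefficients(self, train_setup):
        cohort, a = train_setup
        res = select_bias_model_cv(
            cohort,
            [BiasModelSpec("by_modality"), BiasModelSpec("marginal")],
            a.table,
        )
        tbl = res.table.set_index("candidate")
        if (tbl["mae_mean"].round(1).nunique() == 1):
            assert res.selected.form == "marginal"

    def test_table_reports_per_fold_maes(self, train_setup):
        cohort, a = train_setup
        res = select_bias_model_cv(cohort, [BiasModelSpec("marginal")], a.table)
        fold_cols = [c for c in res.table.columns if c.startswith("mae_fold_")]
        assert len(fold_cols) == 3
        assert res.table[fold_cols].notna().all().all()
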