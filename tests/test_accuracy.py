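"""Bootstrapped accuracy metrics, slope tests and mixed-model contrasts."""

import numpy as np
import pandas as pd
import pytest

from brainpad.accuracy import (
    BootstrapSpec,
    bootstrap_accuracy,
    constrained_r2,
    mixed_abs_pad_model,
    pad_slope_test,
)
from brainpad.cohort import build_cohort, generate_predictions
from conftest import homogeneous_config


def scan_frame(pids, ages, preds, modality="MPRAGE", repetition=None):
    n = len(pids)
    return pd.DataFrame(
        {
            "participant_id": pids,
            "age": ages,
            "sex": ["F"] * n,
            "modality": modality if isinstance(modality, list) else [modality] * n,
            "scanner": ["Aera"] * n,
            "repetition": repetition if repetition is not None else [1] * n,
            "brain_age_pred": preds,
        }
    )


class TestConstrainedR2:
    def test_perfect_predictions(self):
        assert constrained_r2([20, 40, 60], [20, 40, 60]) == 1.0

    def test_hand_computed_zero(self):
        # RSS = 200, TSS = 200
        assert constrained_r2([30, 40, 50], [20, 40, 60]) == pytest.approx(0.0)

    def test_hand_computed_negative(self):
        # RSS = 3200, TSS = 800
        assert constrained_r2([60, 40, 20], [20, 40, 60]) == pytest.approx(-3.0)

    def test_constant_predictions_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(constrained_r2([50, 50, 50], [20, 40, 60]))

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        p, a = rng.normal(50, 10, 30), rng.normal(50, 10, 30)
        perm = rng.permutation(30)
        assert constrained_r2(p, a) == pytest.approx(
            constrained_r2(p[perm], a[perm])
        )


class TestBootstrapAccuracy:
    def test_perfect_predictions_zero_mae(self):
        ages = np.linspace(20, 80, 30)
        rec = scan_frame([f"P{i}" for i in range(30)], ages, ages)
        out = bootstrap_accuracy(rec, BootstrapSpec(base_reps=200, seed=1))
        row = out.iloc[0]
        assert row["mae_mean"] == 0.0
        assert row["mae_lo"] == 0.0 and row["mae_hi"] == 0.0

    def test_single_repetition_matches_plain_mae(self):
        rng = np.random.default_rng(4)
        ages = rng.uniform(20, 90, 200)
        preds = ages + rng.normal(0, 5, 200)
        rec = scan_frame([f"P{i}" for i in range(200)], ages, preds)
        plain = np.mean(np.abs(preds - ages))
        out = bootstrap_accuracy(rec, BootstrapSpec(base_reps=2000, seed=2))
        se = np.std(np.abs(preds - ages)) / np.sqrt(200)
        assert abs(out.iloc[0]["mae_mean"] - plain) < se

    def test_known_noise_matches_folded_normal(self):
        """MAE of N(0, sigma^2) errors converges to sigma * sqrt(2/pi)."""
        rng = np.random.default_rng(9)
        sigma = 6.0
        n = 2000
        ages = rng.uniform(20, 90, n)
        preds = ages + rng.normal(0, sigma, n)
        rec = scan_frame([f"P{i}" for i in range(n)], ages, preds)
        out = bootstrap_accuracy(rec, BootstrapSpec(base_reps=500, seed=3))
        expect = sigma * np.sqrt(2 / np.pi)
        assert out.iloc[0]["mae_mean"] == pytest.approx(expect, rel=0.05)

    def test_ci_widens_with_bonferroni(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(20, 90, 80)
        preds = ages + rng.normal(0, 5, 80)
        rec = scan_frame([f"P{i}" for i in range(80)], ages, preds)
        w1 = bootstrap_accuracy(rec, BootstrapSpec(base_reps=2000, seed=7,
                                                   bonferroni_m=1)).iloc[0]
        w8 = bootstrap_accuracy(rec, BootstrapSpec(base_reps=2000, seed=7,
                                                   bonferroni_m=8)).iloc[0]
        assert (w8["mae_hi"] - w8["mae_lo"]) >= (w1["mae_hi"] - w1["mae_lo"])

    def test_pooled_equals_per_modality_for_single_modality(self):
        rng = np.random.default_rng(6)
        ages = rng.uniform(20, 90, 100)
        preds = ages + rng.normal(0, 5, 100)
        rec = scan_frame([f"P{i}" for i in range(100)], ages, preds)
        out = bootstrap_accuracy(rec, BootstrapSpec(base_reps=2000, seed=8),
                                 pooled=True)
        per = out[out["modality"] == "MPRAGE"].iloc[0]
        pool = out[out["modality"] == "pooled"].iloc[0]
        assert pool["mae_mean"] == pytest.approx(per["mae_mean"], rel=0.05)

    def test_repetition_draw_covers_repeats(self):
        """With two repetitions of very different error, the bootstrap mean
        MAE sits between the two single-repetition MAEs."""
        pids = [f"P{i}" for i in range(50)] * 2
        ages = np.tile(np.linspace(20, 80, 50), 2)
        preds = np.concatenate([ages[:50], ages[50:] + 10.0])
        reps = [1] * 50 + [2] * 50
        rec = scan_frame(pids, ages, preds, repetition=reps)
        out = bootstrap_accuracy(rec, BootstrapSpec(base_reps=1000, seed=9))
        assert 3.0 < out.iloc[0]["mae_mean"] < 7.0


class TestPadSlopeTest:
    def test_exact_linear_pad_recovers_slope(self):
        ages = np.linspace(20, 80, 40)
        b = -0.3
        rec = scan_frame(
            [f"P{i}" for i in range(80)],
            np.concatenate([ages, ages]),
            np.zeros(80),
            modality=["A"] * 40 + ["B"] * 40,
        )
        rec["pad"] = b * rec["age"] + np.where(rec["modality"] == "A", 1.0, -2.0)
        res = pad_slope_test(rec, "pad")
        np.testing.assert_allclose(res.slopes["slope"], b, atol=1e-10)

    def test_power_against_single_nonzero_slope(self):
        rng = np.random.default_rng(12)
        n = 250
        ages = rng.uniform(20, 90, 2 * n)
        mods = ["A"] * n + ["B"] * n
        pad = rng.normal(0, 3, 2 * n)
        pad[n:] += -0.5 * (ages[n:] - 55)
        rec = scan_frame([f"P{i}" for i in range(2 * n)], ages,
                         np.zeros(2 * n), modality=mods)
        rec["pad"] = pad
        res = pad_slope_test(rec, "pad")
        assert res.omnibus_p < 1e-6
        slopes = res.slopes.set_index("modality")
        assert slopes.loc["B", "p"] < 1e-6
        assert slopes.loc["A", "p"] > 0.01

    def test_type_i_error_near_nominal(self):
        """Under a zero-slope null, the per-modality slope tests reject at
        about the nominal 5% rate."""
        rng = np.random.default_rng(77)
        rejections, trials = 0, 0
        for _ in range(200):
            n = 60
            ages = rng.uniform(20, 90, 2 * n)
            rec = scan_frame([f"P{i}" for i in range(2 * n)], ages,
                             np.zeros(2 * n), modality=["A"] * n + ["B"] * n)
            rec["pad"] = rng.normal(0, 3, 2 * n)
            res = pad_slope_test(rec, "pad")
            rejections += int((res.slopes["p"] < 0.05).sum())
            trials += len(res.slopes)
        rate = rejections / trials
        assert 0.02 < rate < 0.09  # binomial band around 0.05, 400 trials

    def test_average_slope_contrast_excludes_modalities(self):
        rng = np.random.default_rng(13)
        n = 100
        ages = rng.uniform(20, 90, 3 * n)
        mods = ["A"] * n + ["B"] * n + ["C"] * n
        pad = rng.normal(0, 2, 3 * n)
        pad[2 * n:] += -0.8 * (ages[2 * n:] - 55)  # C is badly biased
        rec = scan_frame([f"P{i}" for i in range(3 * n)], ages,
                         np.zeros(3 * n), modality=mods)
        rec["pad"] = pad
        res = pad_slope_test(rec, "pad", average_exclude=("C",))
        assert res.average_slope["p"] > 0.01
        assert res.omnibus_p < 1e-6


class TestMixedAbsPadModel:
    def test_balanced_two_modality_matches_paired_means(self):
        """On balanced complete data the modality contrast equals the mean
        within-subject paired difference of |PAD|, computed by brute force."""
        rng = np.random.default_rng(21)
        n = 40
        pids = [f"P{i}" for i in range(n)]
        base = rng.uniform(1, 8, n)
        pad_a = base + rng.normal(0, 0.5, n)
        pad_b = base + 2.0 + rng.normal(0, 0.5, n)
        rec = scan_frame(pids * 2, np.zeros(2 * n), np.zeros(2 * n),
                         modality=["MPRAGE"] * n + ["T2w"] * n)
        rec["pad"] = np.concatenate([pad_a, pad_b])
        res = mixed_abs_pad_model(rec, "pad", reference="MPRAGE")
        paired = np.mean(np.abs(pad_b) - np.abs(pad_a))
        est = res.contrasts.set_index("modality").loc["T2w", "estimate"]
        assert est == pytest.approx(paired, abs=1e-6)

    def test_degenerate_zero_noise_exact(self):
        n = 10
        pids = [f"P{i}" for i in range(n)]
        pad_a = np.full(n, 3.0)
        pad_b = np.full(n, 5.0)
        rec = scan_frame(pids * 2, np.zeros(2 * n), np.zeros(2 * n),
                         modality=["MPRAGE"] * n + ["T2w"] * n)
        rec["pad"] = np.concatenate([pad_a, pad_b])
        res = mixed_abs_pad_model(rec, "pad", reference="MPRAGE")
        assert res.degenerate
        est = res.contrasts.set_index("modality").loc["T2w", "estimate"]
        assert est == pytest.approx(2.0, abs=1e-8)

    def test_recovers_within_subject_shift(self):
        """A +3 y within-subject shift of one modality's |PAD| is recovered
        by the contrast."""
        rng = np.random.default_rng(22)
        n = 80
        pids = [f"P{i}" for i in range(n)]
        base = rng.uniform(2, 10, n)
        rec = scan_frame(pids * 2, np.zeros(2 * n), np.zeros(2 * n),
                         modality=["MPRAGE"] * n + ["T1w"] * n)
        rec["pad"] = np.concatenate(
            [base + rng.normal(0, 1, n), base + 3.0 + rng.normal(0, 1, n)]
        )
        res = mixed_abs_pad_model(rec, "pad", reference="MPRAGE")
        est = res.contrasts.set_index("modality").loc["T1w", "estimate"]
        assert est == pytest.approx(3.0, abs=0.6)

    def test_population_mae_estimates(self):
        """MAE-hat per modality approximates the raw per-modality mean |PAD|
        on balanced data."""
        rng = np.random.default_rng(23)
        n = 60
        pids = [f"P{i}" for i in range(n)]
        rec = scan_frame(pids * 2, np.zeros(2 * n), np.zeros(2 * n),
                         modality=["MPRAGE"] * n + ["T2w"] * n)
        rec["pad"] = np.concatenate(
            [rng.normal(5, 1, n), rng.normal(8, 1, n)]
        )
        res = mixed_abs_pad_model(rec, "pad", reference="MPRAGE")
        mae = res.mae_hat.set_index("modality")["mae_hat"]
        raw = rec.assign(a=rec["pad"].abs()).groupby("modality")["a"].mean()
        assert mae["MPRAGE"] == pytest.approx(raw["MPRAGE"], abs=0.3)
        assert mae["T2w"] == pytest.approx(raw["T2w"], abs=0.3)

    def test_missing_reference_rejected(self):
        rec = scan_frame(["P1", "P2"], [50, 60], [55, 62], modality=["A", "B"])
        rec["pad"] = [1.0, 2.0]
        with pytest.raises(ValueError):
            mixed_abs_pad_model(rec, "pad", reference="MPRAGE")


def test_corrected_pads_have_no_residual_age_slope(homogeneous_cohort):
    """End-to-end: correcting with a well-specified marginal bias model
    leaves no significant PAD-on-age slope."""
    from brainpad.bias import BiasModelSpec, correct_ages, fit_bias_model

    cohort, _ = homogeneous_cohort
    fit = fit_bias_model(cohort, BiasModelSpec("marginal"))
    cohort = cohort.copy()
    cohort["pad_corrected"] = correct_ages(cohort, fit) - cohort["age"]
    res = pad_slope_test(cohort, "pad_corrected")
    assert res.omnibus_p > 0.01
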