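"""End-to-end orchestration of the brain-age evaluation workflow.

The pipeline mirrors the study design the library implements piecewise:
generate (or load) a cohort of scans with predictions; split participants
into train / bias-estimation / test sets; select a bias-model form by 3-fold
cross-validation on the training set; fit the selected model's final
parameters on the independent bias-estimation set; apply the
age-independent inverse correction to the held-out test set; and report
bootstrapped accuracy, residual-slope tests, mixed-model within-subject
contrasts and reliability statistics.  Every artifact is written alongside a
run manifest (seeds, versions, file list) that makes the run reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accuracy import (
    BootstrapSpec,
    bootstrap_accuracy,
    mixed_abs_pad_model,
    pad_slope_test,
)
from .bias import (
    BiasModelFit,
    BiasModelSpec,
    aggregate_cohort_slices,
    correct_ages,
    fit_bias_model,
    select_bias_model_cv,
)
from .cohort import (
    GeneratorConfig,
    build_cohort,
    generate_null_predictions,
    generate_predictions,
    read_cohort,
    write_cohort,
)
from .reliability import build_item_matrix, cronbach_alpha, within_subject_mad
from .splits import (
    SplitAssignment,
    StrataSpec,
    check_distributions,
    make_cv_folds,
    stratified_split,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

DEFAULT_CANDIDATES = (
    BiasModelSpec("marginal", "OLS"),
    BiasModelSpec("by_modality", "OLS"),
    BiasModelSpec("by_scanner", "OLS"),
    BiasModelSpec("marginal", "WLS", "modality"),
    BiasModelSpec("marginal", "WLS", "scanner"),
)



def _json_default(obj):
    """Coerce numpy scalars for JSON output."""
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")

class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass
class PipelineConfig:
    """Run configuration: exactly one of ``generator`` / ``input_csv``."""

    generator: Optional[GeneratorConfig] = None
    input_csv: Optional[str] = None
    proportions: tuple = (0.71, 0.12, 0.17)
    strata: StrataSpec = field(default_factory=StrataSpec)
    cv_folds: int = 3
    sub_fractions: tuple = (0.63, 0.37)
    candidates: Sequence[BiasModelSpec] = DEFAULT_CANDIDATES
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    reference_modality: str = "MPRAGE"
    slope_test_exclude: tuple = ("T2wGRE",)
    out_dir: str = "brainpad_run"
    seed: int = 0

    def __post_init__(self):
        if (self.generator is None) == (self.input_csv is None):
            raise ValueError("provide exactly one of generator / input_csv")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        kwargs = {}
        if raw.get("generator"):
            kwargs["generator"] = GeneratorConfig.from_dict(raw["generator"])
        if raw.get("input_csv"):
            kwargs["input_csv"] = raw["input_csv"]
        if "proportions" in raw:
            kwargs["proportions"] = tuple(raw["proportions"])
        if "strata" in raw:
            s = raw["strata"]
            kwargs["strata"] = StrataSpec(
                age_bin_width=s.get("age_bin_width", 20.0),
                forced_test_modalities=tuple(s.get("forced_test_modalities", ())),
                forced_test_scanners=tuple(s.get("forced_test_scanners", ())),
            )
        if "candidates" in raw:
            kwargs["candidates"] = tuple(
                BiasModelSpec(
                    form=c["form"],
                    fit_method=c.get("fit_method", "OLS"),
                    wls_grouping=c.get("wls_grouping"),
                )
                for c in raw["candidates"]
            )
        if "bootstrap" in raw:
            b = raw["bootstrap"]
            kwargs["bootstrap"] = BootstrapSpec(
                base_reps=b.get("base_reps", 10000),
                alpha=b.get("alpha", 0.05),
                bonferroni_m=b.get("bonferroni_m"),
            )
        for key in ("cv_folds", "reference_modality", "out_dir", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "sub_fractions" in raw:
            kwargs["sub_fractions"] = tuple(raw["sub_fractions"])
        if "slope_test_exclude" in raw:
            kwargs["slope_test_exclude"] = tuple(raw["slope_test_exclude"])
        return cls(**kwargs)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


@_stage("cohort")
def _obtain_cohort(cfg: PipelineConfig, seed_seq) -> pd.DataFrame:
    if cfg.input_csv is not None:
        return read_cohort(cfg.input_csv)
    gen = cfg.generator
    cohort = build_cohort(gen)
    if gen.null_mode:
        cohort = generate_null_predictions(cohort, gen)
    else:
        cohort = generate_predictions(cohort, gen)
        if gen.slice_count > 0:
            cohort = aggregate_cohort_slices(cohort)
    return cohort


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full workflow and write all artifacts under ``cfg.out_dir``.

    Returns the report bundle as a dict (also written as JSON files).  Any
    stage failure raises :class:`PipelineError` with a stage-tagged message.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    split_seed, fold_seed, boot_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )

    cohort = _obtain_cohort(cfg, ss)
    write_cohort(cohort, out / "cohort.csv")

    # --- participant-level splits -------------------------------------
    try:
        assignment = stratified_split(
            cohort, cfg.proportions, cfg.strata, seed=split_seed
        )
        assignment = make_cv_folds(
            assignment, cohort, k=cfg.cv_folds,
            sub_fractions=cfg.sub_fractions, strata=cfg.strata, seed=fold_seed,
        )
        checks = check_distributions(cohort, assignment)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[split] {exc}") from exc
    assignment.to_csv(out / "splits.csv")
    checks.to_json(out / "distribution_checks.json", orient="records", indent=2)

    train = assignment.scans(cohort, "train")
    bias_est = assignment.scans(cohort, "bias_estimation")
    test = assignment.scans(cohort, "test")
    audit = {
        "train_participants": int(assignment.table.eval("split == 'train'").sum()),
        "bias_estimation_participants": int(
            assignment.table.eval("split == 'bias_estimation'").sum()
        ),
        "test_participants": int(assignment.table.eval("split == 'test'").sum()),
        "overlap_empty": not (
            set(train["participant_id"]) & set(test["participant_id"])
            or set(train["participant_id"]) & set(bias_est["participant_id"])
            or set(bias_est["participant_id"]) & set(test["participant_id"])
        ),
    }

    # --- bias model selection and final fit ---------------------------
    try:
        selection = select_bias_model_cv(train, cfg.candidates, assignment.table)
        final_fit = fit_bias_model(bias_est, selection.selected)
    except Exception as exc:
        raise PipelineError(f"[bias] {exc}") from exc
    selection.table.to_json(out / "bias_selection.json", orient="records", indent=2)
    final_fit.to_json(out / "bias_fit.json")

    # --- correction and evaluation on the held-out test set -----------
    try:
        test = test.copy()
        test["brain_age_corrected"] = correct_ages(test, final_fit)
        test["pad"] = test["brain_age_pred"] - test["age"]
        test["pad_corrected"] = test["brain_age_corrected"] - test["age"]
        write_cohort(test, out / "test_corrected.csv")

        boot = BootstrapSpec(
            base_reps=cfg.bootstrap.base_reps,
            alpha=cfg.bootstrap.alpha,
            bonferroni_m=cfg.bootstrap.bonferroni_m,
            seed=boot_seed,
        )
        acc_raw = bootstrap_accuracy(test, boot, pooled=True)
        acc_corr = bootstrap_accuracy(
            test, boot, pooled=True, prediction_column="brain_age_corrected"
        )
        slope = pad_slope_test(
            test, pad_column="pad_corrected",
            average_exclude=cfg.slope_test_exclude,
        )
        mixed = (
            mixed_abs_pad_model(
                test, pad_column="pad_corrected",
                reference=cfg.reference_modality,
            )
            if cfg.reference_modality in set(test["modality"])
            else None
        )
    except Exception as exc:
        raise PipelineError(f"[accuracy] {exc}") from exc
    acc_raw.to_csv(out / "accuracy_uncorrected.csv", index=False)
    acc_corr.to_csv(out / "accuracy_corrected.csv", index=False)

    accuracy_report = {
        "uncorrected": acc_raw.to_dict(orient="records"),
        "corrected": acc_corr.to_dict(orient="records"),
        "slope_test": {
            "omnibus_f": slope.omnibus_f,
            "omnibus_df": list(slope.omnibus_df),
            "omnibus_p": slope.omnibus_p,
            "per_modality": slope.slopes.to_dict(orient="records"),
            "average_slope": slope.average_slope,
            "note": slope.note,
        },
        "mixed_model": None
        if mixed is None
        else {
            "reference": mixed.reference,
            "converged": mixed.converged,
            "degenerate": mixed.degenerate,
            "contrasts": mixed.contrasts.to_dict(orient="records"),
            "mae_hat": mixed.mae_hat.to_dict(orient="records"),
            "total_mae": mixed.total_mae,
        },
    }
    with open(out / "accuracy_report.json", "w", encoding="utf-8") as fh:
        json.dump(accuracy_report, fh, indent=2, default=_json_default)

    # --- reliability ---------------------------------------------------
    try:
        matrix = build_item_matrix(test, pad_column="pad_corrected")
        cron = cronbach_alpha(matrix)
        mad_all = within_subject_mad(test, "pad_corrected", boot)
        fm = (
            cfg.generator.failure_modality["label"]
            if cfg.generator is not None and cfg.generator.failure_modality
            else None
        )
        mad_excl = (
            within_subject_mad(test, "pad_corrected", boot, exclude_modalities=[fm])
            if fm
            else None
        )
    except Exception as exc:
        raise PipelineError(f"[reliability] {exc}") from exc
    reliability_report = {
        "cronbach": cron.to_dict(),
        "dropped_rows": matrix.dropped_rows,
        "dropped_items": matrix.dropped_items,
        "within_subject_mad": mad_all,
        "within_subject_mad_excluding_failure": mad_excl,
    }
    with open(out / "reliability_report.json", "w", encoding="utf-8") as fh:
        json.dump(reliability_report, fh, indent=2, default=_json_default)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "master_seed": cfg.seed,
        "stage_seeds": {"split": split_seed, "folds": fold_seed,
                        "bootstrap": boot_seed},
        "generator": cfg.generator.to_dict() if cfg.generator else None,
        "input_csv": cfg.input_csv,
        "proportions": list(cfg.proportions),
        "selected_bias_model": selection.selected.label(),
        "independence_audit": audit,
        "artifacts": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)

    return {
        "cohort": cohort,
        "assignment": assignment,
        "distribution_checks": checks,
        "selection": selection,
        "bias_fit": final_fit,
        "test": test,
        "accuracy": accuracy_report,
        "reliability": reliability_report,
        "manifest": manifest,
    }
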