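"""Linear bias models for brain-age predictions and their inversion.

Brain-age predictors systematically overestimate young ages and
underestimate old ages ("regression dilution" / regression toward the mean),
so the prediction is well described by

    brain age = intercept + slope * chronological age + error,   slope < 1,

possibly with distinct (intercept, slope) per modality or per scanner model.
The correction applied here is the *age-independent* inverse of the fitted
line,

    corrected brain age = (brain age - intercept) / slope,

which never reads chronological age and therefore cannot inflate accuracy:
the corrected/age correlation equals the uncorrected one, while the variance
is inflated by 1/slope^2.  The age-dependent alternative
``corrected = age + brain age - f(age)`` is provided for diagnostics only; it
inflates the corrected-age/age correlation (never below ~0.87 under the null
with out-of-sample coefficients).

The bias model is fitted on a sample independent of both the predictor's
training data and the test data (the "bias estimation set"), and the model
form (marginal / by modality / by scanner, OLS or group-weighted WLS) is
selected by cross-validation on the bias-corrected MAE.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "BiasModelSpec",
    "BiasModelFit",
    "SelectionResult",
    "FitError",
    "CorrectionError",
    "aggregate_slices",
    "aggregate_cohort_slices",
    "fit_bias_model",
    "correct_ages",
    "naive_correct",
    "select_bias_model_cv",
]

MARGINAL_LEVEL = "__all__"

FORMS = ("marginal", "by_modality", "by_scanner")
_LEVEL_COLUMN = {"marginal": None, "by_modality": "modality", "by_scanner": "scanner"}


class FitError(RuntimeError):
    """Bias model could not be fitted."""


class CorrectionError(RuntimeError):
    """Fitted coefficients cannot be inverted."""


@dataclass(frozen=True)
class BiasModelSpec:
    """Form and fitting method of a candidate bias model."""

    form: str = "marginal"
    fit_method: str = "OLS"
    wls_grouping: Optional[str] = None

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}")
        if self.fit_method not in ("OLS", "WLS"):
            raise ValueError("fit_method must be 'OLS' or 'WLS'")
        if (self.fit_method == "WLS") != (self.wls_grouping is not None):
            raise ValueError("wls_grouping is required iff fit_method is WLS")
        if self.wls_grouping is not None and self.wls_grouping not in (
            "modality",
            "scanner",
        ):
            raise ValueError("wls_grouping must be 'modality' or 'scanner'")

    @property
    def level_column(self) -> Optional[str]:
        return _LEVEL_COLUMN[self.form]

    def label(self) -> str:
        tag = f"{self.form}/{self.fit_method}"
        if self.wls_grouping:
            tag += f"({self.wls_grouping})"
        return tag


@dataclass
class BiasModelFit:
    """Per-level (intercept, slope) estimates of a bias model."""

    spec: BiasModelSpec
    coefficients: Dict[str, Tuple[float, float]]
    n_per_level: Dict[str, int] = field(default_factory=dict)
    unfittable: List[str] = field(default_factory=list)

    @property
    def n_coefficients(self) -> int:
        return 2 * len(self.coefficients)

    def mean_coefficients(self) -> Tuple[float, float]:
        """Unweighted average (intercept, slope) across fitted levels; used
        for levels absent from the bias estimation set."""
        intercepts = [c[0] for c in self.coefficients.values()]
        slopes = [c[1] for c in self.coefficients.values()]
        return float(np.mean(intercepts)), float(np.mean(slopes))

    def to_dict(self) -> dict:
        return {
            "form": self.spec.form,
            "fit_method": self.spec.fit_method,
            "wls_grouping": self.spec.wls_grouping,
            "levels": {
                lvl: {
                    "intercept": ab[0],
                    "slope": ab[1],
                    "n": self.n_per_level.get(lvl),
                }
                for lvl, ab in self.coefficients.items()
            },
            "unfittable": list(self.unfittable),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "BiasModelFit":
        spec = BiasModelSpec(
            form=d["form"], fit_method=d["fit_method"], wls_grouping=d.get("wls_grouping")
        )
        coeffs = {
            lvl: (e["intercept"], e["slope"]) for lvl, e in d["levels"].items()
        }
        n = {lvl: e.get("n") for lvl, e in d["levels"].items()}
        return cls(spec=spec, coefficients=coeffs, n_per_level=n,
                   unfittable=list(d.get("unfittable", [])))

    @classmethod
    def from_json(cls, path) -> "BiasModelFit":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# slice aggregation


def aggregate_slices(slice_predictions: Sequence[float]) -> float:
    """Whole-scan brain age: the median of the per-slice predictions (even
    counts use the midpoint of the two central values)."""
    arr = np.asarray(slice_predictions, dtype=float)
    if arr.size == 0:
        raise ValueError("slice_predictions is empty")
    return float(np.median(arr))


def aggregate_cohort_slices(cohort: pd.DataFrame) -> pd.DataFrame:
    """Collapse ``slice_###`` columns into ``brain_age_pred`` (row medians)
    and drop the slice columns."""
    cols = [c for c in cohort.columns if c.startswith("slice_")]
    if not cols:
        raise ValueError("cohort has no slice_### columns")
    out = cohort.copy()
    out["brain_age_pred"] = np.median(out[cols].to_numpy(float), axis=1)
    return out.drop(columns=cols)


# ---------------------------------------------------------------------------
# fitting


def _ls_fit(ages, preds, weights=None) -> Tuple[float, float]:
    ages = np.asarray(ages, dtype=float)
    if np.ptp(ages) == 0:
        raise FitError("zero age variance within level; singular fit")
    X = sm.add_constant(ages, has_constant="add")
    y = np.asarray(preds, dtype=float)
    if weights is None:
        res = sm.OLS(y, X).fit()
    else:
        res = sm.WLS(y, X, weights=np.asarray(weights, dtype=float)).fit()
    return float(res.params[0]), float(res.params[1])


def fit_bias_model(
    records: pd.DataFrame, spec: BiasModelSpec, min_per_level: int = 3
) -> BiasModelFit:
    """Least-squares fit of brain age on chronological age, per level.

    The marginal form fits one global (intercept, slope); by_modality and
    by_scanner fit one pair per observed level.  WLS weights each observation
    by the inverse frequency of its ``wls_grouping`` level so each modality
    or scanner contributes equally to the fit.  Levels with fewer than
    ``min_per_level`` scans are flagged unfittable, not silently fitted.
    """
    df = records.dropna(subset=["brain_age_pred"])
    if df.empty:
        raise FitError("no records with predictions")
    weights = None
    if spec.fit_method == "WLS":
        counts = df.groupby(spec.wls_grouping)[spec.wls_grouping].transform("size")
        weights = 1.0 / counts.to_numpy(float)

    coeffs: Dict[str, Tuple[float, float]] = {}
    n_per_level: Dict[str, int] = {}
    unfittable: List[str] = []
    if spec.form == "marginal":
        groups = [(MARGINAL_LEVEL, np.arange(len(df)))]
    else:
        col = df[spec.level_column].to_numpy()
        groups = [
            (lvl, np.flatnonzero(col == lvl)) for lvl in sorted(pd.unique(col))
        ]
    ages = df["age"].to_numpy(float)
    preds = df["brain_age_pred"].to_numpy(float)
    for lvl, idx in groups:
        if len(idx) < min_per_level:
            logger.warning("level %r has %d scans (< %d); flagged unfittable",
                           lvl, len(idx), min_per_level)
            unfittable.append(lvl)
            continue
        w = weights[idx] if weights is not None else None
        coeffs[lvl] = _ls_fit(ages[idx], preds[idx], w)
        n_per_level[lvl] = int(len(idx))
    if not coeffs:
        raise FitError("no level had enough scans to fit")
    return BiasModelFit(spec=spec, coefficients=coeffs,
                        n_per_level=n_per_level, unfittable=unfittable)


# ---------------------------------------------------------------------------
# correction


def correct_ages(records: pd.DataFrame, fit: BiasModelFit) -> np.ndarray:
    """Age-independent inverse correction, (brain age - intercept) / slope.

    Uses the record's modality/scanner level for the by-level forms; a level
    absent from the fit falls back on the unweighted mean intercept and mean
    slope across the fitted levels.  Never reads chronological age.
    """
    for lvl, (a, b) in fit.coefficients.items():
        if not np.isfinite(b) or b == 0:
            raise CorrectionError(f"slope of level {lvl!r} is zero or non-finite")
    preds = records["brain_age_pred"].to_numpy(float)
    if fit.spec.form == "marginal":
        a, b = fit.coefficients[MARGINAL_LEVEL]
        return (preds - a) / b
    levels = records[fit.spec.level_column].to_numpy()
    fallback = fit.mean_coefficients()
    intercepts = np.array(
        [fit.coefficients.get(lvl, fallback)[0] for lvl in levels]
    )
    slopes = np.array([fit.coefficients.get(lvl, fallback)[1] for lvl in levels])
    return (preds - intercepts) / slopes


def naive_correct(
    records: pd.DataFrame, fit: BiasModelFit, ages: Optional[np.ndarray] = None
) -> np.ndarray:
    """Age-dependent correction, age + brain age - f(age).  Diagnostics only:
    this variant inflates the corrected-age/age correlation under the null
    because it injects chronological age directly into the output."""
    if fit.spec.form != "marginal":
        raise CorrectionError("naive correction is defined for the marginal fit")
    a, b = fit.coefficients[MARGINAL_LEVEL]
    age = np.asarray(ages, dtype=float) if ages is not None else records["age"].to_numpy(float)
    preds = records["brain_age_pred"].to_numpy(float)
    return age + preds - (a + b * age)


# ---------------------------------------------------------------------------
# cross-validated model selection


@dataclass
class SelectionResult:
    selected: BiasModelSpec
    table: pd.DataFrame  # one row per surviving candidate
    dropped: List[str] = field(default_factory=list)


def select_bias_model_cv(
    records: pd.DataFrame,
    candidates: Sequence[BiasModelSpec],
    folds: pd.DataFrame,
    min_per_level: int = 3,
) -> SelectionResult:
    """Pick the bias model minimizing the bias-corrected MAE across CV folds.

    ``folds`` must carry participant_id, fold and sub labels (from
    :func:`brainpad.splits.make_cv_folds`).  Each candidate is fitted on each
    fold's bias sub-set and scored on the fold's evaluation sub-set; fold
    MAEs are averaged.  Candidates tied after rounding the mean MAE to one
    decimal are broken first by fewest coefficients, then by lowest
    across-fold MAE standard deviation (simplest and most stable wins).
    Candidates unfittable in any fold are dropped with a log entry.
    """
    if not candidates:
        raise ValueError("no candidate specs given")
    fold_ids = sorted(folds.loc[folds["fold"].notna(), "fold"].unique())
    if not fold_ids:
        raise ValueError("folds table carries no fold labels")

    rows = []
    dropped: List[str] = []
    for spec in candidates:
        maes, ncoefs = [], []
        failed = False
        for f in fold_ids:
            in_fold = folds["fold"] == f
            bias_ids = set(
                folds.loc[in_fold & (folds["sub"] == "bias_sub"), "participant_id"]
            )
            eval_ids = set(
                folds.loc[in_fold & (folds["sub"] == "eval_sub"), "participant_id"]
            )
            fit_records = records[records["participant_id"].isin(bias_ids)]
            eval_records = records[records["participant_id"].isin(eval_ids)]
            try:
                fit = fit_bias_model(fit_records, spec, min_per_level=min_per_level)
                corrected = correct_ages(eval_records, fit)
            except (FitError, CorrectionError) as exc:
                logger.warning("candidate %s unfittable in fold %s: %s",
                               spec.label(), f, exc)
                failed = True
                break
            maes.append(float(np.mean(np.abs(corrected - eval_records["age"].to_numpy(float)))))
            ncoefs.append(fit.n_coefficients)
        if failed:
            dropped.append(spec.label())
            continue
        rows.append(
            {
                "candidate": spec.label(),
                "spec": spec,
                "mae_mean": float(np.mean(maes)),
                "mae_sd": float(np.std(maes, ddof=1)) if len(maes) > 1 else 0.0,
                "n_coefficients": float(np.mean(ncoefs)),
                **{f"mae_fold_{f}": m for f, m in zip(fold_ids, maes)},
            }
        )
    if not rows:
        raise FitError("every candidate was unfittable in at least one fold")
    table = pd.DataFrame(rows)
    rounded = table["mae_mean"].round(1)
    best = rounded.min()
    tied = table[rounded == best]
    tied = tied.sort_values(["n_coefficients", "mae_sd", "candidate"], kind="stable")
    selected = tied.iloc[0]["spec"]
    return SelectionResult(selected=selected,
                           table=table.drop(columns=["spec"]),
                           dropped=dropped)
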