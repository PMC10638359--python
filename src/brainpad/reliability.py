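"""Internal consistency of bias-corrected brain-PAD across modalities.

If brain-PAD is to serve as a participant-level biomarker, repeated
predictions of the same person — across modalities and repeat scans — should
agree.  Two statistics quantify that here:

* Cronbach's alpha over a participants x items matrix, where each item is a
  (modality, repetition) pair and cells hold the bias-corrected brain-PAD.
  Missingness is ubiquitous (nobody has every modality four times), so
  participants with fewer than 3 observed items are dropped first, then items
  with more than 95% missing cells, and the item covariance matrix is
  computed by full pairwise deletion (pair-specific means).  The confidence
  interval uses quantiles of the F distribution with df1 = rows - 1 and
  df2 = df1 * items.
* The within-subject mean absolute deviation: each participant's mean
  |PAD - own mean PAD| over their scans, averaged across participants, with a
  bootstrap CI over participants.  The subject-level random effect cancels in
  the within-subject deviations, so this isolates scan-to-scan noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .accuracy import BootstrapSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ItemMatrix",
    "EmptyItemMatrixError",
    "build_item_matrix",
    "pairwise_covariance",
    "cronbach_alpha",
    "CronbachResult",
    "within_subject_mad",
]


class EmptyItemMatrixError(RuntimeError):
    """Dropping rules removed every participant."""


@dataclass
class ItemMatrix:
    data: pd.DataFrame  # rows: participants, columns: "modality#r<k>" items
    dropped_rows: List[str] = field(default_factory=list)
    dropped_items: List[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]


def build_item_matrix(
    records: pd.DataFrame,
    pad_column: str = "pad",
    modalities: Optional[Sequence[str]] = None,
    max_repetitions: int = 4,
    min_items: int = 3,
    max_missing: float = 0.95,
) -> ItemMatrix:
    """Reorganize corrected brain-PAD into a participants x items matrix.

    One column per (modality, repetition) pair in the configured grid;
    dropping is applied in order: participants with fewer than ``min_items``
    observed cells first, then items with more than ``max_missing`` missing.
    """
    df = records.copy()
    df["pad"] = records[pad_column].to_numpy(float)
    if modalities is not None:
        df = df[df["modality"].isin(modalities)]
    df = df[df["repetition"] <= max_repetitions]
    if df.empty:
        raise EmptyItemMatrixError("no records in the configured item grid")
    wide = df.pivot_table(
        index="participant_id",
        columns=["modality", "repetition"],
        values="pad",
        aggfunc="first",
    )
    wide.columns = [f"{m}#r{r}" for m, r in wide.columns]
    wide = wide.sort_index(axis=1)

    observed = wide.notna().sum(axis=1)
    dropped_rows = sorted(wide.index[observed < min_items].astype(str))
    wide = wide[observed >= min_items]
    if wide.empty:
        raise EmptyItemMatrixError("all participants dropped (< min items)")
    missing_frac = wide.isna().mean(axis=0)
    dropped_items = sorted(missing_frac.index[missing_frac > max_missing])
    wide = wide.loc[:, missing_frac <= max_missing]
    if dropped_rows:
        logger.info("dropped %d participants with < %d items",
                    len(dropped_rows), min_items)
    if dropped_items:
        logger.info("dropped items %s (> %.0f%% missing)",
                    dropped_items, 100 * max_missing)
    return ItemMatrix(data=wide, dropped_rows=dropped_rows,
                      dropped_items=dropped_items)


def pairwise_covariance(X: np.ndarray) -> np.ndarray:
    """Covariance matrix under full pairwise deletion.

    Each entry uses only the rows where both items are observed, with means
    taken over those same rows (pair-specific means).  Pairs with fewer than
    two complete cases are NaN.
    """
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    C = np.full((k, k), np.nan)
    obs = ~np.isnan(X)
    for i in range(k):
        for j in range(i, k):
            both = obs[:, i] & obs[:, j]
            n = int(both.sum())
            if n < 2:
                continue
            xi = X[both, i] - X[both, i].mean()
            xj = X[both, j] - X[both, j].mean()
            C[i, j] = C[j, i] = float((xi * xj).sum() / (n - 1))
    return C


@dataclass
class CronbachResult:
    alpha: float
    ci: Tuple[float, float]
    band: str
    n_rows: int
    n_items: int
    df1: float
    df2: float

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "ci": list(self.ci),
            "band": self.band,
            "n_rows": self.n_rows,
            "n_items": self.n_items,
            "df1": self.df1,
            "df2": self.df2,
        }


def _band(alpha: float) -> str:
    if np.isnan(alpha):
        return "undefined"
    if alpha >= 0.95:
        return "redundant"
    if alpha >= 0.9:
        return "excellent"
    if alpha >= 0.8:
        return "acceptable"
    return "questionable"


def cronbach_alpha(X: ItemMatrix, ci_level: float = 0.95) -> CronbachResult:
    """Cronbach's alpha, k/(k-1) * [1 - trace(C) / sum_ij C_ij], with an
    F-distribution confidence interval.

    C is the pairwise-deletion covariance of the item matrix; undefined pairs
    are excluded from both the trace and the total sum.  CI bounds are
    1 - (1 - alpha) * F^-1(a/2, df1, df2) (lower) and the 1 - a/2 analogue
    (upper), with F^-1 the inverse survival function, df1 = rows - 1 and
    df2 = df1 * items.  A zero total covariance leaves alpha undefined (NaN),
    reported as such.
    """
    if X.n_items < 2 or X.n_rows < 2:
        raise ValueError("need at least 2 items and 2 rows")
    C = pairwise_covariance(X.data.to_numpy(float))
    k = X.n_items
    trace = float(np.nansum(np.diag(C)))
    total = float(np.nansum(C))
    df1 = float(X.n_rows - 1)
    df2 = df1 * k
    if total == 0:
        logger.warning("sum of covariances is zero; alpha undefined")
        return CronbachResult(float("nan"), (float("nan"), float("nan")),
                              "undefined", X.n_rows, k, df1, df2)
    alpha = (k / (k - 1)) * (1.0 - trace / total)
    a = 1.0 - ci_level
    lower = 1.0 - (1.0 - alpha) * sps.f.isf(a / 2, df1, df2)
    upper = 1.0 - (1.0 - alpha) * sps.f.isf(1 - a / 2, df1, df2)
    return CronbachResult(float(alpha), (float(lower), float(upper)),
                          _band(alpha), X.n_rows, k, df1, df2)


def within_subject_mad(
    records: pd.DataFrame,
    pad_column: str = "pad",
    boot: Optional[BootstrapSpec] = None,
    exclude_modalities: Sequence[str] = (),
) -> dict:
    """Mean within-subject absolute deviation of corrected brain-PAD.

    Per participant with >= 2 scans: mean |PAD - participant mean PAD|;
    averaged across those participants, with a percentile bootstrap CI over
    participants.  Adding a constant to all of one participant's PADs leaves
    the statistic unchanged.  Returns NaN (reported, not raised) when no
    participant has two scans.
    """
    df = records.copy()
    if exclude_modalities:
        df = df[~df["modality"].isin(set(exclude_modalities))]
    pads = df[pad_column].to_numpy(float)
    df = df.assign(_pad=pads)
    per = (
        df.groupby("participant_id")["_pad"]
        .agg(lambda s: np.abs(s - s.mean()).mean() if len(s) >= 2 else np.nan)
        .dropna()
        .sort_index()
    )
    if per.empty:
        logger.warning("no participant has >= 2 scans; within-subject MAD undefined")
        return {"mad": float("nan"), "ci": [float("nan"), float("nan")],
                "n_participants": 0,
                "excluded_modalities": list(exclude_modalities)}
    values = per.to_numpy()
    mad = float(values.mean())
    ci = [float("nan"), float("nan")]
    if boot is not None:
        rng = np.random.default_rng(boot.seed)
        idx = rng.integers(0, len(values), size=(boot.base_reps, len(values)))
        means = values[idx].mean(axis=1)
        q = boot.alpha / max(boot.bonferroni_m or 1, 1)
        ci = [float(np.percentile(means, 100 * q / 2)),
              float(np.percentile(means, 100 * (1 - q / 2)))]
    return {"mad": mad, "ci": ci, "n_participants": int(len(values)),
            "excluded_modalities": list(exclude_modalities)}
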