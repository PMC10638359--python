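"""Participant-level stratified data subdivisions.

Splitting for brain-age evaluation must happen at the participant level: if
one scan of a participant is in the training set and another in the test set,
performance is spuriously inflated ("participant leakage").  This module
partitions participants into train / bias-estimation / test sets and 3-fold
CV folds, stratifying on the Cartesian product of sex, the participant's
modality set, scanner set and a binned chronological age, with deterministic
largest-remainder apportionment inside each stratum after a seeded shuffle.

Participants carrying a forced-test modality or scanner (mirroring rare
modalities and scanners that only the held-out set should contain) are moved
to the test set before stratification; the remaining target proportions are
recomputed over the remainder.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "StrataSpec",
    "SplitAssignment",
    "stratified_split",
    "make_cv_folds",
    "check_distributions",
    "compute_observation_weights",
    "SPLIT_LABELS",
]

SPLIT_LABELS = ("train", "bias_estimation", "test")
SUB_LABELS = ("bias_sub", "eval_sub")


@dataclass
class StrataSpec:
    """Which variables define the strata and which labels force test."""

    variables: Tuple[str, ...] = ("sex", "modality_set", "scanner_set", "age_bin")
    age_bin_width: float = 20.0
    forced_test_modalities: Tuple[str, ...] = ("T1wFLAIR", "T2wGRE", "IR")
    forced_test_scanners: Tuple[str, ...] = ("Signa HDxt", "Skyra")

    def __post_init__(self):
        if self.age_bin_width <= 0:
            raise ValueError("age_bin_width must be > 0")


@dataclass
class SplitAssignment:
    """Participant -> split label (and CV fold / sub labels when present)."""

    table: pd.DataFrame  # columns: participant_id, split, fold, sub
    proportions: Tuple[float, ...]
    seed: int

    def participants(self, split: str) -> np.ndarray:
        return self.table.loc[self.table["split"] == split, "participant_id"].to_numpy()

    def scans(self, cohort: pd.DataFrame, split: str) -> pd.DataFrame:
        """Every scan inherits its participant's label."""
        ids = set(self.participants(split))
        return cohort[cohort["participant_id"].isin(ids)]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path, proportions=(0.71, 0.12, 0.17), seed=0):
        table = pd.read_csv(path, encoding="utf-8")
        table["participant_id"] = table["participant_id"].astype(str)
        return cls(table=table, proportions=tuple(proportions), seed=seed)


# ---------------------------------------------------------------------------
# stratification machinery


def participant_table(cohort: pd.DataFrame, strata: StrataSpec) -> pd.DataFrame:
    """One row per participant with the stratification variables."""
    grp = cohort.groupby("participant_id", sort=True)
    tab = grp.agg(
        age=("age", "first"),
        sex=("sex", "first"),
    ).reset_index()
    tab["modality_set"] = grp["modality"].apply(
        lambda s: "+".join(sorted(set(s)))
    ).to_numpy()
    tab["scanner_set"] = grp["scanner"].apply(
        lambda s: "+".join(sorted(set(s)))
    ).to_numpy()
    tab["age_bin"] = (tab["age"] // strata.age_bin_width).astype(int)
    return tab


def _stratum_keys(tab: pd.DataFrame, strata: StrataSpec) -> pd.Series:
    parts = [tab[v].astype(str) for v in strata.variables]
    key = parts[0]
    for p in parts[1:]:
        key = key + "|" + p
    return key


def _round_to_sum(desired: np.ndarray, n: int) -> np.ndarray:
    """Round non-negative targets to integers summing to n (largest
    remainder); each count stays within 1 of its target."""
    desired = np.clip(desired, 0.0, None)
    counts = np.floor(desired).astype(int)
    excess = counts.sum() - n
    if excess > 0:  # floor overshoot can only come from the clipping above
        order = np.argsort(desired - counts, kind="stable")
        for i in order:
            if excess == 0:
                break
            if counts[i] > 0:
                counts[i] -= 1
                excess -= 1
    order = np.argsort(-(desired - counts), kind="stable")
    counts[order[: n - counts.sum()]] += 1
    return counts


def _allocate_stratified(
    strata_ids: Dict[str, np.ndarray],
    proportions: Sequence[float],
    rng: np.random.Generator,
) -> list:
    """Allocate ids to groups, stratum by stratum.

    Within each stratum the ids are shuffled (seeded) and cut by
    largest-remainder apportionment; the fractional residual of each stratum
    is carried into the next so the global allocation tracks the target
    proportions even when most strata hold only one or two participants.
    """
    p = np.asarray(proportions, dtype=float)
    carry = np.zeros_like(p)
    out = [[] for _ in p]
    for key in sorted(strata_ids):
        ids = np.array(sorted(strata_ids[key]))
        rng.shuffle(ids)
        desired = len(ids) * p + carry
        counts = _round_to_sum(desired, len(ids))
        carry = desired - counts
        start = 0
        for g, c in enumerate(counts):
            out[g].extend(ids[start : start + c])
            start += c
    return [np.array(g) for g in out]


def stratified_split(
    cohort: pd.DataFrame,
    proportions: Sequence[float] = (0.71, 0.12, 0.17),
    strata: Optional[StrataSpec] = None,
    seed: int = 0,
) -> SplitAssignment:
    """Partition participants into train / bias_estimation / test.

    Forced-test carriers are assigned first; the remaining participants are
    allocated within each stratum by largest-remainder apportionment so the
    realized split fractions track the targets as closely as integer counts
    allow.  Strata smaller than the number of splits are allocated
    best-effort with a logged warning, never silently.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    proportions = tuple(proportions)
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    strata = strata or StrataSpec()
    rng = np.random.default_rng(seed)

    tab = participant_table(cohort, strata)
    n_total = len(tab)

    forced_mods = set(strata.forced_test_modalities)
    forced_scans = set(strata.forced_test_scanners)
    carrier = cohort.groupby("participant_id").apply(
        lambda g: bool(set(g["modality"]) & forced_mods)
        or bool(set(g["scanner"]) & forced_scans),
        include_groups=False,
    )
    forced_ids = set(carrier[carrier].index.astype(str))

    assignment: Dict[str, str] = {pid: "test" for pid in forced_ids}

    remaining = tab[~tab["participant_id"].isin(forced_ids)].copy()
    # recompute target proportions over the remainder: aim at the original
    # target *counts*, minus what forced assignment already consumed
    targets = np.array(proportions) * n_total
    already = np.array([0.0, 0.0, float(len(forced_ids))])
    residual = np.maximum(targets - already, 0.0)
    if residual.sum() == 0:
        residual = np.array([1.0, 0.0, 0.0])
    rem_props = residual / residual.sum()

    if len(remaining):
        keys = _stratum_keys(remaining, strata)
        strata_ids = {
            key: remaining.loc[keys == key, "participant_id"].to_numpy()
            for key in keys.unique()
        }
        n_active = int(np.count_nonzero(rem_props))
        small = [k for k, v in strata_ids.items() if len(v) < n_active]
        if small:
            logger.warning(
                "%d of %d strata have fewer participants than the %d splits; "
                "best-effort allocation with cross-stratum carry (e.g. %s)",
                len(small), len(strata_ids), n_active, small[0],
            )
        groups = _allocate_stratified(strata_ids, rem_props, rng)
        for label, members in zip(SPLIT_LABELS, groups):
            for pid in members:
                assignment[pid] = label

    table = pd.DataFrame(
        {
            "participant_id": sorted(assignment),
            "split": [assignment[p] for p in sorted(assignment)],
        }
    )
    table["fold"] = pd.array([pd.NA] * len(table), dtype="Int64")
    table["sub"] = pd.array([pd.NA] * len(table), dtype="string")
    return SplitAssignment(table=table, proportions=proportions, seed=seed)


def make_cv_folds(
    assignment: SplitAssignment,
    cohort: pd.DataFrame,
    k: int = 3,
    sub_fractions: Tuple[float, float] = (0.63, 0.37),
    strata: Optional[StrataSpec] = None,
    seed: int = 0,
) -> SplitAssignment:
    """Split the training participants into ``k`` stratified folds and each
    fold 63/37 into a bias sub-set and an evaluation sub-set.

    Returns a new :class:`SplitAssignment` whose training rows carry ``fold``
    (1..k) and ``sub`` labels.  All allocation is at the participant level.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if abs(sum(sub_fractions) - 1.0) > 1e-9:
        raise ValueError("sub_fractions must sum to 1")
    strata = strata or StrataSpec()
    rng = np.random.default_rng(seed)

    train_ids = set(assignment.participants("train"))
    if k > len(train_ids):
        raise ValueError(f"k={k} exceeds {len(train_ids)} training participants")
    sub_cohort = cohort[cohort["participant_id"].isin(train_ids)]
    tab = participant_table(sub_cohort, strata)
    keys = _stratum_keys(tab, strata)

    strata_ids = {
        key: tab.loc[keys == key, "participant_id"].to_numpy()
        for key in keys.unique()
    }
    fold_of: Dict[str, int] = {}
    for j, members in enumerate(_allocate_stratified(strata_ids, [1.0 / k] * k, rng),
                                start=1):
        for pid in members:
            fold_of[pid] = j

    sub_of: Dict[str, str] = {}
    for j in range(1, k + 1):
        fold_ids = np.array([p for p, f in fold_of.items() if f == j])
        fold_tab = tab[tab["participant_id"].isin(fold_ids)]
        fkeys = _stratum_keys(fold_tab, strata)
        fold_strata = {
            key: fold_tab.loc[fkeys == key, "participant_id"].to_numpy()
            for key in fkeys.unique()
        }
        groups = _allocate_stratified(fold_strata, sub_fractions, rng)
        for label, members in zip(SUB_LABELS, groups):
            for pid in members:
                sub_of[pid] = label

    table = assignment.table.copy()
    table["fold"] = pd.array(
        [fold_of.get(p, pd.NA) for p in table["participant_id"]], dtype="Int64"
    )
    table["sub"] = pd.array(
        [sub_of.get(p, pd.NA) for p in table["participant_id"]], dtype="string"
    )
    return SplitAssignment(
        table=table, proportions=assignment.proportions, seed=assignment.seed
    )


# ---------------------------------------------------------------------------
# distribution-equality checks


def check_distributions(
    cohort: pd.DataFrame, assignment: SplitAssignment, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise two-sample tests for distribution equality among splits.

    Kolmogorov-Smirnov on participant-level chronological age; chi-square on
    sex, modality and scanner model.  Because allocation is participant-level
    and a participant's repeat scans share modality and scanner labels, the
    categorical tests count each (participant, level) pair once rather than
    each scan — scan-level counts are clustered and would inflate the
    chi-square statistic.  Bonferroni correction is applied across the
    pairwise comparisons within each variable.  Empty splits are skipped with
    a log entry.
    """
    labels = [s for s in SPLIT_LABELS if len(assignment.participants(s))]
    for s in set(SPLIT_LABELS) - set(labels):
        logger.info("split %r is empty; skipped in distribution checks", s)

    part = participant_table(cohort, StrataSpec())
    part = part.merge(assignment.table[["participant_id", "split"]], on="participant_id")
    scans = cohort.merge(assignment.table[["participant_id", "split"]], on="participant_id")

    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for var in ("age", "sex", "modality", "scanner"):
        results = []
        for a, b in pairs:
            if var == "age":
                x = part.loc[part["split"] == a, "age"]
                y = part.loc[part["split"] == b, "age"]
                stat, p = stats.ks_2samp(x, y, method="asymp")
                test = "ks"
            else:
                if var == "sex":
                    frame, col = part, "sex"
                else:
                    frame, col = scans.drop_duplicates(
                        ["participant_id", var]
                    ), var
                sub = frame[frame["split"].isin([a, b])]
                contingency = pd.crosstab(sub["split"], sub[col])
                contingency = contingency.loc[:, (contingency.sum(axis=0) > 0)]
                if contingency.shape[1] < 2:
                    stat, p = 0.0, 1.0
                else:
                    stat, p, _, _ = stats.chi2_contingency(contingency)
                test = "chi2"
            results.append((a, b, test, float(stat), float(p)))
        m = len(results)
        for a, b, test, stat, p in results:
            p_adj = min(1.0, p * m)
            rows.append(
                {
                    "variable": var,
                    "split_a": a,
                    "split_b": b,
                    "test": test,
                    "statistic": stat,
                    "p_value": p,
                    "p_bonferroni": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# observation weights


def compute_observation_weights(
    cohort: pd.DataFrame, scheme: str = "none", age_bin_width: float = 20.0
) -> pd.Series:
    """Per-scan training weights.

    ``none``: all 1.  ``inverse_n_mri``: 1 / participant's scan count (so the
    inverse weights of a participant sum to 1 and the total equals the number
    of participants).  ``inverse_n_mri_age_sex``: additionally multiplied by
    the inverse scan-level prevalence of the scan's age bin and of its sex.
    """
    if scheme not in ("none", "inverse_n_mri", "inverse_n_mri_age_sex"):
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    n = len(cohort)
    if scheme == "none":
        return pd.Series(np.ones(n), index=cohort.index, name="weight")
    counts = cohort.groupby("participant_id")["participant_id"].transform("size")
    w = 1.0 / counts.astype(float)
    if scheme == "inverse_n_mri_age_sex":
        bins = ((cohort["age"] - cohort["age"].min()) // age_bin_width).astype(int)
        bin_prev = bins.map(bins.value_counts(normalize=True))
        if (bin_prev <= 0).any():
            raise ValueError("empty age bin encountered")
        sex_prev = cohort["sex"].map(cohort["sex"].value_counts(normalize=True))
        w = w / bin_prev / sex_prev
    return pd.Series(w.to_numpy(), index=cohort.index, name="weight")
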