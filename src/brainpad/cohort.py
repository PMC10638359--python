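"""Synthetic clinical brain-age cohorts.

Real clinical MRI archives used for brain-age work are rarely shareable, so
this module generates cohorts whose statistical structure matches what such an
archive looks like after prediction: one row per scan, with participant id,
chronological age, sex, modality, scanner, repetition index and a predicted
brain age.  Predictions carry the "regression dilution" bias typical of
brain-age models (overestimation of young ages, underestimation of old ages,
i.e. a slope < 1 of prediction on truth), an additive subject-level random
effect shared across a participant's scans, modality-specific offsets and
noise, and optionally a grossly miscalibrated "failure" modality or a null
mode in which predictions carry no age information at all.

The age distribution is a truncated normal whose underlying location and scale
are numerically calibrated so that the *truncated* mean and SD hit the
configured targets (by default mean 53.5 y, SD 18 y on [15, 95]).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

__all__ = [
    "CalibrationError",
    "ConfigurationError",
    "GeneratorConfig",
    "DEFAULT_MODALITY_TABLE",
    "DEFAULT_SCANNER_TABLE",
    "calibrate_truncated_normal",
    "sample_ages",
    "build_cohort",
    "generate_predictions",
    "generate_null_predictions",
    "write_cohort",
    "read_cohort",
    "slice_columns",
]


class CalibrationError(RuntimeError):
    """No (mu, sigma) reproduces the requested truncated moments."""


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


#: Approximate marginal frequencies of a multi-modality clinical archive:
#: per-participant probability of carrying each modality and the distribution
#: of the number of repeat scans (1-4) given that the modality is present.
#: Three modalities (T1wFLAIR, T2wGRE, IR) are rare; they are the ones a
#: study would hold out for testing only.
DEFAULT_MODALITY_TABLE: dict = {
    "MPRAGE": {"prevalence": 0.61, "repetitions": {1: 0.97, 2: 0.03}},
    "T1w": {"prevalence": 0.75, "repetitions": {1: 0.55, 2: 0.35, 3: 0.05, 4: 0.05}},
    "T2w": {"prevalence": 0.72, "repetitions": {1: 0.50, 2: 0.35, 3: 0.10, 4: 0.05}},
    "T1wFLAIR": {"prevalence": 0.03, "repetitions": {1: 0.90, 2: 0.10}},
    "T2wFLAIR": {"prevalence": 0.45, "repetitions": {1: 0.75, 2: 0.20, 3: 0.04, 4: 0.01}},
    "T2wGRE": {"prevalence": 0.05, "repetitions": {1: 0.85, 2: 0.10, 3: 0.03, 4: 0.02}},
    "IR": {"prevalence": 0.10, "repetitions": {1: 1.0}},
}

#: Participant-level "home scanner" distribution (all of a participant's scans
#: share one scanner model unless a modality lock overrides it).
DEFAULT_SCANNER_TABLE: dict = {
    "Aera": 0.19,
    "Avanto": 0.23,
    "Prisma": 0.16,
    "Sola": 0.03,
    "Signa HDxt": 0.05,
    "Skyra": 0.03,
    "Titan 3T": 0.06,
    "Verio": 0.25,
}

DEFAULT_MODALITY_OFFSETS: dict = {
    "MPRAGE": 0.0,
    "T1w": 1.5,
    "T2w": -0.5,
    "T1wFLAIR": 2.0,
    "T2wFLAIR": 0.5,
    "T2wGRE": 0.0,
    "IR": 1.0,
}

DEFAULT_MODALITY_NOISE_SD: dict = {
    "MPRAGE": 5.0,
    "T1w": 7.0,
    "T2w": 5.5,
    "T1wFLAIR": 6.5,
    "T2wFLAIR": 5.5,
    "T2wGRE": 8.0,
    "IR": 6.0,
}

COHORT_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "modality",
    "scanner",
    "repetition",
    "brain_age_pred",
]


@dataclass
class GeneratorConfig:
    """Everything needed to generate a cohort of scans with predictions.

    The defaults describe a cohort of 1540 participants, ages 15-95 y
    (mean 53.5, SD 18), ~67% female, seven modalities across eight scanner
    models with 1-4 repetitions, a linear prediction bias with intercept
    15.2 y and slope 0.7, a subject-level random effect (SD 3 y) and
    modality-specific scan noise (SD 5-8 y), and one failure modality
    (T2wGRE) with its own grossly miscalibrated line.
    """

    n_participants: int = 1540
    age_bounds: tuple = (15.0, 95.0)
    age_mean_target: float = 53.5
    age_sd_target: float = 18.0
    female_fraction: float = 1039 / 1540
    modality_table: Mapping = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_MODALITY_TABLE)
    )
    scanner_table: Mapping = field(
        default_factory=lambda: dict(DEFAULT_SCANNER_TABLE)
    )
    # lock certain modalities to a fixed scanner regardless of the home
    # scanner (e.g. IR acquired at a single site on one scanner model)
    modality_scanner_lock: Mapping = field(
        default_factory=lambda: {"IR": "Signa HDxt"}
    )
    bias_intercept: float = 15.2
    bias_slope: float = 0.7
    modality_offsets: Mapping = field(
        default_factory=lambda: dict(DEFAULT_MODALITY_OFFSETS)
    )
    modality_noise_sd: Mapping = field(
        default_factory=lambda: dict(DEFAULT_MODALITY_NOISE_SD)
    )
    subject_effect_sd: float = 3.0
    failure_modality: Optional[Mapping] = field(
        default_factory=lambda: {
            "label": "T2wGRE",
            "intercept": 40.0,
            "slope": 0.15,
            "noise_sd": 8.0,
        }
    )
    null_mode: bool = False
    null_features: int = 10
    slice_count: int = 0
    slice_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        low, high = self.age_bounds
        if not low < high:
            raise ConfigurationError("age_bounds must satisfy low < high")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.age_sd_target < 0 or self.subject_effect_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.slice_noise_sd < 0:
            raise ConfigurationError("slice_noise_sd must be >= 0")
        if self.bias_slope == 0:
            raise ConfigurationError("bias_slope must be nonzero")
        if not self.modality_table:
            raise ConfigurationError("modality_table must not be empty")
        if not 0 <= self.female_fraction <= 1:
            raise ConfigurationError("female_fraction must be in [0, 1]")
        for name, entry in self.modality_table.items():
            p = entry["prevalence"]
            if not 0 < p <= 1:
                raise ConfigurationError(f"prevalence of {name} must be in (0, 1]")
            reps = entry["repetitions"]
            if abs(sum(reps.values()) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"repetition distribution of {name} must sum to 1"
                )
            if any(sd < 0 for sd in self.modality_noise_sd.values()):
                raise ConfigurationError("modality noise SDs must be >= 0")
        total = sum(self.scanner_table.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("scanner_table probabilities must sum to 1")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_participants": self.n_participants,
            "age_bounds": list(self.age_bounds),
            "age_mean_target": self.age_mean_target,
            "age_sd_target": self.age_sd_target,
            "female_fraction": self.female_fraction,
            "modality_table": {
                m: {
                    "prevalence": e["prevalence"],
                    "repetitions": {int(k): v for k, v in e["repetitions"].items()},
                }
                for m, e in self.modality_table.items()
            },
            "scanner_table": dict(self.scanner_table),
            "modality_scanner_lock": dict(self.modality_scanner_lock),
            "bias_intercept": self.bias_intercept,
            "bias_slope": self.bias_slope,
            "modality_offsets": dict(self.modality_offsets),
            "modality_noise_sd": dict(self.modality_noise_sd),
            "subject_effect_sd": self.subject_effect_sd,
            "failure_modality": dict(self.failure_modality)
            if self.failure_modality
            else None,
            "null_mode": self.null_mode,
            "null_features": self.null_features,
            "slice_count": self.slice_count,
            "slice_noise_sd": self.slice_noise_sd,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "age_bounds" in d:
            d["age_bounds"] = tuple(d["age_bounds"])
        if "modality_table" in d:
            d["modality_table"] = {
                m: {
                    "prevalence": e["prevalence"],
                    "repetitions": {int(k): v for k, v in e["repetitions"].items()},
                }
                for m, e in d["modality_table"].items()
            }
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# age distribution


def calibrate_truncated_normal(
    low: float, high: float, mean: float, sd: float
) -> tuple:
    """Return (mu, sigma) such that N(mu, sigma) truncated to [low, high]
    has the requested mean and SD.

    Solved numerically on the truncated distribution's first two moments;
    raises :class:`CalibrationError` if no solution exists (e.g. the target
    mean is outside the bounds, or the target SD exceeds what any truncated
    normal on the interval can reach).
    """
    if not low < mean < high:
        raise CalibrationError(
            f"target mean {mean} outside age bounds ({low}, {high})"
        )
    if sd <= 0:
        raise CalibrationError("target sd must be > 0 for calibration")

    def residuals(params):
        mu, log_sigma = params
        sigma = float(np.exp(log_sigma))
        a, b = (low - mu) / sigma, (high - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.root(residuals, x0=[mean, np.log(sd)], method="hybr")
    res = residuals(sol.x)
    if not sol.success or max(abs(res[0]), abs(res[1])) > 1e-6:
        raise CalibrationError(
            f"calibration failed for mean={mean}, sd={sd} on [{low}, {high}]"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def sample_ages(n: int, cfg: GeneratorConfig, seed=None) -> np.ndarray:
    """Draw ``n`` chronological ages from the calibrated truncated normal.

    ``seed`` may be an int or a ``numpy.random.Generator``; the draw is
    reproducible for a fixed seed.  A zero target SD degenerates to all ages
    equal to the target mean.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    low, high = cfg.age_bounds
    if cfg.age_sd_target == 0:
        return np.full(n, float(cfg.age_mean_target))
    mu, sigma = calibrate_truncated_normal(
        low, high, cfg.age_mean_target, cfg.age_sd_target
    )
    a, b = (low - mu) / sigma, (high - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


# ---------------------------------------------------------------------------
# cohort structure


def build_cohort(cfg: GeneratorConfig) -> pd.DataFrame:
    """Generate the scan table (without predictions).

    Each participant receives one age and sex, a home scanner, a subset of
    modalities (independent inclusion by prevalence; participants with no
    modality are assigned one proportionally to prevalence) and a repetition
    count per modality.  Rows are sorted (participant, modality, repetition)
    so that identical (cfg, seed) yield byte-identical tables.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    age_s, sex_s, scan_s, mod_s, rep_s = ss.spawn(5)
    n = cfg.n_participants

    ages = sample_ages(n, cfg, seed=np.random.default_rng(age_s))
    sex_rng = np.random.default_rng(sex_s)
    sexes = np.where(sex_rng.random(n) < cfg.female_fraction, "F", "M")

    scanner_names = sorted(cfg.scanner_table)
    scanner_p = np.array([cfg.scanner_table[s] for s in scanner_names])
    scan_rng = np.random.default_rng(scan_s)
    home_scanner = scan_rng.choice(scanner_names, size=n, p=scanner_p / scanner_p.sum())

    modality_names = sorted(cfg.modality_table)
    prevalences = np.array(
        [cfg.modality_table[m]["prevalence"] for m in modality_names]
    )
    mod_rng = np.random.default_rng(mod_s)
    rep_rng = np.random.default_rng(rep_s)

    width = max(5, len(str(n)))
    rows = []
    for i in range(n):
        pid = f"P{i:0{width}d}"
        include = mod_rng.random(len(modality_names)) < prevalences
        if not include.any():
            j = mod_rng.choice(len(modality_names), p=prevalences / prevalences.sum())
            include[j] = True
        for m, inc in zip(modality_names, include):
            if not inc:
                continue
            reps = cfg.modality_table[m]["repetitions"]
            rep_vals = sorted(reps)
            rep_p = np.array([reps[k] for k in rep_vals], dtype=float)
            n_rep = int(rep_rng.choice(rep_vals, p=rep_p / rep_p.sum()))
            scanner = cfg.modality_scanner_lock.get(m, home_scanner[i])
            for r in range(1, n_rep + 1):
                rows.append(
                    (pid, float(ages[i]), sexes[i], m, scanner, r, np.nan)
                )
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df = df.sort_values(["participant_id", "modality", "repetition"]).reset_index(
        drop=True
    )
    return df


# ---------------------------------------------------------------------------
# predictions


def _modality_params(cfg: GeneratorConfig, modality: str):
    """(intercept, slope, offset, noise_sd) of the generating line for one
    modality, honouring the failure-modality override."""
    fm = cfg.failure_modality
    if fm is not None and modality == fm["label"]:
        return float(fm["intercept"]), float(fm["slope"]), 0.0, float(fm["noise_sd"])
    offset = float(cfg.modality_offsets.get(modality, 0.0))
    noise = float(cfg.modality_noise_sd.get(modality, 5.0))
    return float(cfg.bias_intercept), float(cfg.bias_slope), offset, noise


def generate_predictions(cohort: pd.DataFrame, cfg: GeneratorConfig) -> pd.DataFrame:
    """Attach biased brain-age predictions to a cohort.

    prediction = intercept + slope * age + modality offset + subject effect
    + scan noise; the failure modality uses its own (intercept, slope, noise).
    With ``slice_count > 0``, per-slice predictions (scan value plus i.i.d.
    slice noise) are emitted in ``slice_###`` columns and ``brain_age_pred``
    is left unset, to be produced by :func:`brainpad.bias.aggregate_slices`.
    """
    if cfg.null_mode:
        raise ConfigurationError(
            "cfg.null_mode is set; use generate_null_predictions"
        )
    unknown = set(cohort["modality"]) - set(cfg.modality_table)
    if unknown:
        raise ConfigurationError(f"cohort contains unknown modalities: {sorted(unknown)}")

    ss = np.random.SeedSequence(cfg.seed).spawn(8)
    subj_rng = np.random.default_rng(ss[5])
    noise_rng = np.random.default_rng(ss[6])
    slice_rng = np.random.default_rng(ss[7])

    out = cohort.copy()
    pids = out["participant_id"].drop_duplicates().sort_values().to_numpy()
    subj_eff = dict(
        zip(pids, subj_rng.normal(0.0, cfg.subject_effect_sd, size=len(pids)))
    )

    ages = out["age"].to_numpy(float)
    preds = np.empty(len(out))
    for idx, (modality, age, pid) in enumerate(
        zip(out["modality"], ages, out["participant_id"])
    ):
        b0, b1, off, sd = _modality_params(cfg, modality)
        preds[idx] = (
            b0 + b1 * age + off + subj_eff[pid] + noise_rng.normal(0.0, sd)
        )

    if cfg.slice_count > 0:
        cols = slice_columns(cfg.slice_count)
        slices = preds[:, None] + slice_rng.normal(
            0.0, cfg.slice_noise_sd, size=(len(out), cfg.slice_count)
        )
        out["brain_age_pred"] = np.nan
        out[cols] = slices
    else:
        out["brain_age_pred"] = preds
    return out


def generate_null_predictions(cohort: pd.DataFrame, cfg: GeneratorConfig) -> pd.DataFrame:
    """Predictions with (asymptotically) no age information.

    An ordinary least-squares predictor of age is trained on pure-noise
    features in an independent training draw and evaluated on fresh noise
    features for the cohort, so the output has the reduced-variance character
    of a fitted learner (var ~ (p/n) * var(age)) but no real age signal.
    """
    if not cfg.null_mode:
        raise ConfigurationError("generate_null_predictions requires null_mode")
    p = cfg.null_features
    n_train = len(cohort)
    if p >= n_train:
        raise ConfigurationError(
            f"null_features ({p}) must be < training sample size ({n_train})"
        )
    ss = np.random.SeedSequence(cfg.seed).spawn(12)
    age_rng = np.random.default_rng(ss[8])
    feat_rng = np.random.default_rng(ss[9])

    y_train = sample_ages(n_train, cfg, seed=age_rng)
    X_train = feat_rng.standard_normal((n_train, p))
    A = np.column_stack([np.ones(n_train), X_train])
    beta, *_ = np.linalg.lstsq(A, y_train, rcond=None)

    X_eval = feat_rng.standard_normal((len(cohort), p))
    preds = beta[0] + X_eval @ beta[1:]
    out = cohort.copy()
    out["brain_age_pred"] = preds
    return out


# ---------------------------------------------------------------------------
# I/O


def slice_columns(count: int) -> list:
    return [f"slice_{i:03d}" for i in range(1, count + 1)]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as UTF-8 CSV ('.' decimal separator, missing = empty)."""
    cohort.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    df["participant_id"] = df["participant_id"].astype(str)
    df["repetition"] = df["repetition"].astype(int)
    return df
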