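"""Shared fixtures: small synthetic cohorts used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from brainpad.cohort import GeneratorConfig, build_cohort, generate_predictions


def homogeneous_config(
    n_participants: int = 186,
    modalities=("MPRAGE", "T1w", "T2w", "T2wFLAIR"),
    repetitions=None,
    noise_sd: float = 5.0,
    subject_sd: float = 3.0,
    seed: int = 0,
    **overrides,
) -> GeneratorConfig:
    """A four-modality cohort with a single global bias line, no modality
    offsets and no failure modality: every participant carries every
    modality.  Matches the bias-estimation-sample structure used for
    parameter-recovery checks (186 participants, ~841 scans with the default
    repetition mix)."""
    reps = repetitions or {1: 0.87, 2: 0.13}
    mods = {m: {"prevalence": 1.0, "repetitions": dict(reps)} for m in modalities}
    base = dict(
        n_participants=n_participants,
        modality_table=mods,
        modality_offsets={m: 0.0 for m in modalities},
        modality_noise_sd={m: noise_sd for m in modalities},
        subject_effect_sd=subject_sd,
        failure_modality=None,
        modality_scanner_lock={},
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def noiseless_config(n_participants: int = 50, seed: int = 0, **overrides):
    """All noise sources zero: predictions sit exactly on the bias line."""
    return homogeneous_config(
        n_participants=n_participants,
        noise_sd=0.0,
        subject_sd=0.0,
        seed=seed,
        **overrides,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """250 participants with the full default structure (offsets, failure
    modality, rare modalities) and predictions."""
    cfg = GeneratorConfig(n_participants=250, seed=11)
    return generate_predictions(build_cohort(cfg), cfg), cfg


@pytest.fixture(scope="session")
def homogeneous_cohort():
    cfg = homogeneous_config(seed=21)
    return generate_predictions(build_cohort(cfg), cfg), cfg


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = noiseless_config(seed=31)
    return generate_predictions(build_cohort(cfg), cfg), cfg
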