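"""Accuracy metrics for brain-age predictions under repeated measures.

Clinical cohorts carry several scans per participant (modalities and repeat
acquisitions), so naive pooling inflates accuracy estimates.  The metrics
here follow a repeated-measures bootstrap: each replicate resamples
participants with replacement and, within each sampled participant, draws one
repetition uniformly at random; MAE, Pearson r and a constrained coefficient
of determination are computed per replicate, and percentile confidence
intervals are taken across replicates (Bonferroni-adjusted across the rows of
the emitted table).

The constrained R^2 scores predictions against the identity line
(brain age = chronological age): RSS is taken about that line, TSS about the
mean of the *predictions*, so R^2 can be negative when predictions poorly
follow the identity trend.

Two regression diagnostics complete the report: a scan-level fit of
brain-PAD ~ modality x age testing whether any residual age-dependence
survives the bias correction, and a linear mixed model on |brain-PAD| with
subject and modality fixed effects plus a subject random intercept (REML,
quasi-Newton), whose contrasts estimate within-subject differences in MAE
between each modality and a reference, and whose fixed effects yield a
"population" MAE estimate per modality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapSpec",
    "constrained_r2",
    "bootstrap_accuracy",
    "pad_slope_test",
    "SlopeTestResult",
    "mixed_abs_pad_model",
    "MixedPadResult",
]


@dataclass
class BootstrapSpec:
    """Replicate counts and CI levels for the repeated-measures bootstrap.

    The effective number of replicates is ``base_reps * N_r`` per modality
    and ``base_reps * N_r * N_m`` pooled, where N_r is the maximum repetition
    count and N_m the number of modalities, to account for the extra
    randomness of the per-replicate repetition draw.
    """

    base_reps: int = 10000
    alpha: float = 0.05
    bonferroni_m: Optional[int] = None  # default: rows of the emitted table
    seed: Optional[int] = None

    def __post_init__(self):
        if self.base_reps < 1:
            raise ValueError("base_reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# constrained R^2


def constrained_r2(predictions: Sequence[float], ages: Sequence[float]) -> float:
    """R^2 of the model brain age = chronological age (slope 1, intercept 0).

    RSS sums squared residuals against the identity line; TSS sums squared
    deviations of the predictions about their own mean.  Returns NaN (with a
    warning) when the predictions are constant, since TSS = 0 leaves the
    statistic undefined.
    """
    p = np.asarray(predictions, dtype=float)
    a = np.asarray(ages, dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 observations")
    rss = float(np.sum((p - a) ** 2))
    tss = float(np.sum((p - p.mean()) ** 2))
    if tss == 0:
        warnings.warn("constant predictions: constrained R^2 undefined")
        return float("nan")
    return 1.0 - rss / tss


# ---------------------------------------------------------------------------
# rowwise replicate statistics (internal)


def _row_stats(x: np.ndarray, y: np.ndarray, mask: Optional[np.ndarray]):
    """MAE, Pearson r and constrained R^2 along axis 1, honouring a mask."""
    if mask is None:
        n = x.shape[1]
        mae = np.abs(x - y).mean(axis=1)
        mx = x.mean(axis=1, keepdims=True)
        my = y.mean(axis=1, keepdims=True)
        dx, dy = x - mx, y - my
        cov = (dx * dy).sum(axis=1)
        vx = (dx**2).sum(axis=1)
        vy = (dy**2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(vx * vy)
            r2 = 1.0 - ((x - y) ** 2).sum(axis=1) / vx
        return mae, r, r2
    m = mask.astype(float)
    n = m.sum(axis=1)
    xs = np.where(mask, x, 0.0)
    ys = np.where(mask, y, 0.0)
    mae = np.where(mask, np.abs(x - y), 0.0).sum(axis=1) / n
    mx = xs.sum(axis=1) / n
    my = ys.sum(axis=1) / n
    dx = np.where(mask, x - mx[:, None], 0.0)
    dy = np.where(mask, y - my[:, None], 0.0)
    cov = (dx * dy).sum(axis=1)
    vx = (dx**2).sum(axis=1)
    vy = (dy**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
        r2 = 1.0 - np.where(mask, (x - y) ** 2, 0.0).sum(axis=1) / vx
    return mae, r, r2


def _summarize(reps: Dict[str, np.ndarray], q: float) -> dict:
    out = {}
    for name, vals in reps.items():
        out[f"{name}_mean"] = float(np.nanmean(vals))
        out[f"{name}_lo"] = float(np.nanpercentile(vals, 100 * q / 2))
        out[f"{name}_hi"] = float(np.nanpercentile(vals, 100 * (1 - q / 2)))
    return out


# ---------------------------------------------------------------------------
# repeated-measures bootstrap


def _modality_replicates(sub: pd.DataFrame, n_reps: int, rng, chunk: int):
    """Bootstrap replicates for one modality: resample participants with
    replacement, one random repetition per sampled participant."""
    pids = sub["participant_id"].to_numpy()
    order = np.argsort(pids, kind="stable")
    pids, preds = pids[order], sub["brain_age_pred"].to_numpy(float)[order]
    ages_all = sub["age"].to_numpy(float)[order]
    uniq, starts = np.unique(pids, return_index=True)
    P = len(uniq)
    bounds = np.append(starts, len(pids))
    counts = np.diff(bounds)
    maxc = counts.max()
    idx = np.zeros((P, maxc), dtype=np.int64)
    for i in range(P):
        idx[i, : counts[i]] = np.arange(bounds[i], bounds[i + 1])
    ages_p = ages_all[starts]

    maes, rs, r2s = [], [], []
    done = 0
    step = max(1, min(chunk // max(P, 1), n_reps))
    while done < n_reps:
        c = min(step, n_reps - done)
        pi = rng.integers(0, P, size=(c, P))
        ri = (rng.random((c, P)) * counts[pi]).astype(np.int64)
        rows = idx[pi, ri]
        x = preds[rows]
        y = ages_p[pi]
        mae, r, r2 = _row_stats(x, y, None)
        maes.append(mae)
        rs.append(r)
        r2s.append(r2)
        done += c
    return {
        "mae": np.concatenate(maes),
        "r": np.concatenate(rs),
        "r2": np.concatenate(r2s),
    }, P, len(sub)


def _pooled_replicates(records: pd.DataFrame, n_reps: int, rng, chunk: int):
    """Pooled replicates: resample participants; each sampled participant
    contributes one random repetition of every modality they carry."""
    df = records.sort_values(
        ["participant_id", "modality", "repetition"]
    ).reset_index(drop=True)
    preds = df["brain_age_pred"].to_numpy(float)
    ages = df["age"].to_numpy(float)
    grp = df.groupby(["participant_id", "modality"], sort=True)
    keys = list(grp.indices.keys())
    gidx_list = [np.sort(np.asarray(grp.indices[k])) for k in keys]
    G = len(keys)
    gcounts = np.array([len(ix) for ix in gidx_list])
    gmax = gcounts.max()
    gidx = np.zeros((G, gmax), dtype=np.int64)
    for i, ix in enumerate(gidx_list):
        gidx[i, : len(ix)] = ix
    gage = np.array([ages[ix[0]] for ix in gidx_list])

    part_of_group = np.array([k[0] for k in keys])
    uniq_p = np.unique(part_of_group)
    P = len(uniq_p)
    groups_of_p = [np.flatnonzero(part_of_group == p) for p in uniq_p]
    M = max(len(g) for g in groups_of_p)
    pg = np.zeros((P, M), dtype=np.int64)
    pgm = np.zeros((P, M), dtype=bool)
    for i, g in enumerate(groups_of_p):
        pg[i, : len(g)] = g
        pgm[i, : len(g)] = True

    maes, rs, r2s = [], [], []
    done = 0
    step = max(1, min(chunk // max(P * M, 1), n_reps))
    while done < n_reps:
        c = min(step, n_reps - done)
        pi = rng.integers(0, P, size=(c, P))
        g = pg[pi].reshape(c, P * M)
        gm = pgm[pi].reshape(c, P * M)
        ri = (rng.random(g.shape) * gcounts[g]).astype(np.int64)
        rows = gidx[g, ri]
        x = np.where(gm, preds[rows], 0.0)
        y = np.where(gm, gage[g], 0.0)
        mae, r, r2 = _row_stats(x, y, gm)
        maes.append(mae)
        rs.append(r)
        r2s.append(r2)
        done += c
    return {
        "mae": np.concatenate(maes),
        "r": np.concatenate(rs),
        "r2": np.concatenate(r2s),
    }, P, len(records)


def bootstrap_accuracy(
    records: pd.DataFrame,
    spec: BootstrapSpec,
    pooled: bool = False,
    prediction_column: str = "brain_age_pred",
    chunk: int = 2_000_000,
) -> pd.DataFrame:
    """Bootstrapped MAE, Pearson r and constrained R^2 per modality.

    Returns one row per modality (plus a ``pooled`` row when requested) with
    across-replicate means and percentile CIs at level
    ``1 - alpha / bonferroni_m``.  Modalities with fewer than 2 participants
    are skipped with a log entry.
    """
    df = records.dropna(subset=[prediction_column]).copy()
    if prediction_column != "brain_age_pred":
        df["brain_age_pred"] = df[prediction_column]
    modalities = sorted(df["modality"].unique())
    n_r = int(df["repetition"].max())
    n_m = len(modalities)
    m_rows = spec.bonferroni_m
    if m_rows is None:
        m_rows = n_m + (1 if pooled else 0)
    q = spec.alpha / max(m_rows, 1)
    rng = np.random.default_rng(spec.seed)

    rows = []
    for m in modalities:
        sub = df[df["modality"] == m]
        if sub["participant_id"].nunique() < 2:
            logger.warning("modality %r has < 2 participants; skipped", m)
            continue
        reps, P, n_scans = _modality_replicates(
            sub, spec.base_reps * n_r, rng, chunk
        )
        row = {"modality": m, "n_participants": P, "n_scans": n_scans,
               "replicates": spec.base_reps * n_r}
        row.update(_summarize(reps, q))
        rows.append(row)
    if pooled:
        reps, P, n_scans = _pooled_replicates(
            df, spec.base_reps * n_r * n_m, rng, chunk
        )
        row = {"modality": "pooled", "n_participants": P, "n_scans": n_scans,
               "replicates": spec.base_reps * n_r * n_m}
        row.update(_summarize(reps, q))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# brain-PAD slope tests


@dataclass
class SlopeTestResult:
    omnibus_f: float
    omnibus_df: Tuple[float, float]
    omnibus_p: float
    slopes: pd.DataFrame  # per-modality slope estimates and t-tests
    average_slope: dict  # mean slope across a modality subset
    note: str = ""


def pad_slope_test(
    records: pd.DataFrame,
    pad_column: str = "pad",
    average_exclude: Sequence[str] = (),
) -> SlopeTestResult:
    """Test whether brain-PAD retains any age-dependence, per modality.

    Fits PAD ~ modality * age by least squares over all scans (scans are
    treated as independent; the repeated-measures caveat is recorded in the
    result note).  Reports the omnibus F-test that every modality-specific
    slope is zero, uncorrected per-modality slope t-tests, and a contrast on
    the mean slope across all modalities not listed in ``average_exclude``.
    """
    df = records[["modality", "age"]].copy()
    df["pad"] = records[pad_column].to_numpy(float)
    modalities = sorted(df["modality"].unique())
    note = "scan-level fit; repeated measures within participants not modeled"
    if len(modalities) < 2:
        logger.warning("single modality level; fitting reduced model pad ~ age")
        res = smf.ols("pad ~ age", data=df).fit()
        est = float(res.params["age"])
        slopes = pd.DataFrame(
            [{"modality": modalities[0], "slope": est,
              "se": float(res.bse["age"]), "t": float(res.tvalues["age"]),
              "p": float(res.pvalues["age"])}]
        )
        ftest = res.f_test("age = 0")
        return SlopeTestResult(
            omnibus_f=float(ftest.fvalue), omnibus_df=(1.0, float(res.df_resid)),
            omnibus_p=float(ftest.pvalue), slopes=slopes,
            average_slope={"estimate": est, "p": float(res.pvalues["age"]),
                           "excluded": list(average_exclude)},
            note=note + "; reduced model (one modality)",
        )

    res = smf.ols("pad ~ C(modality) * age", data=df).fit()
    names = res.model.exog_names
    k = len(names)
    ref = modalities[0]

    def slope_row(m):
        L = np.zeros(k)
        L[names.index("age")] = 1.0
        if m != ref:
            L[names.index(f"C(modality)[T.{m}]:age")] = 1.0
        return L

    L_all = np.vstack([slope_row(m) for m in modalities])
    ftest = res.f_test(L_all)
    slope_rows = []
    for m in modalities:
        t = res.t_test(slope_row(m))
        slope_rows.append(
            {"modality": m, "slope": float(t.effect[0]), "se": float(t.sd[0][0]),
             "t": float(t.tvalue[0][0]), "p": float(t.pvalue)}
        )
    included = [m for m in modalities if m not in set(average_exclude)]
    L_avg = np.vstack([slope_row(m) for m in included]).mean(axis=0)
    t_avg = res.t_test(L_avg)
    return SlopeTestResult(
        omnibus_f=float(ftest.fvalue),
        omnibus_df=(float(ftest.df_num), float(ftest.df_denom)),
        omnibus_p=float(ftest.pvalue),
        slopes=pd.DataFrame(slope_rows),
        average_slope={
            "estimate": float(t_avg.effect[0]),
            "se": float(t_avg.sd[0][0]),
            "t": float(t_avg.tvalue[0][0]),
            "p": float(t_avg.pvalue),
            "excluded": list(average_exclude),
        },
        note=note,
    )


# ---------------------------------------------------------------------------
# mixed model on |brain-PAD|


@dataclass
class MixedPadResult:
    contrasts: pd.DataFrame  # modality vs reference, within-subject difference
    mae_hat: pd.DataFrame  # per-modality population MAE estimates
    total_mae: dict
    reference: str
    converged: bool
    degenerate: bool = False
    random_effect_var: float = float("nan")
    residual_var: float = float("nan")
    warnings_: List[str] = field(default_factory=list)


def _fe_contrast(L, params, cov, alpha):
    est = float(L @ params)
    se = float(np.sqrt(L @ cov @ L)) if cov is not None else 0.0
    if se > 0:
        z = est / se
        p = 2 * sps.norm.sf(abs(z))
        zq = sps.norm.isf(alpha / 2)
        lo, hi = est - zq * se, est + zq * se
    else:
        z, p, lo, hi = float("nan"), float("nan"), est, est
    return est, se, z, p, lo, hi


def mixed_abs_pad_model(
    records: pd.DataFrame,
    pad_column: str = "pad",
    reference: str = "MPRAGE",
    alpha: float = 0.05,
) -> MixedPadResult:
    """REML mixed model |brain-PAD| ~ subject + modality + (1 | subject).

    Fixed effects for subject and modality with a subject random intercept,
    fitted by restricted maximum likelihood with a quasi-Newton (L-BFGS)
    optimizer; the random intercept carries the within-subject covariance of
    the repeated measures.  Reports each modality's within-subject contrast
    against the reference (beta_m - beta_ref) with CIs, a per-modality
    "population" MAE estimate <s_i> + beta_m, and the mean of those estimates
    across modalities.  Non-convergence is reported, never silent.  A
    perfectly fitting (zero-residual) model short-circuits to the exact
    least-squares solution with degenerate (zero-width) intervals.
    """
    df = records[["participant_id", "modality"]].copy()
    df["abs_pad"] = np.abs(records[pad_column].to_numpy(float))
    modalities = sorted(df["modality"].unique())
    if reference not in modalities:
        raise ValueError(f"reference modality {reference!r} not present")
    if len(modalities) < 2:
        raise ValueError("need at least 2 modalities")

    formula = (
        "abs_pad ~ C(participant_id) + "
        f"C(modality, Treatment(reference={reference!r}))"
    )
    ref_participants = set(
        df.loc[df["modality"] == reference, "participant_id"]
    )
    paired = {
        m: bool(
            set(df.loc[df["modality"] == m, "participant_id"]) & ref_participants
        )
        for m in modalities
    }

    warns: List[str] = []
    ols = smf.ols(formula, data=df).fit()
    degenerate = ols.ssr <= 1e-10 * max(1.0, float(np.sum(df["abs_pad"] ** 2)))
    if degenerate:
        params = ols.params.to_numpy()
        cov = None
        names = ols.model.exog_names
        converged = True
        re_var, resid_var = 0.0, 0.0
        warns.append("zero-residual fit; exact least-squares solution reported")
    else:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            md = smf.mixedlm(formula, data=df, groups=df["participant_id"],
                             re_formula="1")
            fit = md.fit(reml=True, method="lbfgs", maxiter=200)
        warns.extend(str(w.message) for w in caught)
        converged = bool(fit.converged)
        if not converged:
            logger.warning("mixed model did not converge: %s", warns[-3:])
        names = fit.model.exog_names
        params = fit.fe_params.to_numpy()
        k_fe = len(names)
        cov = np.asarray(fit.cov_params())[:k_fe, :k_fe]
        re_var = float(np.asarray(fit.cov_re).squeeze())
        resid_var = float(fit.scale)

    n_subj = df["participant_id"].nunique()
    subj_cols = [i for i, nm in enumerate(names) if nm.startswith("C(participant_id)")]
    mod_name = {
        m: f"C(modality, Treatment(reference={reference!r}))[T.{m}]"
        for m in modalities
        if m != reference
    }

    contrast_rows, mae_rows, mae_L = [], [], []
    for m in modalities:
        # population MAE: intercept + mean subject effect + beta_m
        L = np.zeros(len(names))
        L[names.index("Intercept")] = 1.0
        for i in subj_cols:
            L[i] = 1.0 / n_subj
        if m != reference:
            L[names.index(mod_name[m])] = 1.0
        mae_L.append(L)
        est, se, z, p, lo, hi = _fe_contrast(L, params, cov, alpha)
        mae_rows.append({"modality": m, "mae_hat": est, "se": se,
                         "lo": lo, "hi": hi})
        if m == reference:
            continue
        Lc = np.zeros(len(names))
        Lc[names.index(mod_name[m])] = 1.0
        est, se, z, p, lo, hi = _fe_contrast(Lc, params, cov, alpha)
        contrast_rows.append(
            {"modality": m, "estimate": est, "se": se, "z": z, "p": p,
             "lo": lo, "hi": hi,
             "within_subject": paired[m]}
        )
        if not paired[m]:
            logger.warning(
                "modality %r shares no participants with %r; contrast is "
                "between-subject only", m, reference,
            )

    L_tot = np.vstack(mae_L).mean(axis=0)
    est, se, z, p, lo, hi = _fe_contrast(L_tot, params, cov, alpha)
    return MixedPadResult(
        contrasts=pd.DataFrame(contrast_rows),
        mae_hat=pd.DataFrame(mae_rows),
        total_mae={"estimate": est, "se": se, "lo": lo, "hi": hi},
        reference=reference,
        converged=converged,
        degenerate=degenerate,
        random_effect_var=re_var,
        residual_var=resid_var,
        warnings_=warns,
    )
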