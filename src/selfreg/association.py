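"""Group-level inference: correlations with bootstrap uncertainty,
two-stage approximations of the mixed-effects models, and end-to-end
parameter-recovery experiments.

The cross-task question — does emotion-reappraisal success predict
dietary self-control success? — is answered with rank (Spearman) or
linear (Pearson) correlations.  Uncertainty comes from a BCa bootstrap:
the point estimate matches the classical coefficient, the 95% interval
plays the role of a credible interval, and ``pp_positive`` (the
fraction of the bootstrap distribution above zero) approximates a
posterior probability that the correlation is positive.

Mixed-effects regressions are approximated by the two-stage
summary-statistics approach: fit each participant separately, then
treat the per-participant coefficients as a sample and summarize them
with a mean and t-interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import ddm as ddm_mod
from .cohort import generate_cohort
from .reappraisal import reappraisal_success_scores
from .scores import compute_trial_scores, fit_taste_health_weights, score_self_control
from .types import CohortConfig, CorrelationResult

__all__ = [
    "correlate",
    "two_stage_group_model",
    "cross_task_association",
    "score_cohort",
    "parameter_recovery_experiment",
]


def _rank_corr_stat(x, y, axis=-1):
    xr = stats.rankdata(x, axis=axis)
    yr = stats.rankdata(y, axis=axis)
    return _pearson_stat(xr, yr, axis=axis)


def _pearson_stat(x, y, axis=-1):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x - x.mean(axis=axis, keepdims=True)
    ym = y - y.mean(axis=axis, keepdims=True)
    num = (xm * ym).sum(axis=axis)
    den = np.sqrt((xm**2).sum(axis=axis) * (ym**2).sum(axis=axis))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def correlate(
    x,
    y,
    method: str = "rank",
    n_resamples: int = 10000,
    seed=None,
) -> CorrelationResult:
    """Correlation with a BCa bootstrap 95% interval.

    Parameters
    ----------
    x, y : paired per-participant scores; pairs with a missing value in
        either vector are dropped (pairwise-complete).
    method : ``"rank"`` (Spearman) or ``"linear"`` (Pearson).

    Raises
    ------
    ValueError : with fewer than 4 complete pairs or a constant input.
    """
    if method not in ("rank", "linear"):
        raise ValueError(f"method must be 'rank' or 'linear', got {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector: correlation undefined")

    stat = _rank_corr_stat if method == "rank" else _pearson_stat
    rho = float(stat(x, y))

    rng = np.random.default_rng(seed)
    # cap resample-matrix memory (BCa jackknifes all n leave-one-out sets)
    batch = max(1, int(5_000_000 // n))
    import warnings as _warnings

    with _warnings.catch_warnings():
        # a degenerate bootstrap distribution (e.g. rho identically 1)
        # is handled by the fallback below
        _warnings.simplefilter("ignore")
        res = stats.bootstrap(
            (x, y),
            stat,
            paired=True,
            vectorized=True,
            n_resamples=n_resamples,
            confidence_level=0.95,
            method="BCa",
            batch=batch,
            random_state=rng,
        )
    boot = res.bootstrap_distribution
    boot = boot[np.isfinite(boot)]
    lo, hi = res.confidence_interval
    if not np.isfinite(lo):
        lo = float(np.min(boot)) if boot.size else rho
    if not np.isfinite(hi):
        hi = float(np.max(boot)) if boot.size else rho
    pp_pos = float(np.mean(boot > 0)) if boot.size else float(rho > 0)
    return CorrelationResult(
        rho=rho,
        interval_low=float(min(lo, rho)),
        interval_high=float(max(hi, rho)),
        pp_positive=pp_pos,
        method=method,
        n=int(n),
    )


def two_stage_group_model(per_participant_fits: pd.DataFrame) -> dict:
    """Stage-2 summary of per-participant (stage-1) coefficients.

    ``per_participant_fits``: one row per participant, one column per
    model term (an optional boolean ``converged`` column restricts the
    summary to converged fits).  Returns group means with 95%
    t-intervals; a zero between-participant SD flags the interval as
    degenerate.
    """
    df = per_participant_fits.copy()
    if "converged" in df.columns:
        df = df[df["converged"].astype(bool)]
        df = df.drop(columns=["converged"])
    df = df.select_dtypes(include=[np.number])
    if len(df) < 3:
        raise ValueError(f"need >= 3 converged participants, got {len(df)}")
    terms = {}
    n = len(df)
    tcrit = stats.t.ppf(0.975, n - 1)
    for col in df.columns:
        vals = df[col].to_numpy(dtype=float)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        half = tcrit * sd / np.sqrt(n)
        terms[col] = {
            "estimate": mean,
            "interval_low": mean - half,
            "interval_high": mean + half,
            "sd": sd,
            "degenerate": bool(sd == 0.0),
        }
    return {"terms": terms, "n_participants": n, "per_participant": df}


def covariate_effects(
    per_participant_values: pd.DataFrame,
    covariates: pd.DataFrame,
) -> dict:
    """Between-participant covariate regression (stage 2 of the two-stage
    scheme for person-level covariates such as hunger, BMI, restraint or
    gender, which are constant within participant).

    Each column of ``per_participant_values`` is regressed on the
    standardized covariates (categorical covariates are dummy-coded);
    returns per-term estimates with 95% confidence intervals.
    """
    import statsmodels.api as sm

    X = pd.get_dummies(covariates, drop_first=True).astype(float)
    X = (X - X.mean()) / X.std(ddof=0).replace(0.0, 1.0)
    X = sm.add_constant(X)
    out = {}
    for col in per_participant_values.columns:
        y = per_participant_values[col].to_numpy(dtype=float)
        res = sm.OLS(y, X).fit()
        ci = res.conf_int()
        out[col] = {
            term: {
                "estimate": float(res.params[term]),
                "interval_low": float(ci.loc[term, 0]),
                "interval_high": float(ci.loc[term, 1]),
            }
            for term in res.params.index
        }
    return out


def cross_task_association(
    participant_scores: pd.DataFrame,
    reappraisal_scores: pd.DataFrame,
    n_resamples: int = 10000,
    seed=None,
) -> dict[str, CorrelationResult]:
    """Rank correlations of dietary success vs reappraisal success.

    Joins the two per-participant tables on ``participant_id``, applies
    each task's exclusions (a participant may be usable in one task
    only), and reports overall-vs-overall plus the valence-wise
    breakdowns.
    """
    ps = participant_scores
    if "excluded_flag" in ps.columns:
        ps = ps[~ps["excluded_flag"].astype(bool)]
    merged = ps.merge(
        reappraisal_scores,
        on="participant_id",
        how="inner",
        suffixes=("_diet", "_reapp"),
    )
    if len(merged) < 4:
        raise ValueError(f"only {len(merged)} overlapping participants (< 4)")
    seeds = np.random.SeedSequence(seed).spawn(3)
    out = {}
    for key, col, ss in (
        ("overall", "success_overall_reapp", seeds[0]),
        ("positive", "success_pos", seeds[1]),
        ("negative", "success_neg", seeds[2]),
    ):
        out[key] = correlate(
            merged["success_overall_diet"],
            merged[col],
            method="rank",
            n_resamples=n_resamples,
            seed=np.random.default_rng(ss),
        )
    return out


def score_cohort(dataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the scoring stage over a generated cohort.

    Returns (participant_scores, reappraisal_scores) tables; scoring
    failures (separation, all-missed) become exclusion flags.
    """
    rows = []
    for pid, g in dataset.choices.groupby("participant_id"):
        excluded, reason = False, ""
        fit = None
        try:
            fit = fit_taste_health_weights(g)
            if fit.separation_flag:
                excluded, reason = True, "separation in taste/health weight fit"
        except ValueError as err:
            excluded, reason = True, str(err)
        summ = score_self_control(g)
        if not summ.defined:
            excluded, reason = True, reason or "no responded challenge trials"
        rows.append(
            {
                "participant_id": pid,
                "w_taste": fit.w_taste if fit else np.nan,
                "w_health": fit.w_health if fit else np.nan,
                "se_taste": fit.se_taste if fit else np.nan,
                "se_health": fit.se_health if fit else np.nan,
                "success_overall": summ.level if summ.defined else np.nan,
                "success_htlh": summ.level_htlh,
                "success_lthh": summ.level_lthh,
                "n_challenge": summ.n_challenge_responded,
                "excluded_flag": excluded,
                "exclusion_reason": reason,
            }
        )
    # participants excluded at the design stage never appear in choices
    for _, r in dataset.exclusions[dataset.exclusions["excluded"]].iterrows():
        rows.append(
            {
                "participant_id": r["participant_id"],
                "w_taste": np.nan,
                "w_health": np.nan,
                "se_taste": np.nan,
                "se_health": np.nan,
                "success_overall": np.nan,
                "success_htlh": None,
                "success_lthh": None,
                "n_challenge": 0,
                "excluded_flag": True,
                "exclusion_reason": r["reason"],
            }
        )
    ps = pd.DataFrame(rows).sort_values("participant_id").reset_index(drop=True)

    rrows = []
    for pid, g in dataset.emotion.groupby("participant_id"):
        rs = reappraisal_success_scores(g)
        rrows.append(
            {
                "participant_id": pid,
                "success_neg": rs.success_neg,
                "success_pos": rs.success_pos,
                "success_overall": rs.success_overall,
                "n_neg": rs.n_neg,
                "n_pos": rs.n_pos,
            }
        )
    return ps, pd.DataFrame(rrows)


def parameter_recovery_experiment(
    config: CohortConfig,
    ddm_trials_per_participant: int = 1000,
    seed=None,
) -> dict:
    """Simulate -> score -> fit -> compare, reporting bias and RMSE.

    Covers: the taste/health weights (fitted logistic coefficients vs
    the effective generating slopes ``a * drift_scale * w``, the slope a
    logistic read-out of diffusion choices approximates), the
    drift-diffusion starting point (refit from freshly simulated trials
    at ``ddm_trials_per_participant`` per participant), the regulation
    deltas vs measured reappraisal success, and the cross-task coupling
    vs the correlation among the generating parameters.

    Returns a JSON-serializable report.
    """
    rng_master = np.random.SeedSequence(seed if seed is not None else config.seed)
    s_ddm, s_fit = rng_master.spawn(2)
    dataset = generate_cohort(config)
    ps, rs = score_cohort(dataset)
    gt = dataset.ground_truth.set_index("participant_id")

    merged = ps[~ps["excluded_flag"]].set_index("participant_id").join(gt, rsuffix="_gt")
    eff_t = merged["ddm_a"] * merged["ddm_drift_scale"] * merged["w_taste_gt"]
    eff_h = merged["ddm_a"] * merged["ddm_drift_scale"] * merged["w_health_gt"]

    def _bias_rmse(est, truth):
        d = np.asarray(est, dtype=float) - np.asarray(truth, dtype=float)
        d = d[np.isfinite(d)]
        return {"bias": float(np.mean(d)), "rmse": float(np.sqrt(np.mean(d**2))),
                "n": int(d.size)}

    report = {
        "w_taste": _bias_rmse(merged["w_taste"], eff_t),
        "w_health": _bias_rmse(merged["w_health"], eff_h),
    }
    # CI coverage of the effective slopes by the logistic Wald intervals
    for name, eff, se_col, est_col in (
        ("w_taste", eff_t, "se_taste", "w_taste"),
        ("w_health", eff_h, "se_health", "w_health"),
    ):
        lo = merged[est_col] - 1.96 * merged[se_col]
        hi = merged[est_col] + 1.96 * merged[se_col]
        cov = ((eff >= lo) & (eff <= hi)).mean()
        report[name]["coverage"] = float(cov)

    # drift-diffusion starting-point recovery on fresh trials
    z_hats = []
    rng_ddm = np.random.default_rng(s_ddm)
    for pid, prof in zip(gt.index, dataset.profiles):
        sv = rng_ddm.uniform(-3.0, 3.0, ddm_trials_per_participant)
        ch, rt = ddm_mod.simulate_trials(
            prof.ddm, prof.ddm.drift_scale * sv, rng=rng_ddm
        )
        fit = ddm_mod.fit_mle(rt, ch, sv, seed=rng_ddm.integers(2**31))
        z_hats.append(fit.params.z_rel)
    report["z_rel"] = _bias_rmse(z_hats, [p.ddm.z_rel for p in dataset.profiles])
    report["z_rel"]["mean_estimate"] = float(np.mean(z_hats))

    # regulation deltas vs measured reappraisal success
    rr = rs.set_index("participant_id").join(gt)
    report["success_neg_vs_delta_neg"] = _bias_rmse(rr["success_neg"], rr["delta_neg"])
    report["success_pos_vs_delta_pos"] = _bias_rmse(rr["success_pos"], rr["delta_pos"])

    # coupling: measured efficacy vs fitted health weight, against ground truth
    eff_gt = (gt["delta_neg"] + gt["delta_pos"]) / 2.0
    gt_corr = float(stats.spearmanr(eff_gt, gt["w_health"]).statistic)
    meas = rr[["success_neg", "success_pos"]].mean(axis=1).to_frame("efficacy").join(
        ps.set_index("participant_id")["w_health"]
    ).dropna()
    meas_corr = (
        float(stats.spearmanr(meas["efficacy"], meas["w_health"]).statistic)
        if len(meas) >= 4
        else float("nan")
    )
    report["coupling"] = {
        "configured_rho": config.coupling_rho,
        "ground_truth_rho": gt_corr,
        "recovered_rho": meas_corr,
    }
    report["n_participants"] = int(config.n_participants)
    report["ddm_trials_per_participant"] = int(ddm_trials_per_participant)
    return report
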