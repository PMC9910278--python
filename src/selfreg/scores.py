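"""Trial- and participant-level dietary scores.

Four quantities are computed from each participant's choices:

* **taste/health weights** — per-participant logistic regression of the
  eat/refuse choice on mean-centered taste and health ratings; the
  fitted coefficients quantify the subjective importance of each
  attribute (log-odds per rating unit);
* **subjective food value** ``sv = w_taste*tr_c + w_health*hr_c`` —
  the weighted evidence for eating, intercept excluded;
* **decision conflict** ``-|sv|`` — maximal (0) when the weighted
  evidence for eating versus refusing is balanced;
* **self-control stakes** ``|tr| + |hr|`` on challenge trials, zero on
  aligned trials — how much is to be gained or lost by exerting
  control.  For the modulator path, stakes are residualized against
  conflict so they carry only unique variance.

Self-control success is the proportion of responded challenge trials
resolved in favor of health: refusing an HTLH food or accepting an
LTHH food.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import classify_trial_type
from .types import CHALLENGE_TYPES, SelfControlSummary, WeightFit

__all__ = [
    "fit_taste_health_weights",
    "ridge_logistic_irls",
    "subjective_value",
    "decision_conflict",
    "stakes",
    "orthogonalize_modulator",
    "score_self_control",
    "compute_trial_scores",
]

_SEPARATION_COEF = 15.0  # |coef| beyond this is treated as quasi-separation


def ridge_logistic_irls(X: np.ndarray, y: np.ndarray, penalty: float = 0.5,
                        maxiter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Logistic regression by iteratively reweighted least squares with a
    small quadratic (ridge) penalty on all coefficients.

    Used as the fallback when the unpenalized likelihood has no finite
    maximum (perfect or quasi-separation, e.g. a participant who never
    chose to eat)."""
    beta = np.zeros(X.shape[1])
    lam = penalty * np.eye(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = X.T @ (y - mu) - penalty * beta
        hess = (X * w[:, None]).T @ X + lam
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def fit_taste_health_weights(trials: pd.DataFrame) -> WeightFit:
    """Fit yes ~ 1 + taste_c + health_c per participant by IRLS.

    ``trials`` needs columns ``tr``, ``hr``, ``choice`` (yes/no/missed).
    Ratings are mean-centered within participant over all presented
    foods (missed trials included in the centering, excluded from the
    likelihood).  On detected separation the fit falls back to a small
    ridge penalty and sets ``separation_flag``.

    Raises
    ------
    ValueError : if every choice was missed, or an attribute has zero
        variance (the weight is unidentifiable).
    """
    tr_c = trials["tr"].to_numpy(dtype=float)
    hr_c = trials["hr"].to_numpy(dtype=float)
    tr_c = tr_c - tr_c.mean()
    hr_c = hr_c - hr_c.mean()
    responded = trials["choice"].isin(["yes", "no"]).to_numpy()
    if not responded.any():
        raise ValueError("all choices missed: cannot fit taste/health weights")
    y = (trials["choice"].to_numpy() == "yes")[responded].astype(float)
    X = np.column_stack([np.ones(responded.sum()), tr_c[responded], hr_c[responded]])
    if np.ptp(X[:, 1]) == 0 or np.ptp(X[:, 2]) == 0:
        raise ValueError("zero variance in taste or health ratings: weight undefined")

    n_used = int(responded.sum())
    both_outcomes = 0 < y.sum() < len(y)
    separated = not both_outcomes
    beta = se = None
    if both_outcomes:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
                beta = np.asarray(res.params)
                se = np.asarray(res.bse)
                if (not res.converged) or np.any(np.abs(beta) > _SEPARATION_COEF):
                    separated = True
            except Exception:
                separated = True
    if separated:
        beta = ridge_logistic_irls(X, y)
        se = np.full(3, np.nan)

    return WeightFit(
        beta0=float(beta[0]),
        w_taste=float(beta[1]),
        w_health=float(beta[2]),
        converged=bool(np.all(np.isfinite(beta))),
        separation_flag=bool(separated),
        se_taste=float(se[1]),
        se_health=float(se[2]),
        n_used=n_used,
    )


def subjective_value(tr_c: float, hr_c: float, fit: WeightFit) -> float:
    """Weighted taste plus weighted health (intercept excluded)."""
    if not fit.converged:
        raise ValueError("weight fit did not converge; subjective value undefined")
    return fit.w_taste * tr_c + fit.w_health * hr_c


def decision_conflict(tr_c: float, hr_c: float, fit: WeightFit) -> float:
    """Negative absolute subjective value; 0 = maximal conflict."""
    return -abs(subjective_value(tr_c, hr_c, fit))


def stakes(tr: float, hr: float, trial_type: str | None = None) -> float:
    """Self-control stakes: |tr| + |hr| on challenge trials, else 0.

    Stakes are defined to be zero throughout the aligned (HTHH, LTLH)
    quadrants, where taste and health agree and no control is needed.
    """
    derived = classify_trial_type(tr, hr)
    if derived is None:
        raise ValueError(f"neutral-zone item (tr={tr}, hr={hr}) has no stakes")
    if trial_type is not None and trial_type != derived:
        raise ValueError(f"trial_type {trial_type} inconsistent with ratings ({derived})")
    return float(abs(tr) + abs(hr)) if derived in CHALLENGE_TYPES else 0.0


def orthogonalize_modulator(target, reference) -> np.ndarray:
    """Residualize ``target`` against ``reference`` (plus intercept).

    Both vectors are mean-centered first (the standard parametric-
    modulator convention); the returned residual has zero mean and zero
    inner product with the reference.  A constant reference carries no
    variance to remove: the mean-centered target is returned with a
    warning.
    """
    t = np.asarray(target, dtype=float)
    r = np.asarray(reference, dtype=float)
    if t.shape != r.shape or t.ndim != 1 or t.size < 2:
        raise ValueError("target and reference must be equal-length vectors (n >= 2)")
    t = t - t.mean()
    r = r - r.mean()
    if np.allclose(r, 0.0):
        warnings.warn("constant reference: returning mean-centered target", RuntimeWarning,
                      stacklevel=2)
        return t
    return t - (t @ r) / (r @ r) * r


def score_self_control(trials: pd.DataFrame) -> SelfControlSummary:
    """Self-control success levels over responded challenge trials.

    Success: refusing an HTLH food or accepting an LTHH food.  Missed
    challenge trials enter neither numerator nor denominator.  With no
    responded challenge trials the level is undefined and flagged.
    """
    ch = trials[trials["trial_type"].isin(CHALLENGE_TYPES)]
    responded = ch[ch["choice"].isin(["yes", "no"])]
    n_missed = len(ch) - len(responded)
    if len(responded) == 0:
        return SelfControlSummary(None, None, None, 0, 0, 0, n_missed, defined=False)
    success = (
        ((responded["trial_type"] == "HTLH") & (responded["choice"] == "no"))
        | ((responded["trial_type"] == "LTHH") & (responded["choice"] == "yes"))
    )
    htlh = responded["trial_type"] == "HTLH"
    lthh = responded["trial_type"] == "LTHH"
    return SelfControlSummary(
        level=float(success.mean()),
        level_htlh=float(success[htlh].mean()) if htlh.any() else None,
        level_lthh=float(success[lthh].mean()) if lthh.any() else None,
        n_challenge_responded=int(len(responded)),
        n_htlh_responded=int(htlh.sum()),
        n_lthh_responded=int(lthh.sum()),
        n_missed_challenge=int(n_missed),
        defined=True,
    )


def scs_flags(trials: pd.DataFrame) -> pd.Series:
    """Per-trial success indicator: 1/0 on responded challenge trials,
    NaN elsewhere (non-challenge or missed)."""
    ch = trials["trial_type"].isin(CHALLENGE_TYPES)
    responded = trials["choice"].isin(["yes", "no"])
    ok = ch & responded
    scs = pd.Series(np.nan, index=trials.index, name="scs")
    succ = ((trials["trial_type"] == "HTLH") & (trials["choice"] == "no")) | (
        (trials["trial_type"] == "LTHH") & (trials["choice"] == "yes")
    )
    scs[ok] = succ[ok].astype(float)
    return scs


def compute_trial_scores(trials: pd.DataFrame, fit: WeightFit) -> pd.DataFrame:
    """Trial-wise sv / conflict / stakes / orthogonalized stakes table.

    Centering matches :func:`fit_taste_health_weights` (within
    participant over all presented foods).  Orthogonalized stakes are
    computed over challenge trials only and are NaN elsewhere (stakes
    are identically zero off the challenge quadrants, so there is
    nothing to residualize).
    """
    if not fit.converged:
        raise ValueError("weight fit did not converge")
    tr = trials["tr"].to_numpy(dtype=float)
    hr = trials["hr"].to_numpy(dtype=float)
    tr_c = tr - tr.mean()
    hr_c = hr - hr.mean()
    sv = fit.w_taste * tr_c + fit.w_health * hr_c
    conflict = -np.abs(sv)
    stk = np.array(
        [stakes(t, h, tt) for t, h, tt in zip(tr, hr, trials["trial_type"])]
    )
    out = trials.copy()
    out["sv"] = sv
    out["conflict"] = conflict
    out["stakes"] = stk
    out["stakes_orth"] = np.nan
    is_ch = trials["trial_type"].isin(CHALLENGE_TYPES).to_numpy()
    if is_ch.sum() >= 2:
        out.loc[is_ch, "stakes_orth"] = orthogonalize_modulator(
            stk[is_ch], conflict[is_ch]
        )
    out["scs"] = scs_flags(trials)
    return out
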