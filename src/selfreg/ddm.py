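"""Drift-diffusion model of accept/refuse food choices.

A single-stage Wiener diffusion between two absorbing boundaries:
evidence starts at ``z_rel * a`` (measured from the lower boundary),
drifts at rate ``v = drift_scale * sv`` (``sv`` = trial-wise subjective
food value), and diffuses with unit coefficient.  Absorption at the
upper boundary is read out as "yes/eat", at the lower boundary as
"no/refuse"; responses slower than the 3-s window are censored
("missed").  A starting point below 0.5 encodes a prior bias toward
refusing the foods.

The first-passage-time density is evaluated by the classic pair of
series expansions (a small-time expansion in image terms and a
large-time eigenfunction expansion), switching per evaluation point to
whichever needs fewer terms for the requested tolerance.  Likelihoods
for censored trials use the analytic survival series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .types import DDMFit, DDMParams, RESPONSE_WINDOW_S

__all__ = [
    "wiener_fpt_density",
    "upper_choice_probability",
    "survival_probability",
    "simulate_trials",
    "fit_mle",
    "negative_log_likelihood",
]

_SERIES_TOL = 1e-7
_MAX_TERMS = 64


def _f1_lower(tau: np.ndarray, w: float, tol: float = _SERIES_TOL) -> np.ndarray:
    """Zero-drift, unit-boundary FPT density at the lower boundary.

    ``tau`` is diffusion time normalized by a^2; ``w`` the relative
    starting point.  Term counts follow the standard error bounds for
    the two expansions; the cheaper one is used per element.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not np.any(pos):
        return out
    t = tau[pos]

    # required terms, small-time expansion
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = 2.0 * tol * np.sqrt(2.0 * np.pi * t)
        ks = np.where(
            arg < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(arg), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        # required terms, large-time expansion
        argl = np.pi * t * tol
        kl = np.where(
            argl < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(argl), 0.0) / (np.pi**2 * t)),
            1.0 / (np.pi * np.sqrt(t)),
        )
        kl = np.maximum(kl, 1.0)

    use_small = ks < kl
    res = np.empty_like(t)

    if np.any(use_small):
        ts = t[use_small]
        K = int(min(np.ceil(ks[use_small].max()), _MAX_TERMS))
        k = np.arange(-K, K + 1)[:, None]
        terms = (w + 2.0 * k) * np.exp(-((w + 2.0 * k) ** 2) / (2.0 * ts[None, :]))
        res[use_small] = terms.sum(axis=0) / np.sqrt(2.0 * np.pi * ts**3)

    if np.any(~use_small):
        tl = t[~use_small]
        K = int(min(np.ceil(kl[~use_small].max()), _MAX_TERMS))
        k = np.arange(1, K + 1)[:, None]
        terms = k * np.exp(-(k**2) * np.pi**2 * tl[None, :] / 2.0) * np.sin(k * np.pi * w)
        res[~use_small] = np.pi * terms.sum(axis=0)

    out[pos] = np.maximum(res, 0.0)
    return out


def wiener_fpt_density(t, params: DDMParams, drift: float, boundary: str):
    """First-passage-time density of the decision time at one boundary.

    Parameters
    ----------
    t : decision time(s) in seconds, strictly positive (non-decision
        time already removed).
    drift : drift rate ``v`` (positive = toward the upper/yes boundary).
    boundary : ``"upper"`` or ``"lower"``.

    Returns the defective density (it integrates to the probability of
    absorbing at that boundary, not to 1).
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr <= 0):
        raise ValueError("decision time must be > 0")
    a, w = params.a, params.z_rel
    v = float(drift)
    if boundary == "upper":
        v, w = -v, 1.0 - w
    elif boundary != "lower":
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    dens = (
        np.exp(-v * a * w - v**2 * t_arr / 2.0) / a**2 * _f1_lower(t_arr / a**2, w)
    )
    return float(dens[0]) if scalar else dens


def upper_choice_probability(params: DDMParams, drift) -> np.ndarray | float:
    """Probability of absorbing at the upper (yes/eat) boundary.

    ``(1 - exp(-2 v z)) / (1 - exp(-2 v a))`` with ``z = z_rel * a``;
    continuous at v = 0 where it equals ``z_rel``.
    """
    v = np.asarray(drift, dtype=float)
    scalar = v.ndim == 0
    v = np.atleast_1d(v)
    a = params.a
    z = params.z_rel * a
    p = np.empty_like(v)
    tiny = np.abs(v) < 1e-10
    p[tiny] = params.z_rel
    vv = v[~tiny]
    # expm1 keeps the ratio stable near 0; switch to exponent arithmetic
    # when the arguments would overflow (strong negative drift).
    big = -2.0 * vv * a > 700.0
    raw = np.empty_like(vv)
    raw[~big] = np.expm1(-2.0 * vv[~big] * z) / np.expm1(-2.0 * vv[~big] * a)
    raw[big] = np.exp(2.0 * vv[big] * (a - z))
    p[~tiny] = raw
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if scalar else p


def _survival_one_boundary(t: float, params: DDMParams, v: np.ndarray, lower: bool,
                           n_terms: int = 128) -> np.ndarray:
    """P(not yet absorbed at the given boundary by decision time t)...

    Actually returns P(absorbed at this boundary AFTER time t), i.e. the
    tail mass of the defective FPT distribution at that boundary,
    obtained by term-wise integration of the large-time series.
    """
    a, w = params.a, params.z_rel
    v = np.asarray(v, dtype=float)
    if lower:
        vv, ww = v, w
    else:
        vv, ww = -v, 1.0 - w
    k = np.arange(1, n_terms + 1)[:, None]
    lam = (vv[None, :] ** 2 + k**2 * np.pi**2 / a**2) / 2.0
    with np.errstate(over="ignore", under="ignore"):
        series = (k * np.sin(k * np.pi * ww)) * np.exp(-lam * t) / lam
        tail = np.pi / a**2 * np.exp(-vv * a * ww) * series.sum(axis=0)
    return np.clip(tail, 0.0, 1.0)


def survival_probability(t: float, params: DDMParams, drift) -> np.ndarray | float:
    """P(decision time > t): probability mass censored beyond ``t``."""
    if t <= 0:
        return np.ones_like(np.asarray(drift, dtype=float)) if np.ndim(drift) else 1.0
    v = np.atleast_1d(np.asarray(drift, dtype=float))
    s = _survival_one_boundary(t, params, v, lower=True) + _survival_one_boundary(
        t, params, v, lower=False
    )
    s = np.clip(s, 0.0, 1.0)
    return float(s[0]) if np.ndim(drift) == 0 else s


def simulate_trials(
    params: DDMParams,
    drifts,
    max_rt: float = RESPONSE_WINDOW_S,
    seed=None,
    dt: float = 1e-3,
    rng: np.random.Generator | None = None,
    bridge: bool = True,
):
    """Simulate choices and RTs by Euler-Maruyama with boundary-bridge correction.

    Between steps the path is a Brownian bridge; absorbing with the
    bridge crossing probability removes the leading-order discretization
    bias of naive Euler first-passage sampling, so the default 1-ms step
    gives near-exact RT distributions.

    Returns
    -------
    (choices, rts) : choices is an array of ``"yes"``/``"no"``/``"missed"``;
        rts are ``t0 + decision time`` for responded trials, NaN for missed.
    """
    drifts = np.asarray(drifts, dtype=float)
    if drifts.size == 0:
        raise ValueError("empty drift vector: nothing to simulate")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = drifts.size
    a = params.a
    window = max_rt - params.t0
    n_steps = int(np.ceil(window / dt))

    choices = np.full(n, "missed", dtype=object)
    rts = np.full(n, np.nan)

    idx = np.arange(n)
    x = np.full(n, params.z_rel * a)
    v = drifts.copy()
    sqdt = np.sqrt(dt)

    for step in range(n_steps):
        if idx.size == 0:
            break
        x_new = x + v * dt + sqdt * rng.standard_normal(idx.size)
        hit_up = x_new >= a
        hit_lo = x_new <= 0.0
        if bridge:
            free = ~(hit_up | hit_lo)
            if np.any(free):
                xo, xn = x[free], x_new[free]
                with np.errstate(over="ignore", under="ignore"):
                    p_up = np.exp(-2.0 * (a - xo) * (a - xn) / dt)
                    p_lo = np.exp(-2.0 * xo * xn / dt)
                u = rng.random(xo.size)
                cross_up = u < p_up
                cross_lo = (~cross_up) & (u < p_up + p_lo)
                f_idx = np.flatnonzero(free)
                hit_up[f_idx[cross_up]] = True
                hit_lo[f_idx[cross_lo]] = True
        done = hit_up | hit_lo
        if np.any(done):
            t_dec = (step + 1) * dt
            rt = params.t0 + t_dec
            if rt <= max_rt:
                sel = idx[done]
                choices[sel] = np.where(hit_up[done], "yes", "no")
                rts[sel] = rt
            keep = ~done
            idx, x, v = idx[keep], x_new[keep], v[keep]
        else:
            x = x_new

    return choices, rts


def negative_log_likelihood(
    theta,
    rts: np.ndarray,
    yes: np.ndarray,
    missed: np.ndarray,
    sv: np.ndarray,
    censor: float = RESPONSE_WINDOW_S,
) -> float:
    """Censored negative log-likelihood at theta = (a, z_rel, t0, drift_scale).

    Responded trials contribute the boundary density at their RT; missed
    trials contribute the survival mass beyond the response window.
    """
    a, z_rel, t0, drift_scale = theta
    if a <= 0 or not (0 < z_rel < 1) or t0 < 0:
        return np.inf
    resp = ~missed
    dt_dec = rts[resp] - t0
    if np.any(dt_dec <= 0) or censor - t0 <= 0:
        return np.inf
    params = DDMParams(a=a, z_rel=z_rel, t0=t0, drift_scale=drift_scale)
    v = drift_scale * sv
    ll = 0.0
    yes_r = yes[resp]
    v_r = v[resp]
    for is_yes, boundary in ((True, "upper"), (False, "lower")):
        m = yes_r == is_yes
        if not np.any(m):
            continue
        # density depends on the trial's own drift: evaluate per drift value
        dens = np.array(
            [
                wiener_fpt_density(t, params, vi, boundary)
                for t, vi in zip(dt_dec[m], v_r[m])
            ]
        )
        ll += np.sum(np.log(np.maximum(dens, 1e-300)))
    if np.any(missed):
        surv = survival_probability(censor - t0, params, v[missed])
        ll += np.sum(np.log(np.maximum(surv, 1e-300)))
    return -ll


def _nll_vectorized(theta, rts, yes, missed, sv, censor):
    """Same likelihood as :func:`negative_log_likelihood` but batching the
    density series across trials (used by the optimizer)."""
    a, z_rel, t0, drift_scale = theta
    if a <= 0 or not (0 < z_rel < 1) or t0 < 0:
        return np.inf
    resp = ~missed
    dt_dec = rts[resp] - t0
    if dt_dec.size and np.min(dt_dec) <= 0:
        return np.inf
    if censor - t0 <= 0:
        return np.inf
    v = drift_scale * sv
    yes_r = yes[resp]
    v_r = v[resp]
    ll = 0.0
    for is_yes in (True, False):
        m = yes_r == is_yes
        if not np.any(m):
            continue
        if is_yes:
            vv, ww = -v_r[m], 1.0 - z_rel
        else:
            vv, ww = v_r[m], z_rel
        tt = dt_dec[m]
        f1 = _f1_lower(tt / a**2, ww)
        log_dens = -vv * a * ww - vv**2 * tt / 2.0 - 2.0 * np.log(a) + np.log(
            np.maximum(f1, 1e-300)
        )
        ll += log_dens.sum()
    if np.any(missed):
        params = DDMParams(a=a, z_rel=z_rel, t0=max(t0, 0.0), drift_scale=drift_scale)
        surv = survival_probability(censor - t0, params, v[missed])
        ll += np.sum(np.log(np.maximum(surv, 1e-300)))
    return -ll


def fit_mle(
    rts,
    choices,
    sv,
    censor: float = RESPONSE_WINDOW_S,
    seed=None,
    n_starts: int = 3,
    min_responded: int = 20,
) -> DDMFit:
    """Fit (a, z_rel, t0, drift_scale) by bounded multi-start MLE.

    Parameters
    ----------
    rts : response times in seconds (NaN for missed trials).
    choices : array of "yes"/"no"/"missed".
    sv : trial-wise subjective value driving the drift.
    censor : response window; passage beyond it is censored mass.
    min_responded : below this count the fit is flagged unconverged
        (the four parameters are underdetermined).
    """
    rts = np.asarray(rts, dtype=float)
    choices = np.asarray(choices, dtype=object)
    sv = np.asarray(sv, dtype=float)
    missed = choices == "missed"
    yes = choices == "yes"
    n_resp = int(np.sum(~missed))
    if n_resp == 0:
        raise ValueError("no responded trials: nothing to fit")
    one_boundary = (yes[~missed].all()) or (not yes[~missed].any())
    if one_boundary:
        warnings.warn(
            "all responses at one boundary; starting point estimate will pin near its bound",
            RuntimeWarning,
            stacklevel=2,
        )

    min_rt = float(np.nanmin(rts[~missed]))
    rng = np.random.default_rng(seed)
    bounds = [
        (0.3, 5.0),
        (0.02, 0.98),
        (1e-3, max(min_rt - 1e-3, 2e-3)),
        (-10.0, 10.0),
    ]
    args = (rts, yes, missed, sv, censor)

    starts = [(1.5, 1.0 / 3.0, min(0.3, 0.8 * min_rt), 0.8)]
    for _ in range(n_starts - 1):
        starts.append(
            (
                rng.uniform(0.8, 2.5),
                rng.uniform(0.2, 0.8),
                rng.uniform(0.3, 0.95) * min_rt,
                rng.uniform(-1.5, 1.5),
            )
        )

    best = None
    for x0 in starts:
        res = optimize.minimize(
            _nll_vectorized,
            np.asarray(x0),
            args=args,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res

    a, z_rel, t0, ds = best.x
    params = DDMParams(a=float(a), z_rel=float(z_rel), t0=float(t0), drift_scale=float(ds))
    converged = bool(best.success and np.isfinite(best.fun) and n_resp >= min_responded)
    return DDMFit(
        params=params,
        neg_loglik=float(best.fun),
        converged=converged,
        n_used=n_resp,
        boundary_warning=one_boundary,
    )
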