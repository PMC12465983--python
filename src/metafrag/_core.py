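"""Vectorised numerical kernel.

The scalar pooling API, the greedy fragility search and the exhaustive
flip-set oracle all funnel through these routines so that every path
shares one set of numerics.  Arrays carry one row per candidate dataset
("state") and one column per study.  Non-informative studies (excluded
double-zero tables) are masked with zero weight rather than dropped, so
state batches whose effective study counts differ can be processed
together.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

REML_TOL = 1e-8
REML_MAX_ITER = 100


def effect_arrays(e1, n1, e0, n0, measure, dz_policy="exclude"):
    """Vectorised per-study effects.

    Parameters are broadcastable arrays of shape (..., k).  Returns
    ``(y, v, informative, corrected)`` where ``v`` is the within-study
    variance; masked studies get ``y = 0`` and ``v = 1`` with
    ``informative = False`` (their weight is zeroed downstream).
    """
    e1 = np.asarray(e1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    e0 = np.asarray(e0, dtype=float)
    n0 = np.asarray(n0, dtype=float)

    zero_cell = (e1 == 0) | (e1 == n1) | (e0 == 0) | (e0 == n0)
    add = np.where(zero_cell, 0.5, 0.0)
    a = e1 + add
    b = n1 - e1 + add
    c = e0 + add
    d = n0 - e0 + add
    m1 = a + b
    m0 = c + d

    double_zero = (e1 == 0) & (e0 == 0)
    if measure in ("OR", "RR") and dz_policy == "exclude":
        informative = ~double_zero
    else:
        informative = np.ones_like(double_zero)

    with np.errstate(divide="ignore", invalid="ignore"):
        if measure == "OR":
            y = np.log(a * d) - np.log(b * c)
            v = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
        elif measure == "RR":
            y = np.log(a / m1) - np.log(c / m0)
            v = 1.0 / a - 1.0 / m1 + 1.0 / c - 1.0 / m0
        elif measure == "RD":
            p1 = a / m1
            p0 = c / m0
            y = p1 - p0
            v = p1 * (1.0 - p1) / m1 + p0 * (1.0 - p0) / m0
        else:  # pragma: no cover - guarded by the enum upstream
            raise ValueError(f"unknown measure {measure!r}")

    y = np.where(informative, y, 0.0)
    v = np.where(informative, v, 1.0)
    return y, v, informative, zero_cell & informative


def pool_batch(
    y,
    v,
    informative,
    model="RE",
    tau2_estimator="REML",
    ci_method="hksj",
    alpha=0.05,
    reml_tol=REML_TOL,
    reml_max_iter=REML_MAX_ITER,
):
    """Pool a batch of meta-analyses; all inputs have shape (..., k).

    Returns a dict of arrays of shape (...,): theta, se, ci_low,
    ci_high, p, tau2, Q, I2, df, n, valid, converged, degenerate,
    significant.  ``valid`` is False where fewer than two studies are
    informative; ``converged`` is False where REML failed; both gate
    ``significant``.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    mask = np.asarray(informative, dtype=bool)

    n_inf = mask.sum(axis=-1)
    valid = n_inf >= 2
    df = n_inf - 1

    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(mask, 1.0 / v, 0.0)
        sw = w.sum(axis=-1)
        sw_safe = np.where(sw > 0, sw, np.nan)
        theta_fe = (w * y).sum(axis=-1) / sw_safe
        Q = (w * (y - theta_fe[..., None]) ** 2).sum(axis=-1)
        I2 = np.where(Q > 0, np.clip((Q - df) / np.where(Q > 0, Q, 1.0), 0.0, 1.0), 0.0)

        converged = np.ones(valid.shape, dtype=bool)
        if model == "FE":
            tau2 = np.zeros(valid.shape)
            theta = theta_fe
            wr = w
            swr = sw_safe
        else:
            sw2 = (w**2).sum(axis=-1)
            denom = sw_safe - sw2 / sw_safe
            tau2_dl = np.maximum(0.0, (Q - df) / np.where(denom > 0, denom, np.nan))
            tau2_dl = np.where(np.isfinite(tau2_dl), tau2_dl, 0.0)
            if tau2_estimator == "DL":
                tau2 = tau2_dl
            elif tau2_estimator == "REML":
                tau2, converged = _reml_batch(
                    y, v, mask, tau2_dl, valid, reml_tol, reml_max_iter
                )
            else:  # pragma: no cover
                raise ValueError(f"unknown tau2 estimator {tau2_estimator!r}")
            wr = np.where(mask, 1.0 / (v + tau2[..., None]), 0.0)
            swr = wr.sum(axis=-1)
            swr = np.where(swr > 0, swr, np.nan)
            theta = (wr * y).sum(axis=-1) / swr

        if ci_method == "hksj" and model != "FE":
            qstat = (wr * (y - theta[..., None]) ** 2).sum(axis=-1)
            var = qstat / (np.where(df > 0, df, np.nan) * swr)
            se = np.sqrt(var)
            crit = stats.t.ppf(1.0 - alpha / 2.0, np.where(df > 0, df, np.nan))
            ratio = np.abs(theta) / np.where(se > 0, se, np.nan)
            p = 2.0 * stats.t.sf(ratio, np.where(df > 0, df, np.nan))
            degenerate = valid & (se == 0)
        else:
            se = swr**-0.5
            crit = stats.norm.ppf(1.0 - alpha / 2.0)
            ratio = np.abs(theta) / np.where(se > 0, se, np.nan)
            p = 2.0 * stats.norm.sf(ratio)
            degenerate = np.zeros(valid.shape, dtype=bool)

        p = np.where(se > 0, p, np.where(theta != 0, 0.0, 1.0))
        half = np.where(se > 0, crit * se, 0.0)
        ci_low = theta - half
        ci_high = theta + half
        significant = valid & converged & ((ci_low > 0) | (ci_high < 0))

    return {
        "theta": theta,
        "se": se,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "p": p,
        "tau2": tau2,
        "Q": Q,
        "I2": I2,
        "df": df,
        "n": n_inf,
        "valid": valid,
        "converged": converged,
        "degenerate": degenerate,
        "significant": significant,
    }


def _reml_batch(y, v, mask, tau2_start, valid, tol, max_iter):
    """Fixed-point REML iteration on tau^2, vectorised over states.

    Update: tau2 <- max(0, sum(w^2 ((y-theta)^2 - v)) / sum(w^2) + 1/sum(w))
    with w = 1/(v + tau2).  States are frozen once successive change
    falls below ``tol``; states still active after ``max_iter`` sweeps
    are flagged non-convergent (their last iterate is retained for
    diagnostics but carries no inferential weight).
    """
    tau2 = np.array(tau2_start, dtype=float, copy=True)
    conv = np.zeros(valid.shape, dtype=bool)
    active = valid.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        w = np.where(mask, 1.0 / (v + tau2[..., None]), 0.0)
        sw = w.sum(axis=-1)
        sw = np.where(sw > 0, sw, np.nan)
        theta = (w * y).sum(axis=-1) / sw
        resid2 = np.where(mask, (y - theta[..., None]) ** 2 - v, 0.0)
        num = (w**2 * resid2).sum(axis=-1)
        sw2 = (w**2).sum(axis=-1)
        t_new = np.maximum(0.0, num / np.where(sw2 > 0, sw2, np.nan) + 1.0 / sw)
        delta = np.abs(t_new - tau2)
        tau2 = np.where(active, t_new, tau2)
        newly = active & (delta <= tol)
        conv |= newly
        active &= ~newly
    return tau2, conv | ~valid


def fit_tables(e1, n1, e0, n0, scenario, dz_policy="exclude"):
    """Fit one scenario on a batch of count tables of shape (..., k)."""
    y, v, informative, _ = effect_arrays(e1, n1, e0, n0, scenario.measure.value, dz_policy)
    return pool_batch(
        y,
        v,
        informative,
        model=scenario.model,
        tau2_estimator=scenario.tau2_estimator or "DL",
        ci_method=scenario.ci_method or "normal",
        alpha=scenario.alpha,
    )
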