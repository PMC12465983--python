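"""Fixed- and random-effects pooling of study effects.

The fixed-effect (common-effect) model assumes one true effect shared by
all studies, with inverse-variance weights ``w_i = 1/s_i^2``.  The
random-effects model draws study-specific true effects from
``N(theta, tau^2)`` and weights by ``w*_i = 1/(s_i^2 + tau^2)``.

Between-study variance ``tau^2`` is estimated either by the
DerSimonian-Laird moment estimator (non-iterative) or by REML
(fixed-point iteration, started at the DL value); REML may fail to
converge, which is reported as a state rather than raised.

The 95% interval is either the conventional normal (Wald) interval or
the Hartung-Knapp-Sidik-Jonkman (HKSJ) interval, which replaces the
model-based variance with a weighted empirical variance of the study
effects and uses a t distribution with N-1 degrees of freedom.
Statistical significance means the interval excludes 0 on the analysis
scale (log OR, log RR, or RD).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._core import REML_MAX_ITER, REML_TOL, pool_batch
from .effects import EffectMeasure, StudyEffect
from .errors import TooFewStudiesError


@dataclass(frozen=True)
class ScenarioSpec:
    """One analysis configuration: model, tau^2 estimator, CI method, measure, alpha.

    The five standard configurations are exposed through :meth:`from_key`:
    ``FE`` (fixed effect), ``S1`` (REML + HKSJ), ``S2`` (REML, normal CI),
    ``S3`` (DL + HKSJ), ``S4`` (DL, normal CI).
    """

    model: str  # "FE" or "RE"
    tau2_estimator: Optional[str]  # "DL" or "REML" (RE only)
    ci_method: Optional[str]  # "normal" or "hksj" (RE only)
    measure: EffectMeasure = EffectMeasure.OR
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.model not in ("FE", "RE"):
            raise ValueError(f"model must be 'FE' or 'RE', got {self.model!r}")
        if self.model == "RE":
            if self.tau2_estimator not in ("DL", "REML"):
                raise ValueError(f"tau2_estimator must be 'DL' or 'REML', got {self.tau2_estimator!r}")
            if self.ci_method not in ("normal", "hksj"):
                raise ValueError(f"ci_method must be 'normal' or 'hksj', got {self.ci_method!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        object.__setattr__(self, "measure", EffectMeasure(self.measure))

    @classmethod
    def from_key(
        cls,
        key: str,
        measure: EffectMeasure | str = EffectMeasure.OR,
        alpha: float = 0.05,
    ) -> "ScenarioSpec":
        table = {
            "FE": ("FE", None, None),
            "S1": ("RE", "REML", "hksj"),
            "S2": ("RE", "REML", "normal"),
            "S3": ("RE", "DL", "hksj"),
            "S4": ("RE", "DL", "normal"),
        }
        if key not in table:
            raise ValueError(f"unknown scenario key {key!r}; expected one of {sorted(table)}")
        model, est, ci = table[key]
        return cls(model=model, tau2_estimator=est, ci_method=ci, measure=measure, alpha=alpha)

    @property
    def key(self) -> str:
        if self.model == "FE":
            return "FE"
        return {
            ("REML", "hksj"): "S1",
            ("REML", "normal"): "S2",
            ("DL", "hksj"): "S3",
            ("DL", "normal"): "S4",
        }[(self.tau2_estimator, self.ci_method)]


@dataclass(frozen=True)
class PoolingResult:
    """Pooled effect, interval and heterogeneity summary for one scenario."""

    theta_hat: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    tau2: float
    Q: float
    I2: float
    df: int
    converged: bool
    scenario: ScenarioSpec
    degenerate: bool = False
    n_informative: int = 0

    @property
    def tau(self) -> float:
        return math.sqrt(self.tau2)

    def to_dict(self) -> dict:
        return {
            "theta_hat": self.theta_hat,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "tau2": self.tau2,
            "tau": self.tau,
            "Q": self.Q,
            "I2": self.I2,
            "df": self.df,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "n_informative": self.n_informative,
            "scenario": self.scenario.key,
            "measure": self.scenario.measure.value,
            "alpha": self.scenario.alpha,
        }


def _arrays(effects: Sequence[StudyEffect]) -> tuple[np.ndarray, np.ndarray]:
    informative = [e for e in effects if e.informative]
    if len(informative) < 2:
        raise TooFewStudiesError(
            f"need >= 2 informative studies, got {len(informative)}"
        )
    y = np.array([e.y for e in informative])
    s = np.array([e.s for e in informative])
    return y, s


def pool_fixed(
    effects: Sequence[StudyEffect],
    measure: EffectMeasure | str = EffectMeasure.OR,
    alpha: float = 0.05,
) -> PoolingResult:
    """Inverse-variance fixed-effect pooling with a normal 95% interval."""
    y, s = _arrays(effects)
    scenario = ScenarioSpec(model="FE", tau2_estimator=None, ci_method=None, measure=measure, alpha=alpha)
    out = pool_batch(y[None, :], s[None, :] ** 2, np.ones((1, len(y)), bool), model="FE", alpha=alpha)
    return _result(out, scenario)


def q_statistic(effects: Sequence[StudyEffect]) -> tuple[float, int, float]:
    """Cochran's Q, its degrees of freedom, and the chi-squared p-value.

    ``Q = sum w_i (y_i - theta_FE)^2`` with fixed-effect weights; under
    homogeneity Q ~ chi^2 with N-1 degrees of freedom.
    """
    y, s = _arrays(effects)
    w = 1.0 / s**2
    theta = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - theta) ** 2))
    df = len(y) - 1
    p = float(stats.chi2.sf(Q, df))
    return Q, df, p


def i_squared(Q: float, df: int) -> float:
    """I^2 = max(0, (Q - df)/Q); by convention 0 when Q = 0."""
    if Q < 0:
        raise ValueError(f"Q must be >= 0, got {Q}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if Q == 0:
        return 0.0
    return max(0.0, (Q - df) / Q)


def estimate_tau2_dl(effects: Sequence[StudyEffect]) -> float:
    """DerSimonian-Laird moment estimator, truncated at zero.

    tau^2_DL = max(0, (Q - df) / (sum w - sum w^2 / sum w)) with
    fixed-effect weights w_i = 1/s_i^2.
    """
    y, s = _arrays(effects)
    w = 1.0 / s**2
    sw = np.sum(w)
    theta = float(np.sum(w * y) / sw)
    Q = float(np.sum(w * (y - theta) ** 2))
    df = len(y) - 1
    denom = sw - np.sum(w**2) / sw
    return max(0.0, (Q - df) / float(denom))


def estimate_tau2_reml(
    effects: Sequence[StudyEffect],
    tol: float = REML_TOL,
    max_iter: int = REML_MAX_ITER,
) -> tuple[float, bool]:
    """REML estimate of tau^2 and a convergence flag.

    Fixed-point iteration on the restricted-likelihood score, started at
    the DL estimate, stopping when successive tau^2 iterates change by
    less than ``tol``.  Non-convergence within ``max_iter`` sweeps is
    reported (converged=False), not raised.
    """
    y, s = _arrays(effects)
    v = s**2
    out = pool_batch(
        y[None, :],
        v[None, :],
        np.ones((1, len(y)), bool),
        model="RE",
        tau2_estimator="REML",
        reml_tol=tol,
        reml_max_iter=max_iter,
    )
    return float(out["tau2"][0]), bool(out["converged"][0])


def pool_random(
    effects: Sequence[StudyEffect],
    tau2: float,
    ci_method: str = "normal",
    measure: EffectMeasure | str = EffectMeasure.OR,
    alpha: float = 0.05,
    tau2_estimator: str = "DL",
) -> PoolingResult:
    """Random-effects pooling at a given tau^2.

    Weights ``w*_i = 1/(s_i^2 + tau^2)``.  With ``ci_method='normal'``
    the standard error is ``(sum w*)^(-1/2)`` and the interval is a
    z-interval; with ``'hksj'`` the variance is the weighted empirical
    variance ``sum w* (y - theta)^2 / ((N-1) sum w*)`` and the interval
    and p-value use the t distribution with N-1 degrees of freedom.
    An HKSJ variance of exactly zero (all effects equal) is flagged
    ``degenerate``; the interval collapses to the point estimate.
    """
    if tau2 < 0:
        raise ValueError(f"tau2 must be >= 0, got {tau2}")
    y, s = _arrays(effects)
    scenario = ScenarioSpec(
        model="RE", tau2_estimator=tau2_estimator, ci_method=ci_method, measure=measure, alpha=alpha
    )
    v = s**2
    mask = np.ones((1, len(y)), bool)
    # reuse the batch kernel's CI machinery at fixed tau2 via a direct computation
    w = 1.0 / (v + tau2)
    sw = float(np.sum(w))
    theta = float(np.sum(w * y) / sw)
    n = len(y)
    df = n - 1
    # heterogeneity diagnostics from FE weights
    w_fe = 1.0 / v
    theta_fe = float(np.sum(w_fe * y) / np.sum(w_fe))
    Q = float(np.sum(w_fe * (y - theta_fe) ** 2))
    I2 = i_squared(Q, df)
    degenerate = False
    if ci_method == "hksj":
        var = float(np.sum(w * (y - theta) ** 2) / (df * sw))
        se = math.sqrt(var)
        if se > 0:
            crit = float(stats.t.ppf(1 - alpha / 2, df))
            p = float(2 * stats.t.sf(abs(theta) / se, df))
        else:
            degenerate = True
            crit = 0.0
            p = 0.0 if theta != 0 else 1.0
    elif ci_method == "normal":
        se = sw**-0.5
        crit = float(stats.norm.ppf(1 - alpha / 2))
        p = float(2 * stats.norm.sf(abs(theta) / se))
    else:
        raise ValueError(f"ci_method must be 'normal' or 'hksj', got {ci_method!r}")
    half = crit * se if se > 0 else 0.0
    return PoolingResult(
        theta_hat=theta,
        se=se,
        ci_low=theta - half,
        ci_high=theta + half,
        p_value=p,
        tau2=float(tau2),
        Q=Q,
        I2=I2,
        df=df,
        converged=True,
        scenario=scenario,
        degenerate=degenerate,
        n_informative=n,
    )


def _result(out: dict, scenario: ScenarioSpec) -> PoolingResult:
    return PoolingResult(
        theta_hat=float(out["theta"][0]),
        se=float(out["se"][0]),
        ci_low=float(out["ci_low"][0]),
        ci_high=float(out["ci_high"][0]),
        p_value=float(out["p"][0]),
        tau2=float(out["tau2"][0]),
        Q=float(out["Q"][0]),
        I2=float(out["I2"][0]),
        df=int(out["df"][0]),
        converged=bool(out["converged"][0]),
        scenario=scenario,
        degenerate=bool(out["degenerate"][0]),
        n_informative=int(out["n"][0]),
    )


def pool(
    effects: Sequence[StudyEffect],
    scenario: ScenarioSpec,
) -> PoolingResult:
    """Pool pre-computed study effects under a full scenario specification."""
    y, s = _arrays(effects)
    out = pool_batch(
        y[None, :],
        s[None, :] ** 2,
        np.ones((1, len(y)), bool),
        model=scenario.model,
        tau2_estimator=scenario.tau2_estimator or "DL",
        ci_method=scenario.ci_method or "normal",
        alpha=scenario.alpha,
    )
    return _result(out, scenario)
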