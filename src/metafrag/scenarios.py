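"""Multi-scenario analysis, subgroup binning and corpus summaries.

Five analysis configurations are compared: the fixed-effect model and
four random-effects scenarios crossing the tau^2 estimator (REML or DL)
with the interval method (HKSJ or normal): S1 = REML+HKSJ, S2 = REML
normal, S3 = DL+HKSJ, S4 = DL normal.  Corpus summaries follow the
convention of restricting fragility distributions to meta-analyses that
are statistically significant under the scenario at hand.

Binning conventions are half-open [a, b) throughout, so a total sample
size of exactly 50 falls in "50-100" and 1000 in ">=1000".  The I^2
interpretive bands deliberately overlap (Cochrane Handbook style); a
separate non-overlapping stratification is used where each
meta-analysis must map to exactly one stratum.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .errors import NonConvergentScenarioError, TooFewStudiesError
from .fragility import FragilityResult, fragility_index_ma, fragility_index_ma_exact
from .improvement import ma_improvement
from .io import MetaAnalysisDataset
from .pooling import PoolingResult, ScenarioSpec, _result
from ._core import fit_tables

SCENARIO_KEYS = ("FE", "S1", "S2", "S3", "S4")

SAMPLE_SIZE_EDGES = (50, 100, 200, 500, 1000)
SAMPLE_SIZE_LABELS = ("<50", "50-100", "100-200", "200-500", "500-1000", ">=1000")
EVENT_EDGES = (10, 50, 100, 500, 1000)
EVENT_LABELS = ("<10", "10-50", "50-100", "100-500", "500-1000", ">=1000")

#: Overlapping interpretive I^2 bands (closed intervals).
I2_BANDS = (
    ("not_important", 0.0, 0.4),
    ("moderate", 0.3, 0.6),
    ("substantial", 0.5, 0.9),
    ("considerable", 0.75, 1.0),
)

#: Non-overlapping strata for analyses needing a unique assignment.
I2_STRATA = (
    ("<0.4", 0.0, 0.4),
    ("0.4-0.6", 0.4, 0.6),
    ("0.6-0.75", 0.6, 0.75),
    (">=0.75", 0.75, 1.0 + 1e-12),
)

OR_MAGNITUDE_CUTS = (1.68, 3.47, 6.71)
RR_MAGNITUDE_CUTS = (1.22, 1.86, 3.00)
MAGNITUDE_LABELS = ("small", "moderate", "median", "large")


def _bin(value: float, edges: Sequence[float], labels: Sequence[str]) -> str:
    for edge, label in zip(edges, labels):
        if value < edge:
            return label
    return labels[-1]


def bin_sample_size(total_n: int) -> str:
    """Total-sample-size bin, half-open: 50 -> '50-100', 1000 -> '>=1000'."""
    if total_n <= 0:
        raise ValueError(f"total_n must be positive, got {total_n}")
    return _bin(total_n, SAMPLE_SIZE_EDGES, SAMPLE_SIZE_LABELS)


def bin_events(total_events: int) -> str:
    """Total-event-count bin, half-open boundaries."""
    if total_events < 0:
        raise ValueError(f"total_events must be >= 0, got {total_events}")
    return _bin(total_events, EVENT_EDGES, EVENT_LABELS)


def i2_bands(i2: float) -> Tuple[str, ...]:
    """All overlapping interpretive bands containing this I^2 (closed ranges)."""
    if not (0.0 <= i2 <= 1.0):
        raise ValueError(f"I2 must be in [0, 1], got {i2}")
    return tuple(name for name, lo, hi in I2_BANDS if lo <= i2 <= hi)


def i2_stratum(i2: float) -> str:
    """Unique non-overlapping stratum: [0,0.4), [0.4,0.6), [0.6,0.75), [0.75,1]."""
    if not (0.0 <= i2 <= 1.0):
        raise ValueError(f"I2 must be in [0, 1], got {i2}")
    for name, lo, hi in I2_STRATA:
        if lo <= i2 < hi:
            return name
    return I2_STRATA[-1][0]


def _magnitude(value: float, cuts: Sequence[float]) -> str:
    if value <= 0:
        raise ValueError(f"ratio must be positive, got {value}")
    if value < 1.0:
        value = 1.0 / value
    return _bin(value, cuts, MAGNITUDE_LABELS)


def categorize_or_magnitude(or_value: float) -> str:
    """OR magnitude band after inverting values < 1; half-open at the cutoffs."""
    return _magnitude(or_value, OR_MAGNITUDE_CUTS)


def categorize_rr_magnitude(rr_value: float) -> str:
    """RR magnitude band after inverting values < 1; RR = 3.00 is 'large'."""
    return _magnitude(rr_value, RR_MAGNITUDE_CUTS)



def _bool_col(df: pd.DataFrame, name: str) -> pd.Series:
    """Boolean mask from a possibly missing / NaN-laden column."""
    if name not in df.columns:
        return pd.Series(False, index=df.index)
    return df[name] == True  # noqa: E712 - NaN-safe elementwise comparison

@dataclass(frozen=True)
class ScenarioOutcome:
    pooling: Optional[PoolingResult]
    fragility: Optional[FragilityResult]
    excluded: bool = False
    reason: str = ""


def run_scenarios(
    dataset: MetaAnalysisDataset,
    measure: str = "OR",
    alpha: float = 0.05,
    cap: int | None = None,
    scenario_keys: Sequence[str] = SCENARIO_KEYS,
    compute_fi: bool = True,
    exact: bool = False,
    dz_policy: str = "exclude",
) -> Dict[str, ScenarioOutcome]:
    """Fit all requested scenarios on one dataset.

    REML non-convergence flags the REML scenarios as excluded (the
    pooled result is still returned with ``converged=False``); DL and
    FE results are unaffected.  Too few informative studies excludes
    every scenario.
    """
    search = fragility_index_ma_exact if exact else fragility_index_ma
    out: Dict[str, ScenarioOutcome] = {}
    for key in scenario_keys:
        spec = ScenarioSpec.from_key(key, measure=measure, alpha=alpha)
        e1, n1, e0, n0 = dataset.count_arrays()
        fit = fit_tables(e1[None, :], n1[None, :], e0[None, :], n0[None, :], spec, dz_policy)
        if not bool(fit["valid"][0]):
            out[key] = ScenarioOutcome(None, None, excluded=True, reason="too_few_studies")
            continue
        pooled = _result(fit, spec)
        if not pooled.converged:
            out[key] = ScenarioOutcome(pooled, None, excluded=True, reason="reml_nonconvergence")
            continue
        frag = None
        if compute_fi:
            frag = search(dataset, spec, cap=cap, dz_policy=dz_policy)
        out[key] = ScenarioOutcome(pooled, frag)
    return out


def analyze_corpus(
    corpus: Sequence[MetaAnalysisDataset],
    measures: Sequence[str] = ("OR",),
    alpha: float = 0.05,
    cap: int | None = None,
    scenario_keys: Sequence[str] = SCENARIO_KEYS,
    compute_fi: bool = True,
    fi_significant_only: bool = True,
    dz_policy: str = "exclude",
) -> pd.DataFrame:
    """Run scenarios across a corpus; one row per (MA, measure, scenario).

    With ``fi_significant_only`` (the default) the costly fragility
    search is run only for meta-analyses whose pooled result is
    significant under the scenario at hand, mirroring the focus of
    fragility reporting on significant findings.
    """
    rows: List[dict] = []
    for ds in corpus:
        for measure in measures:
            try:
                res = run_scenarios(
                    ds, measure=measure, alpha=alpha, cap=cap,
                    scenario_keys=scenario_keys, compute_fi=False, dz_policy=dz_policy,
                )
            except (TooFewStudiesError, NonConvergentScenarioError):
                continue
            for key, outcome in res.items():
                row = {
                    "ma_id": ds.ma_id,
                    "measure": measure,
                    "scenario": key,
                    "n_studies": len(ds),
                    "total_n": ds.total_n,
                    "total_events": ds.total_events,
                    "excluded": outcome.excluded,
                    "reason": outcome.reason,
                }
                if outcome.pooling is not None:
                    p = outcome.pooling
                    significant = (p.ci_low > 0 or p.ci_high < 0) and p.converged
                    row.update(
                        theta=p.theta_hat, se=p.se, ci_low=p.ci_low, ci_high=p.ci_high,
                        ci_length=p.ci_high - p.ci_low, p_value=p.p_value, tau2=p.tau2,
                        Q=p.Q, I2=p.I2, df=p.df, converged=p.converged,
                        significant=significant,
                    )
                    if compute_fi and not outcome.excluded and (
                        significant or not fi_significant_only
                    ):
                        spec = ScenarioSpec.from_key(key, measure=measure, alpha=alpha)
                        frag = fragility_index_ma(ds, spec, cap=cap, dz_policy=dz_policy)
                        row.update(fi=frag.fi, fq=frag.fq, fi_attainable=frag.attainable)
                rows.append(row)
    return pd.DataFrame(rows)


def paired_differences(
    results: pd.DataFrame,
    key_a: str,
    key_b: str,
    measure: str = "OR",
) -> dict:
    """Per-MA FI and CI-length differences between two scenarios (a minus b).

    Restricted to meta-analyses significant under both scenarios with
    attainable FIs in both; the number excluded is reported.
    """
    sub = results[results["measure"] == measure]
    a = sub[sub["scenario"] == key_a].set_index("ma_id")
    b = sub[sub["scenario"] == key_b].set_index("ma_id")
    common = a.index.intersection(b.index)
    a = a.loc[common]
    b = b.loc[common]
    ok = (
        _bool_col(a, "significant")
        & _bool_col(b, "significant")
        & _bool_col(a, "fi_attainable")
        & _bool_col(b, "fi_attainable")
    )
    fi_diff = (a.loc[ok, "fi"] - b.loc[ok, "fi"]).astype(float)
    ci_diff = (a.loc[ok, "ci_length"] - b.loc[ok, "ci_length"]).astype(float)
    return {
        "ma_ids": list(fi_diff.index),
        "fi_diff": fi_diff.to_list(),
        "ci_length_diff": ci_diff.to_list(),
        "n": int(ok.sum()),
        "n_excluded": int(len(common) - ok.sum()),
    }


def summarize_corpus(
    results: pd.DataFrame,
    improvement: Optional[pd.DataFrame] = None,
) -> dict:
    """Corpus-level summary per (measure, scenario).

    Fragility distributions are computed on the significant subset with
    attainable FIs: median/IQR of FI and FQ, proportions with FI = 1,
    FI <= 5, FI >= 22, FQ < 0.01, FQ < 0.05, and median FI within
    sample-size and event bins.  If a per-MA improvement table (columns
    ma_id, measure, scenario, proportion, category, I2) is supplied,
    category proportions by I^2 stratum are included.
    """
    if results.empty:
        raise ValueError("empty corpus results")
    summary: dict = {}
    for (measure, key), grp in results.groupby(["measure", "scenario"], sort=True):
        entry: dict = {
            "n_mas": int(grp["ma_id"].nunique()),
            "n_excluded": int(grp["excluded"].sum()),
            "n_significant": int(_bool_col(grp, "significant").sum()),
        }
        sig = grp[_bool_col(grp, "significant")]
        att = sig[_bool_col(sig, "fi_attainable")]
        entry["n_fi_attainable"] = int(len(att))
        entry["n_fi_not_attainable"] = int(len(sig) - len(att)) if "fi" in sig.columns else 0
        if len(att):
            fi = att["fi"].astype(float)
            fq = att["fq"].astype(float)
            entry.update(
                fi_median=float(fi.median()),
                fi_iqr=[float(fi.quantile(0.25)), float(fi.quantile(0.75))],
                fq_median=float(fq.median()),
                fq_iqr=[float(fq.quantile(0.25)), float(fq.quantile(0.75))],
                prop_fi_1=float((fi == 1).mean()),
                prop_fi_le5=float((fi <= 5).mean()),
                prop_fi_ge22=float((fi >= 22).mean()),
                prop_fq_lt_0_01=float((fq < 0.01).mean()),
                prop_fq_lt_0_05=float((fq < 0.05).mean()),
            )
            by_size: dict = {}
            for label, sub in att.groupby(att["total_n"].map(bin_sample_size)):
                by_size[label] = {
                    "n": int(len(sub)),
                    "fi_median": float(sub["fi"].median()),
                    "prop_fi_1": float((sub["fi"] == 1).mean()),
                    "prop_fi_le5": float((sub["fi"] <= 5).mean()),
                }
            entry["fi_by_sample_size"] = by_size
            by_events: dict = {}
            for label, sub in att.groupby(att["total_events"].map(bin_events)):
                by_events[label] = {
                    "n": int(len(sub)),
                    "fi_median": float(sub["fi"].median()),
                }
            entry["fi_by_events"] = by_events
        if improvement is not None and not improvement.empty:
            imp = improvement[
                (improvement["measure"] == measure) & (improvement["scenario"] == key)
            ]
            if len(imp):
                strata: dict = {}
                for label, sub in imp.groupby(imp["I2"].map(i2_stratum)):
                    counts = sub["category"].value_counts(normalize=True)
                    strata[label] = {
                        "n": int(len(sub)),
                        "category_proportions": {c: float(counts.get(c, 0.0)) for c in
                                                 ("no", "slight", "considerable", "complete")},
                    }
                entry["improvement_by_i2"] = strata
        summary.setdefault(measure, {})[key] = entry
    return summary


def corpus_improvement(
    corpus: Sequence[MetaAnalysisDataset],
    results: pd.DataFrame,
    measure: str = "OR",
    scenario_key: str = "S1",
    alpha: float = 0.05,
    study_cap: int = 20,
    dz_policy: str = "exclude",
) -> pd.DataFrame:
    """Improvement analysis for every significant MA with an attainable FI."""
    by_id = {ds.ma_id: ds for ds in corpus}
    sub = results[
        (results["measure"] == measure)
        & (results["scenario"] == scenario_key)
        & _bool_col(results, "significant")
        & _bool_col(results, "fi_attainable")
    ]
    spec = ScenarioSpec.from_key(scenario_key, measure=measure, alpha=alpha)
    rows = []
    for _, row in sub.iterrows():
        ds = by_id[row["ma_id"]]
        imp = ma_improvement(
            ds, spec, ma_fi=int(row["fi"]), study_cap=study_cap, dz_policy=dz_policy
        )
        rows.append({
            "ma_id": ds.ma_id,
            "measure": measure,
            "scenario": scenario_key,
            "I2": float(row["I2"]),
            "proportion": imp.proportion,
            "category": imp.category,
            "ma_fi": imp.ma_fi,
            "n_not_attainable": imp.n_not_attainable,
        })
    return pd.DataFrame(rows)
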