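"""Seeded generator of Cochrane-like corpora of binary-outcome meta-analyses.

The generative model mirrors the standard random-effects data model.
For meta-analysis ``m`` with true mean effect ``theta_m`` (log odds
ratio scale):

* number of studies ``k ~ 2 + NegBin(r, p)`` (support starts at 2),
* per study, a common arm size drawn log-normally (balanced arms),
* control risk ``p0 ~ Beta(a, b)``,
* study-specific true effect ``theta_i ~ N(theta_m, tau^2)``,
* treatment risk from inverting the log OR at ``p0``,
* event counts drawn binomially in each arm.

Across the corpus, ``theta_m ~ N(theta, theta_sd^2)`` so that a
realistic fraction of meta-analyses is genuinely non-null.  True
effects are always generated on the log-OR scale; RR and RD analyses
run on the same count tables.

Default parameters are calibrated to the published profile of large
Cochrane corpora of binary-outcome meta-analyses: about 4 studies per
meta-analysis (IQR roughly 3-8), a median total sample size around 700
(IQR roughly 300-1900), a median of about 130 total events, and roughly
29% of meta-analyses significant under REML + HKSJ pooling of odds
ratios.  Everything is a function of ``(seed, index)``, so corpora are
bit-reproducible.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Tuple

import numpy as np

from .effects import TwoByTwoTable
from .io import MetaAnalysisDataset, write_corpus


@dataclass(frozen=True)
class SyntheticConfig:
    """Corpus-level generative parameters; the seed fully determines output."""

    n_mas: int = 100
    seed: int = 0
    # studies per MA: k = 2 + NegBin(k_nb_r, k_nb_p)
    k_nb_r: float = 0.8
    k_nb_p: float = 0.16
    # balanced per-arm size: round(LogNormal(mu, sigma)), clipped below at 5
    arm_lognorm_mu: float = 4.0
    arm_lognorm_sigma: float = 1.1
    # control risk: Beta(a, b)
    p0_beta_a: float = 1.6
    p0_beta_b: float = 7.5
    # effects on the log-OR scale
    theta: float = 0.0  # corpus mean effect
    theta_sd: float = 0.5  # between-MA spread of true mean effects
    tau2: float = 0.05  # within-MA between-study variance

    def __post_init__(self) -> None:
        if self.n_mas < 0:
            raise ValueError(f"n_mas must be >= 0, got {self.n_mas}")
        if not (0 < self.k_nb_p < 1):
            raise ValueError(f"k_nb_p must be in (0, 1), got {self.k_nb_p}")
        for name in ("k_nb_r", "arm_lognorm_sigma", "p0_beta_a", "p0_beta_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau2 < 0 or self.theta_sd < 0:
            raise ValueError("tau2 and theta_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_ma(config: SyntheticConfig, index: int) -> MetaAnalysisDataset:
    """Generate meta-analysis ``index`` of the corpus, deterministically.

    The RNG stream is seeded by ``(seed, index)``, so any single
    meta-analysis can be regenerated without materialising the corpus.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, index]))
    k = 2 + int(rng.negative_binomial(config.k_nb_r, config.k_nb_p))
    theta_ma = config.theta + config.theta_sd * rng.standard_normal()
    arm = np.maximum(
        5, np.round(rng.lognormal(config.arm_lognorm_mu, config.arm_lognorm_sigma, size=k))
    ).astype(int)
    p0 = np.clip(rng.beta(config.p0_beta_a, config.p0_beta_b, size=k), 1e-4, 1 - 1e-4)
    theta_i = theta_ma + np.sqrt(config.tau2) * rng.standard_normal(k)
    logit_p0 = np.log(p0) - np.log1p(-p0)
    p1 = _expit(logit_p0 + theta_i)
    e1 = rng.binomial(arm, p1)
    e0 = rng.binomial(arm, p0)
    studies = tuple(
        (f"s{j + 1}", TwoByTwoTable(e1=int(e1[j]), n1=int(arm[j]), e0=int(e0[j]), n0=int(arm[j])))
        for j in range(k)
    )
    return MetaAnalysisDataset(ma_id=f"ma{index + 1:05d}", studies=studies)


def generate_corpus(config: SyntheticConfig) -> Tuple[List[MetaAnalysisDataset], dict]:
    """Generate the full corpus and a manifest describing it.

    The manifest records the config, its SHA-256 hash, and corpus
    totals; an empty corpus (n_mas = 0) still yields a valid manifest.
    """
    corpus = [generate_ma(config, i) for i in range(config.n_mas)]
    cfg = config.to_dict()
    digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    manifest = {
        "config": cfg,
        "config_sha256": digest,
        "n_mas": len(corpus),
        "n_studies": sum(len(ds) for ds in corpus),
        "total_n": sum(ds.total_n for ds in corpus),
        "total_events": sum(ds.total_events for ds in corpus),
        "schema": "ma_id,study_id,e1,n1,e0,n0",
    }
    return corpus, manifest


def write_corpus_with_manifest(
    corpus: List[MetaAnalysisDataset], manifest: dict, out_dir: str | Path
) -> Tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus_path = out_dir / "corpus.csv"
    manifest_path = out_dir / "manifest.json"
    write_corpus(corpus, corpus_path)
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return corpus_path, manifest_path


def simulate_normal_effects(
    n_mas: int,
    k: int,
    theta: float,
    tau2: float,
    rng: np.random.Generator,
    s_low: float = 0.1,
    s_high: float = 0.3,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw study effects from the normal-normal model with known SEs.

    Returns ``(y, s)`` of shape (n_mas, k) with
    ``y_ij ~ N(theta_ij, s_ij^2)``, study-specific true effects
    ``theta_ij ~ N(theta, tau2)`` and ``s_ij ~ U(s_low, s_high)``.
    Used for estimator calibration studies where the within-study
    variances are treated as known.
    """
    s = rng.uniform(s_low, s_high, size=(n_mas, k))
    u = rng.normal(0.0, np.sqrt(tau2), size=(n_mas, k))
    y = theta + u + s * rng.standard_normal((n_mas, k))
    return y, s
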