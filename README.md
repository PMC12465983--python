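# metafrag

Fragility analysis of binary-outcome meta-analyses: how many
single-patient event-status changes would it take to overturn the
statistical significance of a pooled treatment effect?

Evidence-synthesis methodologists and meta-epidemiologists use the
**fragility index (FI)** as a supplement to p-values: for a
meta-analysis (MA) of N two-arm trials with binary outcomes, the FI is
the minimum number of event flips — a patient's outcome changed from
event to non-event or vice versa, anywhere across the included trials —
that moves the pooled 95% confidence interval across the null. The
**fragility quotient (FQ)** is FI divided by the total sample size.
Because the verdict depends on how the pooling is done, `metafrag`
computes both quantities under five standard configurations: the
fixed-effect model, and the random-effects model with τ² estimated by
REML or DerSimonian–Laird, each with or without the
Hartung–Knapp–Sidik–Jonkman (HKSJ) interval adjustment.

## The model

Each study i contributes an estimated effect y_i (log OR, log RR, or
RD) with standard error s_i, computed from its 2×2 table with a 0.5
continuity correction whenever the table contains a zero cell. The
random-effects model assumes

    y_i ~ N(θ_i, s_i²),   θ_i ~ N(θ, τ²),

pooled with inverse-variance weights w*_i = 1/(s_i² + τ̂²). Cochran's
Q, I² = max(0, (Q − df)/Q), and τ̂² (DL moment estimator, or REML by
fixed-point iteration) quantify heterogeneity. The HKSJ interval
replaces the model-based variance with the weighted empirical variance
Σw*_i(y_i − θ̂)² / ((N−1)Σw*_i) and uses t(N−1) quantiles.

The FI search is a deterministic beam search over single-flip
modifications: every candidate flip is evaluated by re-fitting the full
scenario from scratch (corrections re-resolved, τ² re-estimated), and
an exhaustive breadth-first oracle (`fragility_index_ma_exact`)
certifies minimality on small instances.

## Worked example

```python
import metafrag as mf

ds = mf.MetaAnalysisDataset("example", (
    ("trial-1", mf.TwoByTwoTable(e1=12, n1=20, e0=4, n0=20)),
    ("trial-2", mf.TwoByTwoTable(e1=11, n1=20, e0=5, n0=20)),
))
spec = mf.ScenarioSpec.from_key("FE", measure="OR")   # fixed effect, log OR
res = mf.fragility_index_ma(ds, spec)
print(res.fi, round(res.fq, 4), res.direction, round(res.p_initial, 4))
```

prints

```
5 0.0625 toward_null 0.002
```

The pooled log OR is significant (p = 0.002), and five event flips —
6.25% of the 80 patients — are enough to make the 95% interval cross
the null; `res.plan` lists the exact flips and `res.trail` the p-value
after each one. Under REML + HKSJ (`ScenarioSpec.from_key("S1")`) the
same data are *not* significant to begin with (the t(1)-based HKSJ
interval is wide for two studies), and the search reports the flips
needed to reach significance instead.

Command-line equivalents:

```sh
metafrag simulate --seed 7 --n-mas 100 --out corpus/
metafrag fi corpus/corpus.csv --scenario S1 --measure OR
metafrag scenarios corpus/corpus.csv --measures OR,RR --out results/
metafrag summarize results/
```

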