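# hdmediation

Confounder-adjusted high-dimensional mediation analysis for observational
studies, with overlap weighting as the recommended propensity-score
adjustment.

## The problem

In an observational epigenetic study, a binary exposure X (say, smoking)
may affect a continuous outcome Y (say, an estimated immune-cell level)
partly through a small number of mediators hidden among p >> n candidates
M₁,…,M_p (CpG methylation levels), while baseline confounders C distort
every path.  The working models are

    M_k = a_k + α_k X + φ_kᵀ C + e_k          (exposure → mediator)
    Y   = a + γ X + βᵀ M + ηᵀ C + ε           (mediator → outcome)

and mediator k carries the indirect effect α_k β_k.  Testing
H₀: α_k β_k = 0 for thousands of k at once raises three linked problems:
dimensionality (p >> n), confounding (C is never randomized), and the
composite null (α_k β_k = 0 holds when either factor is zero, making the
max-P statistic non-uniform under the null).

`hdmediation` implements two complete workflows over four
confounding-adjustment schemes:

* **Adjustments** — regression adjustment (`ra`), propensity-score
  regression (`psr`), inverse probability weighting (`ipw`), and overlap
  weighting (`ow`, w = 1−π for exposed and π for unexposed, bounded and
  exactly balancing at the logistic MLE).
* **`mhima2`** (recommended) — confounding-controlled sure independence
  screening down to d = ⌊2n/log n⌋ candidates ranked by the adjusted
  |β̂_k|, de-biased Lasso inference on all screened candidates, and a
  joint-significance test calibrated on the three-component mixture null
  (pointwise FDR with plug-in null proportions).
* **`hima`** — the classic two-stage route: the same screen, MCP-penalized
  selection, then max-P testing with Benjamini–Hochberg correction against
  the full mediator universe.

A fully parameterized synthetic-data generator reproduces the benchmark
study conditions (8 confounders, logistic exposure, sparse α/β with
indirect effects 0.16–0.30, AR(1) mediator-error correlation), so every
stage is testable without external data.

## Worked example

```python
from hdmediation import SimulationConfig, WorkflowConfig, run_workflow, simulate_dataset

ds = simulate_dataset(SimulationConfig(n=500, p=1000), seed=42)
report = run_workflow(ds, WorkflowConfig(test_method="mhima2", adjustment="ow", seed=1))
print(report.significant[["mediator_id", "alpha_hat", "beta_hat",
                          "alpha_beta", "percent_TE", "p_adjusted"]])
```

prints (mediators M1–M4 are the true ones, with α·β = 0.16, 0.20, 0.25, 0.30):

```
  mediator_id  alpha_hat  beta_hat  alpha_beta  percent_TE    p_adjusted
0          M1   0.398202  0.442976    0.176394   10.036696  8.371662e-04
1          M2   0.490682  0.513626    0.252027   14.340145  2.491707e-04
2          M3   0.525177  0.425048    0.223226   12.701393  2.752260e-06
3          M4   0.692744  0.538086    0.372756   21.209550  2.240568e-08
```

`alpha_beta` is each mediator's estimated indirect effect, `percent_TE`
its share of the total exposure effect (direct effect γ̂ plus all
significant indirect effects), and `p_adjusted` the estimated pointwise
FDR of its max-P statistic.  The same dataset analysed with
`test_method="hima"` yields the more conservative BH-based calls.

Short narrative scripts for each capability live in `examples/`; a thin
CLI (`hdmediation simulate | run | benchmark`) covers shell use, e.g.

```bash
hdmediation run --pheno pheno.tsv --mediators methylation.tsv \
    --exposure smoking --outcome nk_level --confounders age,sex,cd4 \
    --adjust ow --test mhima2 --out report.tsv
```

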