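# megade — cross-study differential-expression mega-analysis

`megade` pools per-gene differential-expression effect sizes across many
independently profiled case/control expression studies — the setting where a
gene's signal is too weak or too inconsistent to trust in any single cohort,
but a dozen public datasets together can resolve it.  It is a mega-analysis
in the strict sense: effect sizes are computed from the raw per-study
matrices, not harvested from publications.

It is aimed at researchers combining public case/control transcriptomics
series (e.g. GEO) for a disease of interest, and at anyone who wants the
pooling, heterogeneity and screening machinery exercisable end-to-end on
synthetic data with known ground truth.

## The model

For each study *i* and gene *g*, the effect size is the log2 fold change
(LFC): the difference of mean log2 expression, case minus control, with the
Welch sampling variance

```
y_i = mean(case) - mean(control),     v_i = s²_case/n_case + s²_control/n_control .
```

Per gene, the studies are combined under both standard models:

* **fixed effect** — inverse-variance weights `w_i = 1/v_i`,
  `est = Σ w_i y_i / Σ w_i`, `se = √(1/Σ w_i)`;
* **random effects** — between-study variance τ² estimated by the
  DerSimonian–Laird method of moments from Cochran's
  `Q = Σ w_i (y_i − est_FE)²`,

  ```
  τ² = max(0, (Q − df) / (Σ w_i − Σ w_i² / Σ w_i)),   df = k − 1,
  ```

  then the same weighted mean with `w*_i = 1/(v_i + τ²)`.

Heterogeneity is reported as `Q`, its chi-square p-value `p_Q`, and
`I² = max(0, 100·(Q − df)/Q)`.  The random-effects estimate is selected when
heterogeneity is significant (`p_Q < 0.05`), the fixed-effect estimate
otherwise; inference is a two-sided Wald z-test with a normal 95% CI.

Genes are then screened on three criteria: measured in at least half of the
studies, pooled `p < 0.05`, and pooled LFC `> 0.59` or `< −1.00` (roughly a
50% expression increase or decrease on the fold scale).  Study-level
moderators (total sample size, region, study year) can be regressed against
a gene's per-study effects, and gene lists can be tested for overlap
(one-sided Fisher/hypergeometric) and GMT gene-set enrichment with
Benjamini–Hochberg FDR control.

## Worked example

```python
from megade import (SimulationConfig, generate_studies, normalize_log2,
                    collect_effects, pool_effects, screen_genes)

# 14 studies with arm sizes mirroring a published autism mega-analysis
# design; 10% of 500 genes carry a true log2 effect of 1.2 with
# between-study variance 0.1
cfg = SimulationConfig(n_genes=500, frac_null=0.9, mu=1.2, tau2=0.1, seed=42)
studies, truth = generate_studies(cfg)

effects = collect_effects([normalize_log2(s) for s in studies])
meta = pool_effects(effects)
screened = screen_genes(meta, n_studies_total=len(studies))

hits = screened[screened.passed]
print(len(hits), "genes pass the screen")
print(hits[["gene", "k", "est", "p", "I2", "model_used"]].head(3).to_string(index=False))
```

prints

```
54 genes pass the screen
  gene  k      est            p        I2 model_used
G00011 11 1.126815 9.641972e-18 68.825912     random
G00012 11 1.077790 3.013975e-14 72.841485     random
G00025 11 0.742932 3.145238e-30 42.340364      fixed
```

Each hit was measured in `k` of the 14 studies (platform dropout removed it
from the rest); `est` is the pooled LFC of the selected model, `I2` the
percentage of variability attributed to between-study heterogeneity (genes
with large `I2` switch to the random-effects model).  In this run the
generator planted 54 non-null genes, and the screen recovers exactly those
54 with no false positives.

The same run is available from the shell:

```
megade simulate --seed 42 --out sim/          # matrices + ground truth
megade run --config run.yaml                  # full pipeline with manifest
megade overlap --list-a pe.txt --list-b asd.txt --background 20000
```

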