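# Methods

## Setting and model

`megade` addresses the cross-study ("mega-analysis") setting: K independent
case/control expression studies, each a gene × sample matrix on the log2
scale, pooled per gene into a single effect estimate with heterogeneity
diagnostics.  The canonical design it mirrors is a published pooling of 14
autism case/control GEO series (arm sizes from 2 to 233 samples, four
countries, publication years 2007–2017); that design ships as the bundled
registry and drives the synthetic generator's defaults.

Per study the effect size is the log2 fold change (LFC), the difference of
mean log2 expression between arms, with the Welch variance
`s²_case/n_case + s²_control/n_control` computed from non-missing samples
(n−1 denominators).  The Welch form is the standard sampling variance for a
difference of means and is what inverse-variance pooling expects.  A record
is emitted only when both arms retain at least two non-missing samples.

Pooling per gene follows the classical two-model scheme: fixed effect with
weights `1/v_i`; Cochran's Q with `df = k − 1` and
`I² = max(0, 100(Q − df)/Q)`; DerSimonian–Laird (DL) τ² truncated at zero;
random effects with weights `1/(v_i + τ²)`.  The random-effects model is
reported when the heterogeneity test is significant at `q_alpha = 0.05`,
otherwise the fixed-effect model.  Gene-level inference is a Wald z-test on
the selected estimate with a 1.96 normal CI, consistent with the z-based
test (no t correction, no Hartung–Knapp adjustment in v1).  DL was chosen
as the canonical method-of-moments estimator for this two-model framework;
an iterative REML estimator is available behind `tau2_method="REML"`.
The implementation was cross-checked against an established meta-analysis
package (metafor 4.8, `method="DL"`): estimates, SEs, Q, I² and τ² agree to
12 decimals on a 5-study fixture frozen into the test suite.

The gene screen applies three criteria: (1) the gene was measured in at
least half of all studies in the design (ceiling for odd totals — the
stricter reading); (2) pooled `p < 0.05` (raw, not FDR-adjusted — the
screen is deliberately a raw-p filter; BH-adjusted values are available
from the enrichment module); (3) pooled LFC `> 0.59` or `< −1.00`.  The
asymmetric bounds both correspond to roughly a 50% change on the
fold-change scale: `2^0.59 − 1 ≈ +50.5%`, `1 − 2^−1 = −50%`.  Both are
strict inequalities.  The coverage denominator is the total number of
studies in the design, not the number that assayed the gene's platform.

## Normalization

"Normalization" is pluggable (`none | median | quantile`), defaulting to
per-sample median-centring after an optional `log2(x+1)` transform — the
mildest method that removes the per-study/array offsets the simulator
injects.  Two caveats worth knowing:

* LFC is location-invariant within a study, so a constant study offset
  cancels in case − control regardless of normalization; centring matters
  only for artifacts that differ between samples.
* Median-centring assumes most genes are unregulated.  When a large
  fraction of genes shift in one direction, the case-column medians absorb
  part of the signal and every LFC is biased toward zero (≈0.1 log2 units
  at 10% regulated genes with unit effects).  For that reason the
  parameter-recovery evaluation below uses `method="none"` on data whose
  only nuisance is the per-study offset.

## Synthetic data generator

Each value is `baseline_g + offset_i + θ_gi·1[case] + N(0, within_sd)`:
gene baselines uniform on log2 ∈ [2, 12], study offsets N(0, 0.5) — both
nuisance structure — and the realised effect `θ_gi ~ N(μ, τ²)` i.i.d.
across studies for non-null genes, exactly 0 for null genes.  Study-level
moderator effects (region shifts, a slope in total sample size, a slope in
centred year) add to θ for every gene, emulating technical study-level
drivers of expression change.  Dropout is independent Bernoulli per
(gene, study), emulating platform differences that leave a gene unmeasured
in some series (the headline gene of the reference design was absent from
6 of its 14 studies, a rate near the 0.43 exercised in tests).

Defaults are the reference study conditions: K = 14 with the registry's arm
sizes, 500 genes, 90% null, μ = 1.0, τ² = 0.15, `within_sd` = 1.0 (a
conventional log2-scale residual sd for array data; the real studies' noise
magnitude is not published), dropout 0.2.  A single root generator seeded
from `seed` draws, in order: baselines, study offsets, null flags, the θ
matrix, the dropout mask, then per-study noise in study order — identical
seed and config give bit-identical matrices.

What the generator does **not** emulate: probe-level artifacts, batch
surrogate structure, count-distributed RNA-seq noise (no negative-binomial
mode), gene–gene correlation, or confounding between group and technical
covariates.  Passing tests therefore demonstrate correctness of the
statistics under a Gaussian-on-log model, not robustness to everything real
GEO series contain.

## Evaluation protocols and observed behaviour

* **Parameter recovery** — 500 genes, all non-null, μ = 1.0, τ² = 0.15,
  the 14-study design, `method="none"` (see the normalization caveat):
  the median random-effects estimate recovers μ within ±0.1 and the median
  DL τ² falls within ±50% of the truth (DL is slightly downward-biased in
  the median at k = 14 with heterogeneous `v_i`; ≈0.13–0.14 observed).
* **Type-I control** — 2,000 all-null genes through the full pipeline
  (median centring on): the pooled two-sided test rejects at 5% for
  5–6% of genes across seeds.  The mild anticonservatism comes from
  small-arm studies (one study has a 2-sample case arm) whose variance
  estimates are noisy; it stays inside the 3–7% band asserted in tests.
* **Moderator coverage** — a +0.5 region effect planted by the generator
  lands inside its own OLS 95% CI in ≥90 of 100 seeded replicates.

## Moderator regression

Per gene, per-study LFCs are regressed by OLS on an intercept plus total
sample size, region dummies (treatment coding, most frequent level as
reference) and centred publication year; p-values and 95% CIs are
normal-theory t-based.  Unweighted OLS is the default, matching a generic
regression routine; `weighted=True` uses 1/v_i weights.  Constant or
collinear design columns are dropped with a warning (rightmost first)
rather than failing — a registry with a single region simply loses its
region term.  This is ordinary regression of effect sizes, not a
mixed-effects meta-regression with τ² re-estimation per moderator model.

## Overlap and enrichment

Both tests are one-sided in the enrichment direction.  The overlap p-value
is the exact hypergeometric upper tail (equivalently one-sided Fisher on
the 2×2 table); the odds ratio uses a Haldane 0.5 correction only when a
zero cell occurs; fold enrichment is `observed / (n_a·n_b/N)`.  The
background universe N is always an explicit parameter (size or explicit
symbol list; 20,000 protein-coding symbols is the conventional default)
because published overlap p-values are unrecoverable without knowing the
universe their tool used — `universe_for_target_p` inverts a target p to
the implied universe size as a diagnostic.  Gene-set enrichment applies the
same hypergeometric test per GMT set with Benjamini–Hochberg adjustment
within one collection at a time (ranking a collection is a within-family
question); no ranked/weighted KS-style statistic is provided, since the
overlap formulation is the method being packaged.

## Numerical choices

* Sampling variances are floored at 1e−8 (flagged) so zero-spread
  degenerate genes keep finite weights.
* τ² and I² truncate at 0; `I² = 0` when `Q = 0`.
* Enrichment results sort by (p, set name) for deterministic ties.
* Result TSVs are written with `%.10g`, making repeat runs byte-identical
  and round-trips exact to ~1e−9 relative.
* Genes observed in fewer than two studies are skipped by pooling (the
  estimate would be undefined), and the pipeline log counts them.

## Known limitations

No probe→gene mapping, no GEO download/parsing, no empirical-Bayes variance
moderation, no publication-bias diagnostics, no leave-one-out influence
analysis, no Hartung–Knapp small-k correction.  The screen's raw-p
criterion is inherited from the screening procedure being packaged and is
anticonservative over many genes; users wanting FDR control should filter
on the optional BH column instead.
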