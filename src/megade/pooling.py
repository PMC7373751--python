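"""Fixed- and random-effects pooling of per-study effect sizes.

For one gene with effects ``y_i`` and sampling variances ``v_i`` over ``k``
studies:

* fixed effect — inverse-variance weights ``w_i = 1/v_i``,
  ``est = sum(w_i y_i) / sum(w_i)``, ``se = sqrt(1 / sum(w_i))``;
* heterogeneity — Cochran's ``Q = sum w_i (y_i - est_FE)^2`` with
  ``df = k - 1``, ``p_Q`` from the chi-square upper tail,
  ``I2 = max(0, 100 (Q - df) / Q)``;
* between-study variance — DerSimonian-Laird method of moments,
  ``tau2 = max(0, (Q - df) / (sum w_i - sum w_i^2 / sum w_i))``,
  with an iterative REML estimator available behind ``tau2_method``;
* random effects — same weighted mean with ``w*_i = 1/(v_i + tau2)``.

Model selection follows the usual two-stage rule: the random-effects
estimate is reported when the heterogeneity test is significant
(``p_Q < q_alpha``, default 0.05), the fixed-effect estimate otherwise.
Gene-level inference is a Wald z-test on the selected estimate with a
normal 95% CI (multiplier 1.96).

The gene screen keeps a gene when (1) it was measured in at least a given
fraction of all studies (default half, rounded up), (2) its pooled p is
below alpha, and (3) its pooled LFC exceeds an asymmetric threshold pair
(default > 0.59 for up-regulation, < -1.00 for down-regulation; on the
fold-change scale both correspond to roughly a 50% change).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MetaResult",
    "ScreenCriteria",
    "fixed_effect",
    "heterogeneity",
    "random_effect",
    "tau2_reml",
    "pool_gene",
    "pool_effects",
    "screen_genes",
    "forest_table",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

META_COLUMNS = [
    "gene", "k", "fe_est", "fe_se", "tau2", "re_est", "re_se",
    "Q", "df", "p_Q", "I2", "model_used",
    "est", "se", "ci_low", "ci_high", "z", "p",
]


@dataclass
class MetaResult:
    """Pooled record for one gene: both models, heterogeneity, selection."""

    gene: str
    k: int
    fe_est: float
    fe_se: float
    tau2: float
    re_est: float
    re_se: float
    Q: float
    df: int
    p_Q: float
    I2: float
    model_used: str
    est: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float


@dataclass
class ScreenCriteria:
    """The three gene-screening thresholds, as configuration."""

    min_study_fraction: float = 0.5
    alpha: float = 0.05
    lfc_upper: float = 0.59
    lfc_lower: float = -1.00

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (self.lfc_lower < 0 < self.lfc_upper):
            raise ValueError("need lfc_lower < 0 < lfc_upper")
        if not (0 < self.min_study_fraction <= 1):
            raise ValueError("min_study_fraction must be in (0, 1]")

    def min_studies(self, n_studies_total: int) -> int:
        return math.ceil(self.min_study_fraction * n_studies_total)


def _check_yv(y: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if y.shape != v.shape or y.ndim != 1:
        raise ValueError("y and v must be 1-D arrays of equal length")
    if len(y) < 2:
        raise ValueError("pooling needs k >= 2 studies")
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be > 0")
    return y, v


def fixed_effect(y, v) -> tuple[float, float]:
    """Inverse-variance pooled estimate and its standard error."""
    y, v = _check_yv(y, v)
    w = 1.0 / v
    sw = w.sum()
    return float((w * y).sum() / sw), float(math.sqrt(1.0 / sw))


def heterogeneity(y, v, fe_est: float) -> tuple[float, int, float, float, float]:
    """Cochran's Q, df, p_Q, I2 (percent) and DerSimonian-Laird tau2."""
    y, v = _check_yv(y, v)
    w = 1.0 / v
    Q = float((w * (y - fe_est) ** 2).sum())
    df = len(y) - 1
    p_Q = float(stats.chi2.sf(Q, df))
    I2 = max(0.0, 100.0 * (Q - df) / Q) if Q > 0 else 0.0
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    return Q, df, p_Q, I2, tau2


def random_effect(y, v, tau2: float) -> tuple[float, float]:
    """Random-effects pooled estimate with weights 1/(v_i + tau2)."""
    y, v = _check_yv(y, v)
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    w = 1.0 / (v + tau2)
    sw = w.sum()
    return float((w * y).sum() / sw), float(math.sqrt(1.0 / sw))


def tau2_reml(y, v, tol: float = 1e-10, max_iter: int = 200) -> float:
    """Restricted maximum-likelihood tau2 (iterative; DL is the default)."""
    y, v = _check_yv(y, v)

    def neg_restricted_ll(t2: float) -> float:
        w = 1.0 / (v + t2)
        mu = (w * y).sum() / w.sum()
        return 0.5 * (
            np.log(v + t2).sum() + (w * (y - mu) ** 2).sum() + math.log(w.sum())
        )

    res = optimize.minimize_scalar(
        neg_restricted_ll,
        bounds=(0.0, max(1e-6, 10.0 * float(np.var(y)) + 1.0)),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    return float(max(0.0, res.x))


def pool_gene(
    gene: str,
    y,
    v,
    q_alpha: float = 0.05,
    tau2_method: str = "DL",
) -> MetaResult:
    """Pool one gene's per-study effects and select the reporting model."""
    y, v = _check_yv(y, v)
    fe_est, fe_se = fixed_effect(y, v)
    Q, df, p_Q, I2, tau2 = heterogeneity(y, v, fe_est)
    if tau2_method == "REML":
        tau2 = tau2_reml(y, v)
    elif tau2_method != "DL":
        raise ValueError(f"unknown tau2_method {tau2_method!r}")
    re_est, re_se = random_effect(y, v, tau2)
    model = "random" if p_Q < q_alpha else "fixed"
    est, se = (re_est, re_se) if model == "random" else (fe_est, fe_se)
    z = est / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(
        gene=gene, k=len(y),
        fe_est=fe_est, fe_se=fe_se, tau2=tau2,
        re_est=re_est, re_se=re_se,
        Q=Q, df=df, p_Q=p_Q, I2=I2,
        model_used=model,
        est=est, se=se,
        ci_low=est - Z_95 * se, ci_high=est + Z_95 * se,
        z=z, p=p,
    )


def pool_effects(
    effects: pd.DataFrame,
    q_alpha: float = 0.05,
    tau2_method: str = "DL",
) -> pd.DataFrame:
    """Pool a tidy effects table (study_id, gene, lfc, variance) per gene.

    Genes observed in fewer than two studies are skipped.  Returns one row
    per pooled gene with the :data:`META_COLUMNS` fields.
    """
    rows = []
    for gene, grp in effects.groupby("gene", sort=True):
        if len(grp) < 2:
            continue
        res = pool_gene(
            str(gene),
            grp["lfc"].to_numpy(),
            grp["variance"].to_numpy(),
            q_alpha=q_alpha,
            tau2_method=tau2_method,
        )
        rows.append(res.__dict__)
    out = pd.DataFrame(rows, columns=META_COLUMNS)
    return out


def screen_genes(
    results: pd.DataFrame,
    n_studies_total: int,
    criteria: ScreenCriteria | None = None,
    add_bh: bool = True,
) -> pd.DataFrame:
    """Apply the three-part gene screen; emit per-criterion flags.

    Adds boolean columns ``pass_coverage`` (measured in at least the
    required number of studies), ``pass_p`` and ``pass_lfc`` plus their
    conjunction ``passed``.  The screen itself uses raw p-values; a
    Benjamini-Hochberg ``p_bh`` column is appended for reference unless
    ``add_bh`` is disabled.
    """
    if n_studies_total < 2:
        raise ValueError("n_studies_total must be >= 2")
    criteria = criteria or ScreenCriteria()
    need_k = criteria.min_studies(n_studies_total)
    out = results.copy()
    if add_bh and len(out):
        from .enrichment import bh_adjust

        out["p_bh"] = bh_adjust(out["p"].to_numpy())
    out["pass_coverage"] = out["k"] >= need_k
    out["pass_p"] = out["p"] < criteria.alpha
    out["pass_lfc"] = (out["est"] > criteria.lfc_upper) | (
        out["est"] < criteria.lfc_lower
    )
    out["passed"] = out["pass_coverage"] & out["pass_p"] & out["pass_lfc"]
    return out


def forest_table(
    gene: str,
    effects: pd.DataFrame,
    model: str = "fixed",
    tau2: float = 0.0,
) -> pd.DataFrame:
    """Per-study rows of a forest plot: effect, 95% CI, normalized weight.

    ``effects`` is the tidy per-study table filtered or filterable to one
    gene; weights are the selected model's pooling weights scaled to sum
    to 100.
    """
    sub = effects.loc[effects["gene"] == gene]
    if sub.empty:
        raise ValueError(f"no per-study effects for gene {gene!r}")
    v = sub["variance"].to_numpy(dtype=float)
    if model == "fixed":
        w = 1.0 / v
    elif model == "random":
        w = 1.0 / (v + tau2)
    else:
        raise ValueError(f"model must be fixed or random, got {model!r}")
    half = Z_95 * np.sqrt(v)
    lfc = sub["lfc"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "study_id": sub["study_id"].to_numpy(),
            "lfc": lfc,
            "ci_low": lfc - half,
            "ci_high": lfc + half,
            "weight_pct": 100.0 * w / w.sum(),
        }
    )
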