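"""Moderator regression: per-study effect sizes on study-level covariates.

For one gene, the per-study LFCs are regressed (ordinary least squares) on
an intercept plus any of three study-level moderators:

* ``size`` — total sample size, n_case + n_control;
* ``region`` — country, treatment-coded with the most frequent level as
  reference;
* ``year`` — publication year, centred at its mean.

Coefficient p-values and 95% CIs are normal-theory t-based, as produced by
an ordinary regression routine.  Weighted least squares with weights
1/variance is available behind a flag; the default is unweighted.
Rank-deficient design columns (e.g. region with a single level, constant
year) are dropped with a warning rather than failing the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import StudyMeta

logger = logging.getLogger(__name__)

__all__ = ["ModeratorFit", "build_design", "fit_moderators"]

TERMS = ("size", "region", "year")


@dataclass
class ModeratorFit:
    """OLS result for one gene: one row per retained design column."""

    gene: str
    terms: pd.DataFrame  # columns: term, coef, se, p, ci_low, ci_high
    n_studies: int
    r2: float
    dropped: list[str]


def build_design(
    registry: list[StudyMeta] | pd.DataFrame,
    terms=TERMS,
) -> pd.DataFrame:
    """Design matrix indexed by study_id with the requested moderators."""
    if not isinstance(registry, pd.DataFrame):
        registry = pd.DataFrame([m.__dict__ for m in registry])
    registry = registry.set_index("study_id")
    design = pd.DataFrame(index=registry.index)
    for term in terms:
        if term == "size":
            design["size"] = (
                registry["n_case"].astype(float) + registry["n_control"].astype(float)
            )
        elif term == "year":
            yr = registry["year"].astype(float)
            design["year"] = yr - yr.mean()
        elif term == "region":
            region = registry["country"].astype(str)
            ref = region.value_counts().index[0]  # most frequent level is reference
            for level in sorted(set(region) - {ref}):
                design[f"region[{level}]"] = (region == level).astype(float)
        else:
            raise ValueError(f"unknown moderator term {term!r}")
    return design


def fit_moderators(
    effects: pd.DataFrame,
    registry: list[StudyMeta] | pd.DataFrame,
    gene: str,
    terms=TERMS,
    weighted: bool = False,
) -> ModeratorFit:
    """Regress one gene's per-study LFCs on the study-level moderators."""
    sub = effects.loc[effects["gene"] == gene]
    if sub.empty:
        raise ValueError(f"no per-study effects for gene {gene!r}")
    design = build_design(registry, terms).loc[sub["study_id"]]

    dropped = []
    for col in list(design.columns):
        if design[col].nunique() <= 1:
            dropped.append(col)
            design = design.drop(columns=col)
            logger.warning("moderator column %r is constant; dropped", col)
    # collinear columns make the fit non-identifiable; drop from the right
    ones = np.ones((len(design), 1))
    for col in reversed(list(design.columns)):
        X_try = np.hstack([ones, design.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(X_try) < X_try.shape[1]:
            probe = design.drop(columns=col)
            X_probe = np.hstack([ones, probe.to_numpy(dtype=float)])
            if np.linalg.matrix_rank(X_probe) == np.linalg.matrix_rank(X_try):
                dropped.append(col)
                design = probe
                logger.warning("moderator column %r is collinear; dropped", col)
    X = sm.add_constant(design, has_constant="add")
    k = len(sub)
    if k < X.shape[1] + 1:
        raise ValueError(
            f"{gene}: {k} studies cannot support {X.shape[1]} design columns"
        )
    y = sub["lfc"].to_numpy(dtype=float)
    if weighted:
        model = sm.WLS(y, X.to_numpy(), weights=1.0 / sub["variance"].to_numpy())
    else:
        model = sm.OLS(y, X.to_numpy())
    fit = model.fit()
    ci = fit.conf_int(alpha=0.05)
    names = ["intercept"] + list(design.columns)
    table = pd.DataFrame(
        {
            "term": names,
            "coef": fit.params,
            "se": fit.bse,
            "p": fit.pvalues,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(fit.rsquared)  # NaN when the response is constant
    return ModeratorFit(
        gene=gene,
        terms=table,
        n_studies=k,
        r2=r2,
        dropped=dropped,
    )
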