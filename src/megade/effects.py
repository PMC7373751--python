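"""Per-study normalization and log-fold-change effect sizes.

The effect-size index is the difference of mean log2 expression, case minus
control (LFC), with a Welch-form sampling variance

    var(LFC) = s2_case / n_case + s2_control / n_control

computed from sample variances (n-1 denominator) over non-missing values.
This is the standard sampling variance that feeds inverse-variance pooling.

Normalization is deliberately mild and pluggable: after an optional
``log2(x + 1)`` transform of raw intensities, each sample (column) is
median-centred to remove study/array offsets; quantile normalization is
available as a stricter alternative, ``none`` as an escape hatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = ["StudyEffect", "VARIANCE_FLOOR", "normalize_log2", "study_effects"]

#: lower bound on the sampling variance; keeps inverse-variance weights
#: finite for degenerate zero-spread genes (records are flagged)
VARIANCE_FLOOR = 1e-8

EFFECT_COLUMNS = [
    "study_id",
    "gene",
    "lfc",
    "variance",
    "n_case",
    "n_control",
    "var_floored",
]


@dataclass(frozen=True)
class StudyEffect:
    """One gene's effect in one study: LFC, its variance, per-arm n used."""

    study_id: str
    gene: str
    lfc: float
    variance: float
    n_case: int
    n_control: int
    var_floored: bool = False


def normalize_log2(
    study: ExpressionStudy,
    already_log: bool = True,
    method: str = "median",
) -> ExpressionStudy:
    """Log2-transform (if needed) and normalize one study.

    ``method`` is one of ``"median"`` (subtract each sample's median),
    ``"quantile"`` (classic rank-mean quantile normalization across
    samples) or ``"none"``.  Raw-scale input must be non-negative; a +1
    pseudocount tolerates zeros.
    """
    values = study.values
    if not already_log:
        if (values < 0).any().any():
            raise ValueError(
                f"{study.meta.study_id}: negative raw intensities cannot be log2-transformed"
            )
        values = np.log2(values + 1.0)
    if method == "median":
        values = values - values.median(axis=0)
    elif method == "quantile":
        values = _quantile_normalize(values)
    elif method != "none":
        raise ValueError(f"unknown normalization method {method!r}")
    return ExpressionStudy(values=values, groups=study.groups, meta=study.meta)


def _quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Rank-mean quantile normalization; NaNs stay NaN.

    The reference distribution is the pooled empirical distribution of all
    non-missing values; each column's values are replaced by the reference
    quantiles at their within-column ranks, which handles columns with
    unequal numbers of missing cells.
    """
    flat = values.to_numpy(dtype=float).ravel()
    ref = np.sort(flat[~np.isnan(flat)])
    if ref.size == 0:
        return values.copy()
    grid = np.linspace(0.0, 1.0, ref.size)
    ranked = values.rank(method="first")
    out = values.copy()
    for col in values.columns:
        mask = values[col].notna()
        n = int(mask.sum())
        if n == 0:
            continue
        q = (ranked.loc[mask, col].to_numpy() - 1.0) / max(n - 1, 1)
        out.loc[mask, col] = np.interp(q, grid, ref)
    return out


def study_effects(study: ExpressionStudy) -> pd.DataFrame:
    """Per-gene LFC and Welch variance for one normalized study.

    Returns a tidy frame with columns ``study_id, gene, lfc, variance,
    n_case, n_control, var_floored``.  Genes with fewer than two
    non-missing values in either arm are skipped (and counted in the log);
    variances below :data:`VARIANCE_FLOOR` are floored and flagged.
    """
    case_cols = study.case_samples
    ctrl_cols = study.control_samples
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError(
            f"{study.meta.study_id}: need >=2 case and >=2 control samples "
            f"(have {len(case_cols)}/{len(ctrl_cols)})"
        )
    case = study.values[case_cols].to_numpy(dtype=float)
    ctrl = study.values[ctrl_cols].to_numpy(dtype=float)

    n_case = np.sum(~np.isnan(case), axis=1)
    n_ctrl = np.sum(~np.isnan(ctrl), axis=1)
    ok = (n_case >= 2) & (n_ctrl >= 2)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info(
            "%s: skipped %d genes with <2 non-missing samples in an arm",
            study.meta.study_id,
            n_skipped,
        )

    with np.errstate(invalid="ignore"):
        mean_case = np.nanmean(np.where(np.isnan(case), np.nan, case), axis=1)
        mean_ctrl = np.nanmean(ctrl, axis=1)
        var_case = _nanvar_ddof1(case, n_case)
        var_ctrl = _nanvar_ddof1(ctrl, n_ctrl)

    lfc = mean_case - mean_ctrl
    variance = var_case / np.maximum(n_case, 1) + var_ctrl / np.maximum(n_ctrl, 1)
    floored = variance < VARIANCE_FLOOR
    variance = np.maximum(variance, VARIANCE_FLOOR)

    out = pd.DataFrame(
        {
            "study_id": study.meta.study_id,
            "gene": study.genes,
            "lfc": lfc,
            "variance": variance,
            "n_case": n_case.astype(int),
            "n_control": n_ctrl.astype(int),
            "var_floored": floored,
        }
    )
    return out.loc[ok].reset_index(drop=True)


def _nanvar_ddof1(arr: np.ndarray, n: np.ndarray) -> np.ndarray:
    out = np.full(arr.shape[0], np.nan)
    enough = n >= 2
    if enough.any():
        out[enough] = np.nanvar(arr[enough], axis=1, ddof=1)
    return out


def collect_effects(studies) -> pd.DataFrame:
    """Concatenate :func:`study_effects` over several normalized studies."""
    frames = [study_effects(s) for s in studies]
    return pd.concat(frames, ignore_index=True)
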