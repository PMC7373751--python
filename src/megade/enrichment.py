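"""Gene-list overlap significance and overlap-based gene-set enrichment.

Two tests, both one-sided in the enrichment direction:

* :func:`fisher_overlap` — is the overlap of two gene lists drawn from a
  common background universe larger than chance?  Exact hypergeometric
  upper-tail p (equivalent to one-sided Fisher's exact on the 2x2 table).
* :func:`enrich_sets` — the same question for one query list against every
  set in a GMT collection, with Benjamini-Hochberg control of the FDR
  across the collection.

The background universe is an explicit parameter everywhere (a size or an
explicit symbol list; ~20,000 protein-coding genes is a common choice).
Published overlap p-values are extremely sensitive to this universe, so it
is never a hidden constant; :func:`universe_for_target_p` inverts the
relationship as a diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "EnrichmentResult",
    "fisher_overlap",
    "enrich_sets",
    "bh_adjust",
    "universe_for_target_p",
]


@dataclass
class OverlapResult:
    """Overlap of two gene lists against a background universe."""

    n_background: int
    n_a: int
    n_b: int
    n_overlap: int
    odds_ratio: float
    fold_enrichment: float
    p: float
    overlap_genes: list[str]


@dataclass
class EnrichmentResult:
    """One gene set's enrichment in a query list."""

    name: str
    set_size: int
    n_overlap: int
    overlap_genes: list[str]
    p: float
    q: float


def _overlap_p(n_background: int, n_a: int, n_b: int, n_overlap: int) -> float:
    """P(overlap >= observed) under random draws from the universe."""
    return float(stats.hypergeom.sf(n_overlap - 1, n_background, n_a, n_b))


def fisher_overlap(
    list_a, list_b, background
) -> OverlapResult:
    """One-sided Fisher/hypergeometric overlap test for two gene lists.

    ``background`` is either the universe size (int) or an explicit symbol
    collection; with an explicit universe, list members outside it are
    logged and clipped.  The odds ratio comes from the 2x2 membership
    table, with a Haldane 0.5 correction only when a zero cell occurs.
    """
    a = list(dict.fromkeys(list_a))
    b = list(dict.fromkeys(list_b))
    if not a or not b:
        raise ValueError("gene lists must be non-empty")
    if isinstance(background, (int, np.integer)):
        n_bg = int(background)
    else:
        universe = set(background)
        n_bg = len(universe)
        for name, lst in (("A", a), ("B", b)):
            outside = [g for g in lst if g not in universe]
            if outside:
                logger.warning(
                    "list %s: %d genes outside the background were clipped",
                    name, len(outside),
                )
        a = [g for g in a if g in universe]
        b = [g for g in b if g in universe]
        if not a or not b:
            raise ValueError("a gene list is empty after clipping to the background")
    n_a, n_b = len(a), len(b)
    if n_a + n_b - len(set(a) & set(b)) > n_bg:
        raise ValueError("background universe smaller than the union of the lists")
    shared = sorted(set(a) & set(b))
    k = len(shared)
    p = _overlap_p(n_bg, n_a, n_b, k)
    table = np.array(
        [[k, n_a - k], [n_b - k, n_bg - n_a - n_b + k]], dtype=float
    )
    if (table == 0).any():
        table = table + 0.5
    odds = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    fold = k / (n_a * n_b / n_bg)
    return OverlapResult(
        n_background=n_bg, n_a=n_a, n_b=n_b, n_overlap=k,
        odds_ratio=odds, fold_enrichment=float(fold), p=p,
        overlap_genes=shared,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_sets(
    query,
    collection: GeneSetCollection,
    background,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query list in every collection set.

    Returns one row per testable set with columns ``name, set_size,
    n_overlap, overlap_genes, p, q``, sorted by ascending p (ties by set
    name).  BH adjustment is applied within this collection only.
    """
    query = list(dict.fromkeys(query))
    if not query:
        raise ValueError("query list must be non-empty")
    if isinstance(background, (int, np.integer)):
        n_bg = int(background)
        universe = None
    else:
        universe = set(background)
        n_bg = len(universe)
        missing = [g for g in query if g not in universe]
        if missing:
            logger.warning("%d query genes outside the background were clipped",
                           len(missing))
            query = [g for g in query if g in universe]
    qset = set(query)
    rows = []
    for name, members in collection:
        members = set(members) if universe is None else set(members) & universe
        if not members:
            logger.warning("set %r has no members in the background; skipped", name)
            continue
        shared = sorted(qset & members)
        p = _overlap_p(n_bg, len(members), len(query), len(shared))
        rows.append(
            {
                "name": name,
                "set_size": len(members),
                "n_overlap": len(shared),
                "overlap_genes": ",".join(shared),
                "p": p,
            }
        )
    if not rows:
        raise ValueError("no testable sets in the collection")
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "name"], kind="mergesort").reset_index(drop=True)


def universe_for_target_p(
    n_a: int, n_b: int, n_overlap: int, target_p: float,
    n_max: int = 10_000_000,
) -> int | None:
    """Smallest universe size at which the overlap reaches a target p.

    The overlap p-value falls monotonically as the universe grows (a fixed
    overlap becomes more surprising), so this inverts a published p-value
    to the universe size it implies.  Returns None when even ``n_max``
    cannot reach the target.  Diagnostic only.
    """
    lo = n_a + n_b - n_overlap
    if _overlap_p(n_max, n_a, n_b, n_overlap) > target_p:
        return None
    hi = n_max
    while lo < hi:
        mid = (lo + hi) // 2
        if _overlap_p(mid, n_a, n_b, n_overlap) <= target_p:
            hi = mid
        else:
            lo = mid + 1
    return lo
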