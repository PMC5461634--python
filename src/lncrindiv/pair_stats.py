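"""Stable-pair and reversal-pair statistics.

A *stable pair* is an ordered lncRNA pair (low, high) whose within-sample
ordering ``low < high`` holds in strictly more than a stability fraction
(default 95%) of normal samples. A *reversal pair* is a stable pair whose
ordering is significantly flipped in cancer samples: the 2x2 table of
(normal/cancer) x (low<high / low>high) counts (a, b, c, d) is tested with a
one-sided Fisher's exact test toward enrichment of the flipped orientation in
cancer, and the p-values are Benjamini-Hochberg adjusted over all stable
pairs tested in the run; pairs with q below the FDR threshold (default 0.1)
are retained. A reversal of (low < high) implies the low member moved up or
the high member moved down, which is how per-member dysregulation directions
are recorded.

Exact within-sample expression ties contribute to neither orientation of a
pair (continuous expression rarely ties and no tie rule is implied by the
ordering model).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "rank_transform",
    "find_stable_pairs",
    "binomial_stability_pvalue",
    "fisher_reversal_pvalue",
    "bh_adjust",
    "find_reversal_pairs",
]


def rank_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Per-sample rank profile: smallest value gets rank 1, ties averaged."""
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("expression values must be finite")
    ranks = stats.rankdata(arr, axis=0, method="average")
    return pd.DataFrame(ranks, index=values.index, columns=values.columns)


def _pairwise_less_counts(values: np.ndarray, block: int = 64) -> np.ndarray:
    """counts[i, j] = number of samples with values[i, s] < values[j, s].

    Accumulated over sample blocks to bound memory at ~G^2 * block bytes.
    """
    n_lnc, n_samp = values.shape
    counts = np.zeros((n_lnc, n_lnc), dtype=np.int64)
    for start in range(0, n_samp, block):
        chunk = values[:, start : start + block]
        counts += (chunk[:, None, :] < chunk[None, :, :]).sum(axis=2)
    return counts


def find_stable_pairs(matrix_normal: pd.DataFrame, stability_frac: float = 0.95) -> pd.DataFrame:
    """Find ordered pairs stable across normal samples.

    Parameters
    ----------
    matrix_normal
        lncRNA-by-sample expression values of the normal group (>= 2 samples).
    stability_frac
        Strict support threshold: a pair (low, high) is stable when
        ``a / (a + b) > stability_frac``, with ``a`` the number of tie-free
        normal samples showing ``low < high`` and ``b`` the flipped count.

    Returns
    -------
    DataFrame with columns ``low``, ``high``, ``a``, ``b``, ``support``; each
    stable pair appears in exactly one orientation (low-in-normal first).
    """
    if not 0.5 < stability_frac <= 1:
        raise ValueError("stability_frac must be in (0.5, 1]")
    if matrix_normal.shape[1] < 2:
        raise ValueError("need at least 2 normal samples")
    vals = matrix_normal.to_numpy(dtype=float)
    less = _pairwise_less_counts(vals)
    iu, ju = np.where(np.triu(np.ones_like(less, dtype=bool), k=1))
    # canonical orientation: member observed below its partner
    a_fwd, a_rev = less[iu, ju], less[ju, iu]
    fwd = a_fwd >= a_rev
    low = np.where(fwd, iu, ju)
    high = np.where(fwd, ju, iu)
    a = less[low, high]
    b = less[high, low]
    n = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        supp = np.where(n > 0, a / np.maximum(n, 1), 0.0)
    keep = (n > 0) & (supp > stability_frac)
    ids = matrix_normal.index.to_numpy()
    out = pd.DataFrame(
        {
            "low": ids[low[keep]],
            "high": ids[high[keep]],
            "a": a[keep],
            "b": b[keep],
            "support": supp[keep],
        }
    )
    return out.sort_values(["low", "high"], kind="mergesort").reset_index(drop=True)


def binomial_stability_pvalue(k_min: int, n: int) -> float:
    """One-sided binomial tail P(X >= k_min | n, p = 1/2), exact summation.

    Quantifies how unlikely a pair ordering is to hold in at least ``k_min``
    of ``n`` samples if either orientation were equally likely.
    """
    if not 0 <= k_min <= n:
        raise ValueError("require 0 <= k_min <= n")
    return float(stats.binom.sf(k_min - 1, n, 0.5))


def fisher_reversal_pvalue(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p for enrichment of the flipped orientation in cancer.

    ``a``/``b`` are normal-sample counts of the stable and flipped orientation,
    ``c``/``d`` the cancer-sample counts. The p-value is the hypergeometric
    upper tail P(D >= d) over 2x2 tables with the observed margins.
    """
    counts = np.array([a, b, c, d])
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("all-zero contingency table")
    total = a + b + c + d
    flipped = b + d
    cancer = c + d
    return float(stats.hypergeom.sf(d - 1, total, flipped, cancer))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def find_reversal_pairs(
    stable_pairs: pd.DataFrame,
    matrix_normal: pd.DataFrame,
    matrix_cancer: pd.DataFrame,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Test every stable pair for significant order reversal in cancer.

    For each stable pair the cancer counts (c = low<high, d = low>high; exact
    ties dropped) are added to the normal counts, the one-sided Fisher p is
    computed, p-values are BH-adjusted across *all* stable pairs tested, and
    pairs with ``q < fdr`` are returned together with the implied per-member
    directions (``low`` member: up; ``high`` member: down).

    Returns a DataFrame with columns low, high, a, b, c, d, p, q.
    """
    if matrix_cancer.shape[1] == 0:
        raise ValueError("cancer group is empty")
    if len(stable_pairs) == 0:
        logger.warning("find_reversal_pairs: empty stable-pair set")
        return pd.DataFrame(columns=["low", "high", "a", "b", "c", "d", "p", "q"])
    pos = pd.Series(np.arange(len(matrix_cancer.index)), index=matrix_cancer.index)
    li = pos.loc[stable_pairs["low"]].to_numpy()
    hi = pos.loc[stable_pairs["high"]].to_numpy()
    vals = matrix_cancer.to_numpy(dtype=float)
    vl, vh = vals[li], vals[hi]
    c = (vl < vh).sum(axis=1)
    d = (vl > vh).sum(axis=1)
    a = stable_pairs["a"].to_numpy()
    b = stable_pairs["b"].to_numpy()
    total, flipped, cancer_n = a + b + c + d, b + d, c + d
    p = stats.hypergeom.sf(d - 1, total, flipped, cancer_n)
    q = bh_adjust(p)
    out = stable_pairs[["low", "high", "a", "b"]].copy()
    out["c"], out["d"], out["p"], out["q"] = c, d, p, q
    out = out[out["q"] < fdr].reset_index(drop=True)
    return out
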