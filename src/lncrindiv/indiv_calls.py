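"""Per-lncRNA partner curation and per-sample DE calling.

For a target lncRNA possessing reversal pairs, the partners are curated in
three steps. First the target's population-level dysregulation direction is
estimated as the sign of (mean rank in cancer - mean rank in normal); targets
with exactly equal means carry no direction and are excluded. Second, only
reversal pairs whose flip implies that direction are retained: a target
called *up* must be the low member of its stable pairs (it climbed past the
partner), a target called *down* the high member. Third, each partner's
coefficient of variation of rank across all samples (cancer and normal
pooled, sample standard deviation with n-1) is computed, and the (at most) 3
partners with the smallest CV are selected - a near-constant partner rank is
evidence that a reversal reflects movement of the target, not the partner.

An individual cancer sample is then called DE for the target exactly when the
reversed orientation holds in that sample for a strict majority of the
selected pairs; the call direction is the target's population direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix
from .pair_stats import find_reversal_pairs, find_stable_pairs, rank_transform

logger = logging.getLogger(__name__)

UP, DOWN, NONE = "up", "down", "none"

__all__ = [
    "TargetPartnerSet",
    "population_direction",
    "retain_concordant_partners",
    "partner_cv",
    "select_top_partners",
    "call_sample",
    "call_with_partners",
    "curate_partner_sets",
    "lncrindiv",
]


@dataclass
class TargetPartnerSet:
    """Curated reference partners for one target lncRNA.

    ``partners`` lists every direction-concordant reversal partner with its
    CV of rank; ``selected`` holds the ids of the (<= ``k``) smallest-CV
    partners actually used for calling. For an *up* target the reversed
    orientation in a sample is ``target > partner``; for a *down* target it is
    ``target < partner``.
    """

    target: str
    direction: str
    partners: pd.DataFrame = field(repr=False)  # columns: partner, cv
    selected: list[str] = field(default_factory=list)

    def reversed_in(self, target_values: pd.Series, partner_values: pd.DataFrame) -> pd.DataFrame:
        """Boolean (partner x sample) table of the reversed orientation."""
        if self.direction == UP:
            return partner_values.lt(target_values, axis=1)
        return partner_values.gt(target_values, axis=1)


def population_direction(target: str, rank_normal: pd.DataFrame, rank_cancer: pd.DataFrame) -> str | None:
    """Population dysregulation direction of ``target``: sign of the mean-rank shift.

    Returns ``"up"``, ``"down"``, or None when the mean ranks tie exactly
    (the target is then excluded from individual calling).
    """
    m_n = rank_normal.loc[target].mean()
    m_c = rank_cancer.loc[target].mean()
    if m_c > m_n:
        return UP
    if m_c < m_n:
        return DOWN
    return None


def retain_concordant_partners(target: str, direction: str, reversal_pairs: pd.DataFrame) -> list[str]:
    """Partners of ``target`` whose reversal implies the target's direction.

    An up-regulated target must be the ``low`` member of the stable pair
    (stable ``target < partner`` reversed to ``target > partner``); a
    down-regulated target must be the ``high`` member.
    """
    if direction == UP:
        rows = reversal_pairs[reversal_pairs["low"] == target]
        return rows["high"].tolist()
    rows = reversal_pairs[reversal_pairs["high"] == target]
    return rows["low"].tolist()


def partner_cv(rank_all: pd.DataFrame, partner: str) -> float:
    """Coefficient of variation of ``partner``'s rank over all pooled samples.

    CV = sample standard deviation (n-1) / mean. Ranks are >= 1, so the mean
    is always positive; a single sample has no dispersion estimate.
    """
    r = rank_all.loc[partner].to_numpy(dtype=float)
    if r.size < 2:
        raise ValueError("CV needs at least two samples")
    return float(r.std(ddof=1) / r.mean())


def select_top_partners(partner_set: TargetPartnerSet, k: int = 3) -> TargetPartnerSet:
    """Keep the k smallest-CV partners (all, if fewer); CV ties break
    lexicographically on partner id so selection is deterministic."""
    ordered = partner_set.partners.sort_values(["cv", "partner"], kind="mergesort")
    partner_set.selected = ordered["partner"].head(k).tolist()
    return partner_set


def call_sample(partner_set: TargetPartnerSet, sample_values: pd.Series) -> bool:
    """DE decision for one sample: strict majority of selected pairs reversed."""
    if not partner_set.selected:
        raise ValueError("partner set has no selected partners")
    tv = sample_values[partner_set.target]
    pv = sample_values[partner_set.selected]
    flipped = (pv < tv).sum() if partner_set.direction == UP else (pv > tv).sum()
    return bool(flipped * 2 > len(partner_set.selected))


def curate_partner_sets(
    reversal_pairs: pd.DataFrame,
    rank_normal: pd.DataFrame,
    rank_cancer: pd.DataFrame,
    k: int = 3,
) -> dict[str, TargetPartnerSet]:
    """Build the selected partner set for every target with reversal pairs."""
    rank_all = pd.concat([rank_normal, rank_cancer], axis=1)
    cv = rank_all.std(axis=1, ddof=1) / rank_all.mean(axis=1)
    targets = pd.unique(pd.concat([reversal_pairs["low"], reversal_pairs["high"]]))
    out: dict[str, TargetPartnerSet] = {}
    for target in targets:
        direction = population_direction(target, rank_normal, rank_cancer)
        if direction is None:
            logger.info("target %s excluded: tied mean ranks", target)
            continue
        partners = retain_concordant_partners(target, direction, reversal_pairs)
        if not partners:
            continue
        tab = pd.DataFrame({"partner": partners, "cv": cv.loc[partners].to_numpy()})
        pset = TargetPartnerSet(target=target, direction=direction, partners=tab)
        out[target] = select_top_partners(pset, k=k)
    return out


def call_with_partners(
    partner_sets: dict[str, TargetPartnerSet],
    matrix_cancer: pd.DataFrame,
    all_lnc_ids=None,
) -> pd.DataFrame:
    """Apply curated partner sets to every cancer sample.

    Returns the DE call matrix (lncRNA x sample, values in {up, down, none});
    rows default to the union of lncRNAs in ``matrix_cancer`` so lncRNAs
    without partner sets appear as all-``none``.
    """
    index = matrix_cancer.index if all_lnc_ids is None else pd.Index(all_lnc_ids)
    calls = pd.DataFrame(NONE, index=index, columns=matrix_cancer.columns, dtype=object)
    for target, pset in partner_sets.items():
        tv = matrix_cancer.loc[target]
        pv = matrix_cancer.loc[pset.selected]
        flipped = pv.lt(tv, axis=1) if pset.direction == UP else pv.gt(tv, axis=1)
        de = flipped.sum(axis=0) * 2 > len(pset.selected)
        calls.loc[target, de.values] = pset.direction
    return calls


def lncrindiv(
    matrix_normal: pd.DataFrame,
    matrix_cancer: pd.DataFrame,
    stability_frac: float = 0.95,
    fdr: float = 0.1,
    k: int = 3,
    return_partner_sets: bool = False,
):
    """Full individual-level DE pipeline.

    ranks -> stable pairs (normal) -> reversal pairs (cancer, Fisher + BH) ->
    per-target partner curation -> per-sample strict-majority calls.

    Parameters
    ----------
    matrix_normal, matrix_cancer
        lncRNA-by-sample expression values on any common monotone scale,
        sharing the same lncRNA index.
    stability_frac, fdr, k
        Stability threshold (strict), reversal FDR threshold, and the
        maximum number of reference partners per target.

    Returns
    -------
    The DE call matrix (lncRNA x cancer sample, {up, down, none}); with
    ``return_partner_sets=True`` also the dict of curated partner sets.
    """
    if matrix_normal.shape[1] == 0 or matrix_cancer.shape[1] == 0:
        raise ValueError("both groups must be non-empty")
    if not matrix_normal.index.equals(matrix_cancer.index):
        raise ValueError("normal and cancer matrices must share the same lncRNA index")
    stable = find_stable_pairs(matrix_normal, stability_frac=stability_frac)
    reversal = find_reversal_pairs(stable, matrix_normal, matrix_cancer, fdr=fdr)
    rank_n = rank_transform(matrix_normal)
    rank_c = rank_transform(matrix_cancer)
    psets = curate_partner_sets(reversal, rank_n, rank_c, k=k)
    calls = call_with_partners(psets, matrix_cancer, all_lnc_ids=matrix_cancer.index)
    if return_partner_sets:
        return calls, psets
    return calls
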