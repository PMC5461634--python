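"""Copy-number / expression concordance at the individual level.

Per-sample log2 copy-ratio values are discretized to {-1, 0, +1} with strict
cutoffs (ratio > 0.1 amplification, ratio < -0.1 deletion). For each lncRNA
the patients called DE (up or down) are compared with the patients carrying
the direction-matched copy-number state (gain for up, loss for down) over
the population of patients present in both matrices; the overlap is scored
with an upper-tail hypergeometric test. Concordance of individual-level DE
calls with an orthogonal DNA-level signal is evidence the calls are real.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .indiv_calls import DOWN, NONE, UP

logger = logging.getLogger(__name__)

__all__ = ["discretize_cna", "concordance_test", "cohort_concordance"]


def discretize_cna(log2_ratio: pd.DataFrame, amp_cut: float = 0.1, del_cut: float = -0.1) -> pd.DataFrame:
    """Discretize per-sample log2 copy ratios to states in {-1, 0, +1}.

    Strict inequalities: ratio > ``amp_cut`` is amplification (+1), ratio <
    ``del_cut`` deletion (-1), anything else (boundaries included) neutral.
    """
    if amp_cut <= del_cut:
        raise ValueError("amp_cut must exceed del_cut")
    arr = log2_ratio.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("log2 ratios must be finite")
    states = np.zeros_like(arr, dtype=int)
    states[arr > amp_cut] = 1
    states[arr < del_cut] = -1
    return pd.DataFrame(states, index=log2_ratio.index, columns=log2_ratio.columns)


def concordance_test(de_calls: pd.DataFrame, cna_matrix: pd.DataFrame, lnc_id: str) -> dict:
    """Hypergeometric overlap of DE patients with direction-matched CNA patients.

    The population is the patients shared by both matrices. For an
    up-regulated lncRNA the matched state is +1 (gain), for down-regulated
    -1 (loss). Returns a dict with the call direction, set sizes, the
    observed overlap and the upper-tail p-value P(overlap >= observed); when
    either set is empty the test is skipped (``p`` is None).
    """
    if lnc_id not in de_calls.index or lnc_id not in cna_matrix.index:
        raise KeyError(f"{lnc_id!r} missing from calls or CNA matrix")
    shared = [s for s in de_calls.columns if s in cna_matrix.columns]
    if not shared:
        raise ValueError("no shared patients between calls and CNA matrix")
    calls = de_calls.loc[lnc_id, shared]
    directions = set(calls[calls != NONE])
    if len(directions) != 1:
        return {"lnc_id": lnc_id, "direction": None, "n_shared": len(shared),
                "n_de": 0, "n_altered": 0, "overlap": 0, "p": None,
                "note": "no single call direction"}
    direction = directions.pop()
    state = 1 if direction == UP else -1
    cna = cna_matrix.loc[lnc_id, shared]
    de_set = calls == direction
    alt_set = cna == state
    n_de, n_alt = int(de_set.sum()), int(alt_set.sum())
    overlap = int((de_set & alt_set).sum())
    if n_de == 0 or n_alt == 0:
        return {"lnc_id": lnc_id, "direction": direction, "n_shared": len(shared),
                "n_de": n_de, "n_altered": n_alt, "overlap": overlap, "p": None,
                "note": "empty DE or altered set"}
    p = float(stats.hypergeom.sf(overlap - 1, len(shared), n_alt, n_de))
    return {"lnc_id": lnc_id, "direction": direction, "n_shared": len(shared),
            "n_de": n_de, "n_altered": n_alt, "overlap": overlap, "p": p, "note": ""}


def cohort_concordance(de_calls: pd.DataFrame, cna_matrix: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Run :func:`concordance_test` for every shared lncRNA and summarize.

    Returns ``{"table": per-lncRNA DataFrame, "n_tested": ..,
    "n_significant": ..}`` where significance is ``p < alpha``.
    """
    shared_lnc = [l for l in de_calls.index if l in cna_matrix.index]
    shared_samples = [s for s in de_calls.columns if s in cna_matrix.columns]
    if not shared_lnc or not shared_samples:
        raise ValueError("empty shared lncRNA/sample universe")
    rows = [concordance_test(de_calls, cna_matrix, lnc) for lnc in shared_lnc]
    table = pd.DataFrame(rows)
    tested = table["p"].notna()
    return {
        "table": table,
        "n_tested": int(tested.sum()),
        "n_significant": int((table.loc[tested, "p"] < alpha).sum()),
    }
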