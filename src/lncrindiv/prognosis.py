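"""Prognostic-signature machinery on individual-level DE calls.

For each candidate lncRNA, patients are split into with-DE and without-DE
groups; a candidate is admitted when both the log-rank test and a univariate
Cox proportional-hazards fit give P < 0.05 (uncorrected, one screening
family). The candidate's risk direction is its DE direction when the DE
group carries the higher hazard (HR > 1); DE patterns associated with
*better* survival cannot be expressed by the union risk rule below and are
not admitted.

The signature is grown by forward selection on Harrell's concordance index:
candidates are ranked by decreasing individual C-index, the best seeds the
signature, and each further candidate is kept only if adding it strictly
increases the C-index of the combined risk score. The combined score of a
member set is the *union rule*: a patient is high risk as soon as any member
is DE in its risk direction. Because every member's call reduces to at most
three within-sample expression comparisons, the final signature exports as a
threshold-free clinical rule table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex

from .indiv_calls import DOWN, NONE, UP, TargetPartnerSet

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureCandidate",
    "Signature",
    "screen_candidates",
    "harrell_c_index",
    "forward_select",
    "assign_risk_groups",
    "survival_association",
    "export_rules",
    "apply_rules",
    "km_plot",
]

MIN_GROUP = 3  # smallest testable group; needs >= 1 event as well


@dataclass
class SignatureCandidate:
    lnc_id: str
    risk_direction: str
    logrank_p: float
    cox_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    c_index: float


@dataclass
class Signature:
    members: list[tuple[str, str]]  # (lnc_id, risk_direction), selection order
    c_index: float
    candidates: list[SignatureCandidate] = field(default_factory=list, repr=False)

    @property
    def member_ids(self) -> list[str]:
        return [m for m, _ in self.members]


def _align(de_calls: pd.DataFrame, survival: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    shared = [s for s in de_calls.columns if s in survival.index]
    if not shared:
        raise ValueError("no shared samples between calls and survival table")
    surv = survival.loc[shared]
    if surv["time"].isna().any() or surv["event"].isna().any():
        raise ValueError("survival table has missing time/event for analysed samples")
    return de_calls[shared], surv


def _cox_univariate(indicator: np.ndarray, time: np.ndarray, event: np.ndarray):
    df = pd.DataFrame({"x": indicator.astype(float), "time": time, "event": event})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["x"]))
    lo, hi = np.exp(cph.confidence_intervals_.loc["x"]).to_numpy()
    p = float(cph.summary.loc["x", "p"])
    return hr, (float(lo), float(hi)), p


def harrell_c_index(risk_score, time, event) -> float:
    """Harrell's concordance index of a risk score against survival.

    A usable pair has unequal times with the earlier time an observed event;
    the pair scores 1 if the earlier-failing sample has the higher risk, 0.5
    on a risk tie, 0 otherwise. 0.5 means no predictive ability, 1 perfect.
    """
    risk = np.asarray(risk_score, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    # lifelines scores concordance for *higher = longer survival*; negate risk
    return float(_lifelines_cindex(t, -risk, e))


def screen_candidates(de_calls: pd.DataFrame, survival: pd.DataFrame, alpha: float = 0.05) -> list[SignatureCandidate]:
    """Screen every called lncRNA for association with overall survival.

    For each lncRNA with calls, samples split into DE / non-DE groups (both
    of size >= 3 with >= 1 event, else skipped). Admission requires log-rank
    and univariate Cox P < ``alpha``, with HR > 1 for the DE group; the risk
    direction is then the lncRNA's DE direction.
    """
    calls, surv = _align(de_calls, survival)
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    out: list[SignatureCandidate] = []
    for lnc in calls.index:
        row = calls.loc[lnc]
        de = (row != NONE).to_numpy()
        directions = set(row[row != NONE])
        if len(directions) != 1:
            if len(directions) > 1:
                logger.info("skip %s: mixed call directions", lnc)
            continue
        direction = directions.pop()
        n_de, n_not = int(de.sum()), int((~de).sum())
        if n_de < MIN_GROUP or n_not < MIN_GROUP:
            continue
        if event[de].sum() < 1 or event[~de].sum() < 1:
            continue
        lr = _logrank_test(time[de], time[~de], event[de], event[~de])
        try:
            hr, ci, cox_p = _cox_univariate(de, time, event)
        except Exception as exc:  # convergence/separation
            logger.info("skip %s: Cox fit failed (%s)", lnc, exc)
            continue
        if lr.p_value >= alpha or cox_p >= alpha:
            continue
        if hr <= 1:
            logger.info("skip %s: DE group protective (HR=%.3f)", lnc, hr)
            continue
        c = harrell_c_index(de.astype(float), time, event)
        out.append(
            SignatureCandidate(
                lnc_id=str(lnc), risk_direction=direction, logrank_p=float(lr.p_value),
                cox_p=cox_p, hazard_ratio=hr, hr_ci=ci, c_index=c,
            )
        )
    if not out:
        logger.warning("screen_candidates: no admissible candidates")
    return out


def _union_risk(calls: pd.DataFrame, members: list[tuple[str, str]]) -> np.ndarray:
    """Binary union risk score: 1 iff any member is DE in its risk direction."""
    risk = np.zeros(calls.shape[1], dtype=float)
    for lnc, direction in members:
        if lnc not in calls.index:
            raise KeyError(f"signature member {lnc!r} absent from call matrix")
        risk = np.maximum(risk, (calls.loc[lnc] == direction).to_numpy(float))
    return risk


def forward_select(
    candidates: list[SignatureCandidate],
    de_calls: pd.DataFrame,
    survival: pd.DataFrame,
) -> Signature:
    """Forward selection of the maximal-C-index signature.

    Candidates are ordered by decreasing individual C-index (ties broken
    lexicographically by id). The best candidate seeds the signature; each
    remaining candidate is tried once in order and kept only if the C-index
    of the union-rule risk score strictly increases.
    """
    if not candidates:
        raise ValueError("forward_select needs at least one candidate")
    calls, surv = _align(de_calls, survival)
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    order = sorted(candidates, key=lambda c: (-c.c_index, c.lnc_id))
    members = [(order[0].lnc_id, order[0].risk_direction)]
    best_c = harrell_c_index(_union_risk(calls, members), time, event)
    for cand in order[1:]:
        trial = members + [(cand.lnc_id, cand.risk_direction)]
        c = harrell_c_index(_union_risk(calls, trial), time, event)
        if c > best_c:
            members, best_c = trial, c
    return Signature(members=members, c_index=best_c, candidates=order)


def assign_risk_groups(de_calls: pd.DataFrame, signature: Signature) -> pd.Series:
    """Per-sample {'high','low'}: high iff any member is DE in its risk direction."""
    risk = _union_risk(de_calls, signature.members)
    return pd.Series(np.where(risk > 0, "high", "low"), index=de_calls.columns, name="risk_group")


def survival_association(
    groups: pd.Series,
    time,
    event,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Log-rank test plus uni- and multivariable Cox fits for a binary grouping.

    Returns ``{"logrank_p": ..., "univariate": {term: {HR, CI, p}},
    "multivariate": {...}}``; the multivariable fit adjusts for all provided
    covariate columns. A term whose fit fails (separation, degenerate
    covariate) is reported as ``{"error": ...}`` and the run continues.
    """
    g = pd.Series(groups)
    x = (g == "high").astype(float) if g.dtype == object else g.astype(float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    hi = x.to_numpy() > 0
    lr = _logrank_test(t[hi], t[~hi], e[hi], e[~hi])
    out = {"logrank_p": float(lr.p_value), "univariate": {}, "multivariate": {}}
    try:
        hr, ci, p = _cox_univariate(x.to_numpy(), t, e)
        out["univariate"]["group"] = {"HR": hr, "CI": ci, "p": p}
    except Exception as exc:
        out["univariate"]["group"] = {"error": str(exc)}
    if covariates is not None and covariates.shape[1] > 0:
        df = covariates.copy().astype(float)
        df.insert(0, "group", x.to_numpy())
        df["time"], df["event"] = t, e
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            for term in cph.params_.index:
                lo, hi_ci = np.exp(cph.confidence_intervals_.loc[term]).to_numpy()
                out["multivariate"][term] = {
                    "HR": float(np.exp(cph.params_[term])),
                    "CI": (float(lo), float(hi_ci)),
                    "p": float(cph.summary.loc[term, "p"]),
                }
            return out
        except Exception:
            pass
        # joint fit failed: retry per covariate so one bad column cannot void the rest
        for term in ["group"] + list(covariates.columns):
            cols = {"group": x.to_numpy()} if term == "group" else {term: covariates[term].to_numpy(float)}
            sub = pd.DataFrame({**cols, "time": t, "event": e})
            try:
                cph = CoxPHFitter()
                cph.fit(sub, duration_col="time", event_col="event")
                name = sub.columns[0]
                lo, hi_ci = np.exp(cph.confidence_intervals_.loc[name]).to_numpy()
                out["multivariate"][term] = {
                    "HR": float(np.exp(cph.params_[name])),
                    "CI": (float(lo), float(hi_ci)),
                    "p": float(cph.summary.loc[name, "p"]),
                }
            except Exception as exc:
                out["multivariate"][term] = {"error": str(exc)}
    return out


def km_plot(groups: pd.Series, time, event, ax=None, path=None):
    """Kaplan-Meier curves for the high/low risk groups (thin optional output).

    The annotated p-value is always the log-rank statistic, never read off
    the plot. Returns the matplotlib axes; saves to ``path`` if given.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    g = pd.Series(groups)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label in ("high", "low"):
        mask = (g == label).to_numpy()
        if mask.any():
            KaplanMeierFitter().fit(t[mask], e[mask], label=f"{label} risk").plot_survival_function(ax=ax)
    hi = (g == "high").to_numpy()
    lr = _logrank_test(t[hi], t[~hi], e[hi], e[~hi])
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_title(f"log-rank P = {lr.p_value:.2e}")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def export_rules(
    signature: Signature,
    partner_sets: dict[str, TargetPartnerSet],
) -> pd.DataFrame:
    """Export the signature as threshold-free pairwise comparison rules.

    One row per (member, partner) comparison: for an *up* (risk) member the
    dysregulated state in a sample is ``expression(member) higher than
    expression(partner)``; for *down*, lower. A member is called DE in a
    sample when a strict majority of its comparisons hold, and the sample is
    high risk when any member is called. The table is both human-readable and
    machine-applicable (see :func:`apply_rules`).
    """
    rows = []
    for lnc, direction in signature.members:
        pset = partner_sets.get(lnc)
        if pset is None or not pset.selected:
            raise ValueError(f"signature member {lnc!r} has no selected partners")
        k = len(pset.selected)
        majority = k // 2 + 1
        relation = "higher" if direction == UP else "lower"
        for partner in pset.selected:
            rows.append(
                {
                    "member": lnc,
                    "risk_direction": direction,
                    "relation": relation,
                    "partner": partner,
                    "n_comparisons": k,
                    "majority_needed": majority,
                }
            )
    return pd.DataFrame(rows)


def apply_rules(rules: pd.DataFrame, expression: pd.DataFrame) -> pd.Series:
    """Classify samples {'high','low'} directly from expression via the rules.

    For each member: count comparisons that hold in the sample (member value
    strictly higher/lower than partner value); the member fires on a strict
    majority; any firing member makes the sample high risk. Needs only the
    member and partner rows of ``expression``; no thresholds are involved.
    """
    high = pd.Series(False, index=expression.columns)
    for member, grp in rules.groupby("member", sort=False):
        relation = grp["relation"].iloc[0]
        needed = int(grp["majority_needed"].iloc[0])
        mv = expression.loc[member]
        pv = expression.loc[grp["partner"].tolist()]
        hold = pv.lt(mv, axis=1) if relation == "higher" else pv.gt(mv, axis=1)
        high |= hold.sum(axis=0) >= needed
    return pd.Series(np.where(high, "high", "low"), index=expression.columns, name="risk_group")
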