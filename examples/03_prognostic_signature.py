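"""Forward-select a prognostic signature from individual DE calls.

Simulates a 300-patient cohort in which the individual-level DE status of
one lncRNA (lncRisk, down-regulation) triples the hazard, screens every
called lncRNA by log-rank + univariate Cox (P < 0.05 on both), forward-
selects the maximal-C-index signature under the union risk rule, and prints
the threshold-free comparison rules a clinic could apply to a single sample.
"""

import numpy as np
import pandas as pd

from lncrindiv import (
    Signature,
    assign_risk_groups,
    export_rules,
    forward_select,
    screen_candidates,
    survival_association,
)
from lncrindiv.indiv_calls import TargetPartnerSet
from lncrindiv.sim_eval import synth_survival

rng = np.random.default_rng(1)
n = 300
patients = [f"p{i}" for i in range(n)]

# individual-level DE status: one survival-informative lncRNA + noise lncRNAs
de_risk = rng.random(n) < 0.3
calls = pd.DataFrame("none", index=["lncRisk"], columns=patients, dtype=object)
calls.loc["lncRisk", de_risk] = "down"
for j in range(5):
    mask = rng.random(n) < 0.25
    row = pd.Series("none", index=patients, dtype=object)
    row[mask] = "up" if j % 2 else "down"
    calls.loc[f"lncNoise{j}"] = row

surv = synth_survival(de_risk.astype(int), hazard_ratio=3.0, rng=rng)
survival = pd.DataFrame(
    {"time": surv["time"].values, "event": surv["event"].values}, index=patients
)

candidates = screen_candidates(calls, survival)
print("admitted candidates (log-rank & Cox P < 0.05, HR > 1):")
for c in candidates:
    print(f"  {c.lnc_id}: HR={c.hazard_ratio:.2f}, C-index={c.c_index:.3f}")

signature = forward_select(candidates, calls, survival)
print(f"signature: {signature.members}, combined C-index {signature.c_index:.3f}")

groups = assign_risk_groups(calls, signature)
assoc = survival_association(groups, survival["time"], survival["event"])
hr = assoc["univariate"]["group"]
print(f"high-risk group: n={int((groups == 'high').sum())}, "
      f"HR={hr['HR']:.2f} (95% CI {hr['CI'][0]:.2f}-{hr['CI'][1]:.2f}), "
      f"log-rank P={assoc['logrank_p']:.2e}")

# export the members' pairwise comparison rules (here with synthetic partners)
partner_sets = {
    lnc: TargetPartnerSet(
        lnc, direction,
        partners=pd.DataFrame({"partner": [f"{lnc}_ref{k}" for k in range(3)], "cv": 0.1}),
        selected=[f"{lnc}_ref{k}" for k in range(3)],
    )
    for lnc, direction in signature.members
}
print()
print(export_rules(signature, partner_sets).to_string(index=False))
print("\nA sample is high risk when, for any member, the stated comparison")
print("holds against a strict majority of its reference partners.")
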