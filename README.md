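# lncrindiv

Individual-level differential expression of lncRNAs from within-sample rank
reversals — with a spike-in benchmark, a survival-signature selector and a
copy-number concordance test.

## The problem

Standard differential-expression tools (t-tests, edgeR/DESeq-style models)
report whether a lncRNA is dysregulated *on average* across a cancer cohort.
But lncRNA expression is highly heterogeneous between patients: a transcript
silenced in one tumour may be untouched in the next. Clinical use — assigning
*this* patient to a risk group — needs a per-sample call, and it needs one
that survives batch effects and normalisation differences between
laboratories.

`lncrindiv` is for computational biologists who want per-patient DE calls
from bulk (or pseudo-bulk) lncRNA expression matrices, and prognostic rules
built on them that transfer across platforms.

## The method

Only the *relative ordering* of expression values within one sample is used,
which is invariant to any monotone normalisation.

1. **Stable pairs.** Convert each sample to ranks. An ordered pair
   (A, B) is *stable* when A < B holds in more than 95% of normal samples:
   a/(a+b) > 0.95, where a and b count the two orientations (ties count for
   neither). Observing, say, 95/100 one way by chance has one-sided binomial
   probability P(X ≥ 95 | n=100, p=½) = 6.26 × 10⁻²³.
2. **Reversal pairs.** For each stable pair, the 2×2 table (a, b; c, d) of
   orientation counts in normal vs cancer samples is tested with a one-sided
   Fisher exact test for enrichment of the flipped orientation d in cancer;
   Benjamini–Hochberg FDR < 0.1 over all stable pairs defines reversal pairs.
   A reversal of A < B implies A moved up or B moved down.
3. **Partner curation.** For a target lncRNA: estimate its population
   direction (sign of the mean-rank shift in cancer); keep only reversal
   partners whose flip implies that direction; rank partners by the
   coefficient of variation (CV = sd/mean) of their rank across all samples —
   a near-constant partner rank pins the reversal on the target — and keep
   the ≤ 3 smallest-CV partners.
4. **Individual calls.** A cancer sample is called DE for the target exactly
   when a strict majority of the selected pairs is reversed *in that sample*.

On top of the calls:

* **Benchmarking** (`sim_eval`): a synthetic-cohort generator emulating real
  lncRNA profiles (detection-floor clump, noisy low-expression shoulder,
  expressed tail, drop-outs, per-patient dysregulation) plus the spike-in
  protocol measuring event-level sensitivity, specificity, the F-score
  (harmonic mean of sensitivity and specificity) and the per-sample
  consistency of call directions with paired cancer-normal rank changes.
* **Prognosis** (`prognosis`): screen called lncRNAs by log-rank and
  univariate Cox (P < 0.05 on both, HR > 1 for the DE group), forward-select
  the signature maximising Harrell's C-index under the *union risk rule* (a
  patient is high-risk as soon as any member is DE in its risk direction),
  and export each member's ≤ 3 pairwise comparisons as a threshold-free
  clinical rule table.
* **Copy-number concordance** (`cna_concordance`): discretize per-sample log2
  copy ratios (> 0.1 amplification, < −0.1 deletion) and test, per lncRNA,
  the hypergeometric overlap of DE patients with direction-matched
  copy-altered patients.

## Worked example

```bash
python examples/01_individual_de_calls.py
```

```
186 of 300 lncRNAs pass the detection filter
4482 stable pairs (26.1% of all pairs)
181 lncRNAs callable (have curated reversal partners)
777 up + 975 down individual (lncRNA, sample) DE calls
direction agreement with simulated truth: 83.4%
```

About a quarter of all pairs are order-stable across the 120 normal samples
(the regime real cohorts show); almost every lncRNA with reversal pairs gets
curated reference partners; and the per-patient calls are spread over the
disease samples — each (lncRNA, sample, direction) triple is one
individual-level call. The benchmark example prints the detection statistics
of the spike-in protocol:

```bash
python examples/02_spike_in_benchmark.py
```

```
scenario  log2fc  sensitivity  specificity  f_score  consistency  stable_frac
60 vs 60     1.0     0.977817     0.987545 0.982641     0.941907     0.272946
60 vs 60     2.0     0.994971     0.983862 0.989385     0.929793     0.254606
```

`examples/03_prognostic_signature.py` and `examples/04_cna_concordance.py`
walk through signature selection / rule export and the copy-number
concordance test the same way. A thin command-line interface mirrors the
library (`lncrindiv --help`): subcommands `stable-pairs`, `reversal-pairs`,
`call`, `simulate`, `evaluate`, `consistency`, `benchmark`, `signature`,
`cna-concordance`, all reading and writing tab-separated text.

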