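# Methods

## The calling model

All inference is on within-sample relative expression orderings (REOs).
For lncRNAs i, j and sample s, the observable is the indicator
x_i(s) < x_j(s); it is invariant under any strictly monotone per-sample
transform, which is the method's defence against batch effects and
normalisation differences.

**Stable pairs.** With a the number of tie-free normal samples showing
low < high and b the flipped count, a pair is stable when a/(a+b) > 0.95
(strict). Ties contribute to neither orientation: continuous expression
rarely ties exactly, and the ordering model has no tie semantics. Stability
of an ordering in at least k of n samples is quantified by the exact
one-sided binomial tail P(X ≥ k | n, ½); for k=95, n=100 this is
6.26 × 10⁻²³.

**Reversal pairs.** Each stable pair contributes a 2×2 table
(a, b; c, d) of orientation counts in normal vs cancer. The one-sided
Fisher exact p-value for enrichment of the flipped orientation in cancer is
the hypergeometric upper tail P(D ≥ d) over tables with the observed
margins (computed vectorised via `scipy.stats.hypergeom`, verified against
full enumeration in the tests). The test is one-sided because the
hypothesis is directional — a stable ordering becoming its reverse.
Benjamini–Hochberg correction is applied over the family of *all* stable
pairs tested in a run (that is the set on which p-values are produced);
pairs with q < 0.1 are reversal pairs. A reversal of (low < high) implies
per-member directions: low → up, high → down.

**Partner curation and calls.** A target's population direction is the sign
of its mean-rank shift between groups (rank-scale, robust; an exact tie
excludes the target). Only reversal partners whose flip implies that
direction are retained. Each partner's CV of rank — sample standard
deviation (n−1 denominator) over mean, across normal and cancer samples
pooled — measures how constant its rank is; the ≤ 3 smallest-CV partners are
selected (CV ties broken lexicographically by id, so selection is
deterministic). A sample is called DE exactly when a strict majority of the
selected pairs is reversed in it (k=3 → ≥2, k=2 → both, k=1 → the one);
the strict reading prevents single-pair false calls at k=2. Partners may
themselves be call targets; no exclusion is imposed.

## The synthetic cohort generator

The generator (`sim_eval.make_model`) does not imitate any particular
dataset; it reproduces the *structural* features of real lncRNA profiles
that the method's operating point depends on. Per-lncRNA log2 baselines
follow a three-component mixture:

| component | default mass | location | role |
|---|---|---|---|
| central clump | 50% | Normal(7.0, 0.07) | near-floor transcripts whose orderings churn |
| low shoulder | 45% | Uniform(5.6, 6.65) | low-expressed transcripts; noise grows with depth |
| expressed tail | 5% | clusters, heights 7.35 + Exp(1.0), capped at 11 | clearly expressed minority |

Per-lncRNA noise standard deviations are log-uniform on (0.06, 0.15) —
the tight per-probe variability typical of RMA-processed arrays — except in
the shoulder, where noise is inflated by (1 + 8·depth) below the clump
centre, emulating measurement degradation toward the detection limit; a 15%
minority of shoulder lncRNAs stays tightly regulated (precisely controlled
low-abundance transcripts). Latent values below the detection limit (6.0)
are recorded as 0 (drop-out), and the standard pre-processing filter keeps
lncRNAs detected in ≥ 90% of samples (inclusive threshold).

Two anchors, both properties of real cohorts, fixed this geometry once:
(i) 25–30% of all post-filter pairs are order-stable in ~200-sample normal
cohorts at the 95% threshold, and (ii) reversal-partner expression gaps lie
within reach of log2 fold changes of 1–2, so reversals of stable orderings
are physically realisable. A flat uniform baseline cannot satisfy both at
once: forcing 27% stability pushes the stability boundary to about half the
dynamic range, beyond any realistic fold change. The mixture separates the
two scales — orderings churn inside the clump, are deeply stable across
components, and the filter removes the drop-out-prone noisy shoulder.

**Disease cohorts** (`synth_disease_cohort`): 95% of lncRNAs carry a
dysregulation direction (real tumour cohorts exhibit DE status for nearly
every lncRNA in some patients). Directions respect the expression scale:
trace-level transcripts (> 1 log2 below the clump) can only be gained,
saturated ones (> 2 log2 above) only lost — silencing an absent transcript
is unmeasurable, and rank saturation otherwise inverts weak direction
estimates at the extremes. Each dysregulated lncRNA has its own patient
prevalence, uniform on (0.05, 0.15), and each affected (lncRNA, patient)
cell is shifted by a log2 magnitude uniform on (0.7, 1.3) — modest 1.6–2.5×
fold changes; per-patient heterogeneity in both membership and magnitude is
the phenomenon the method is designed to resolve. The prevalence ceiling
matters: joint prevalence of simultaneous two-sided movements scales with
its square, and keeping it low prevents reversal pairs at gaps beyond any
single shift's reach.

**Spike-ins** (`spike_in_de`): the evaluation disease matrix starts as an
exact paired copy of the normals; each spiked lncRNA receives ± log2FC in a
binomially drawn number of samples (expectation `mean_de_samples` = 10,
minimum 1).

## The benchmark protocol

`run_spikein_benchmark` has two phases, mirroring the method's original
evaluation design (pair discovery on a real, broadly dysregulated cohort;
spike-in evaluation on paired samples):

1. **Discovery.** Generate a normal cohort and a dysregulated disease
   cohort, apply the detection filter to the pooled samples, run the full
   pipeline, and keep each identified target's curated partner set.
2. **Evaluation.** Draw 50 up- and 50 down-regulated lncRNAs *from the
   identified sets*, spike them into paired copies of the normal samples at
   the scenario's log2FC, call every sample with the discovery partner sets,
   and score at the (lncRNA, sample)-event level: sensitivity = correctly
   directed calls / spiked events (a wrong-direction call is not a correct
   identification); specificity = uncalled non-events / non-events over the
   full call grid (the event-level denominator is the only one consistent
   with specificity magnitudes near 0.999); F-score = harmonic mean of the
   two.

A single-phase protocol (discovering reversal pairs on the spiked samples
themselves) is statistically underpowered by construction: ~10 flips out of
210 cancer samples cannot clear BH at FDR 0.1 against the full stable-pair
family, so it cannot reach the reference operating point regardless of
generator settings.

The **consistency score** is computed on matched tissue pairs, the synthetic
analogue of paired cancer-normal tissue: each normal sample gets a genuinely
dysregulated disease twin (fresh draw plus population dysregulation)
carrying the same spiked events. Per disease sample, among its DE calls,
the score is the fraction whose direction matches the sign of the
cancer-minus-normal rank change (a zero rank change matches neither);
samples with no calls are excluded from averages. Spike-only paired copies
would be the wrong substrate here: with only ~5 true events per sample, the
score would be dominated by the false-call rate rather than by directional
agreement, which is not what the paired-tissue comparison measures.

Default problem sizes — 500 lncRNAs, 210 normal + 210 disease samples, 10
replicates per scenario cell, with a 60 vs 60 small-cohort scenario — were
chosen as the package's desk-scale working point; 500 lncRNAs keeps the
chance small that a spiked lncRNA is another target's sole reference
partner. Measured operating point at these defaults (210 vs 210, mean of 10
replicates): sensitivity 0.75 / 0.99 / 0.996 at log2FC 1.0 / 1.5 / 2.0,
specificity ≈ 0.995–0.998 throughout, F-score ≈ 0.99 at log2FC ≥ 1.5,
consistency ≈ 0.96–0.98, stable-pair fraction 0.26–0.29. Passing tests show
the implementation reproduces this regime on data with the stated
structure; they do not certify performance on real cohorts, whose
correlation structure (co-regulation beyond small clusters, sample-level
artefacts) the generator deliberately omits.

## Survival machinery

Candidates are screened per called lncRNA by splitting patients into
with/without-DE groups (both groups ≥ 3 patients with ≥ 1 event; smaller
splits are degenerate and skipped). Admission requires log-rank P < 0.05
and univariate Cox P < 0.05 — uncorrected, as one screening family — and
HR > 1 for the DE group; the risk direction is then the lncRNA's DE
direction, fixed at screening time. DE patterns associated with *longer*
survival cannot be expressed by the union rule and are not admitted.

Forward selection ranks candidates by decreasing individual Harrell
C-index (ties lexicographic), seeds with the best, then tries each
remaining candidate once in order, keeping it only if the combined C-index
strictly increases (an equal value discards the addition). The combined
risk score of a member set is the binary union rule — high risk iff any
member is DE in its risk direction — the only combination the published
two-lncRNA signature form exhibits; it is also what makes the final
signature exportable as threshold-free rules. C-index: over usable pairs
(unequal times, earlier time an observed event), concordant = 1, risk tie =
0.5; 0.5 means no predictive ability, 1 perfect. The backend is
`lifelines.utils.concordance_index`, cross-checked against an O(n²) pair
enumeration in the tests; log-rank and Cox fits come from lifelines.

`export_rules` emits, per member, its ≤ 3 comparisons ("expression of X
higher/lower than partner P") plus the strict-majority threshold;
`apply_rules` classifies new samples directly from expression values with no
thresholds, and round-trips exactly to `assign_risk_groups` on the training
calls.

## Copy-number concordance

Log2 copy ratios discretize with strict cutoffs (> 0.1 amplification,
< −0.1 deletion; boundary values neutral). For each lncRNA with a single
call direction, the test population is the patients present in both
matrices (no imputation across partially overlapping cohorts); the overlap
between DE patients and direction-matched altered patients (up ↔ gain,
down ↔ loss) is scored with the upper-tail hypergeometric probability of an
overlap at least as large. lncRNAs with an empty DE or altered set are
skipped and reported.

## Numerical and interface choices

* Pair counting is exact integer comparison, accumulated over sample blocks
  (memory ≤ G² × block booleans); p-values come from scipy's hypergeometric
  survival function, BH from statsmodels.
* Calls, stable pairs and reversal pairs are deterministic for fixed
  inputs; all generator randomness flows from a single seed through
  `numpy.random.SeedSequence` spawning.
* Missing values are rejected at the format layer (rank machinery has no NA
  semantics); recorded zeros are legitimate values (drop-outs) and
  participate in comparisons, where they simply sit at the bottom of the
  ordering.
* Expression files are plain TSV on any monotone scale; platform formats
  and normalisation are upstream concerns.

## Known limitations

* The generator's samples are independent given the model; real cohorts
  carry co-regulation and shared sample-level artefacts that can correlate
  pair flips beyond what the benchmark probes.
* Individual calls require the target to possess reversal partners within
  the dysregulation's reach; lncRNAs at the extremes of the expression range
  (nothing stably below/above them) are structurally uncallable in the
  corresponding direction.
* At small k the strict-majority rule makes single-partner targets fire on
  any flip of their lone pair; k = 1 calls carry correspondingly less
  evidence (the partner audit table exposes k per target).
* Screening p-values are intentionally uncorrected (matching the published
  procedure); treat the candidate table as a screen, not as inference.
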