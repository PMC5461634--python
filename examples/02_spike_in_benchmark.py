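"""Spike-in benchmark: sensitivity/specificity/F-score and consistency.

Runs a reduced version of the spike-in evaluation protocol (two fold
changes, two replicates, 60 vs 60 samples) and prints the per-scenario mean
detection statistics. Sensitivity is the fraction of spiked (lncRNA, sample)
events called with the correct direction; specificity the fraction of
untouched cells left uncalled; the F-score their harmonic mean; and the
consistency score the per-sample fraction of calls whose direction matches
the paired cancer-normal rank change.
"""

from lncrindiv import BenchmarkConfig, run_spikein_benchmark, summarize_benchmark

cfg = BenchmarkConfig(
    n_lnc=300,
    sizes=((60, 60),),
    log2fc_grid=(1.0, 2.0),
    n_up=30,
    n_down=30,
    n_seeds=2,
    seed=0,
)
report = run_spikein_benchmark(cfg)
print(summarize_benchmark(report).to_string(index=False))
print()
print("Detection sharpens as the spiked fold change grows; specificity and")
print("the paired-sample consistency stay high throughout.")
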