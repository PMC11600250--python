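"""Compare all four sorters on a small simulated benchmark.

Generates 2 small-class sets at 1/50 scale (~2,000 spikes each) to keep
the example fast, runs AE-Ensemble, DeepAE, DEC and IDEC on each, and
prints per-set accuracies plus improvements relative to the ensemble.
The full-scale comparison (10 sets per class at ~10,000 spikes) is what
scripts/acceptance.py reproduces.
"""

from measort import make_benchmark_suite, run_benchmark
from measort.pipeline import default_sorters

suite = make_benchmark_suite("small", n_sets=2, scale_factor=0.02, rng_seed=1)
print(f"{len(suite)} sets, ~{len(suite[0][1])} spikes each")

result = run_benchmark(suite, default_sorters(), seed=11, size_class="small")
print(result.table[["set_id", "model", "accuracy", "improvement_pct"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nper-model summary (mean over sets):")
print(result.summary[["accuracy_mean", "improvement_mean"]]
      .to_string(float_format=lambda v: f"{v:.3f}"))
# improvement_pct is 100 * (accuracy / ensemble accuracy - 1) on the
# same set: positive means the sorter beat the ensemble reference there.
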