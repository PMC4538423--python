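"""Permutation significance of a detected module.

Each gene's values are shuffled independently within each condition,
destroying all covariance; the full pipeline is re-run on every shuffled
dataset and its module score (total |delta bicor| over within-module pairs)
forms the null distribution.
"""

from bmkc import BenchmarkConfig, PipelineConfig, generate_benchmark, permutation_test

control, disease, truth = generate_benchmark(BenchmarkConfig(sigma=0.1, seed=42))
cfg = PipelineConfig(filter_fraction=0.0, n_permutations=0, seed=42)
result = permutation_test(control, disease, cfg, n_permutations=100, seed=42)

print(f"observed module score: {result.observed_score:.2f} "
      f"({result.n_observed_modules} module(s) detected)")
print(f"null scores: max {result.null_scores.max():.2f}, "
      f"mean {result.null_scores.mean():.2f} over {result.n_permutations} permutations")
print(f"empirical p-value: {result.p_value:.3f} (add-one: {result.p_value_add_one:.3f})")
print()
print("The observed score towers over every permutation null, so the")
print("detected differential coexpression is not a high-dimensionality")
print("artifact of the selection procedure.")
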