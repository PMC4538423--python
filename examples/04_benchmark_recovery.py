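"""Planted-module benchmark: recovery across noise levels.

A 20-gene coexpressed block (pairwise correlation 1/(1 + sigma^2)) is
hidden among 100 noise genes; the disease group is pure noise.  The full
pipeline (bicor, gain thresholds T1=0.8/T2=0.4, k=4 percolation) should
return the block as one differential coexpression module while the signal
stands clear of the 30-sample null correlation spread.
"""

from bmkc import run_benchmark_study

df = run_benchmark_study(sigmas=(0.1, 0.25, 1.0), repeats=10, master_seed=1)
print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print("median_size 20 with jaccard 1 means the planted block is recovered")
print("exactly; at sigma = 1 the within-block correlation drops to 0.5,")
print("below the T1 = 0.8 threshold, and recovery collapses.")
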