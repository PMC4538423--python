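# bmkc — differential coexpression modules via biweight midcorrelation and k-clique percolation

Complex diseases rarely trace back to one gene changing its expression
level; more often a *group* of genes loses (or gains, or reverses) its
coordination between conditions.  `bmkc` finds such groups.  Given two
expression matrices over the same genes — one per condition, e.g. normal
and disease tissue — it:

1. computes a robust gene–gene correlation matrix per condition with the
   **biweight midcorrelation** (bicor), which median-centres each profile
   and down-weights outlying samples with Tukey biweight weights on the
   9·MAD scale;
2. binarizes the pair of matrices into one **differential coexpression
   graph** with a threshold rule — `gain` (edge when |bicor| ≥ T1 in normal
   and ≤ T2 in disease), `loss` (the mirror), or `absdiff` (edge when the
   signed correlation changes by ≥ T3 without growing in magnitude, which
   catches reversals such as +0.9 → −0.7);
3. prunes isolated genes and, optionally, the lowest-degree fraction of
   the graph;
4. detects overlapping gene modules by **k-clique percolation**: a module
   is the union of all k-cliques reachable from one another through
   shared-(k−1)-vertex adjacency (default k = 4);
5. assesses significance with a **group-wise permutation test**: each
   gene's values are shuffled independently within each condition, the
   whole pipeline is re-run, and the module score
   Σ_modules Σ_pairs |bicor_N(i,j) − bicor_D(i,j)| forms the empirical
   null.

A synthetic benchmark generator plants a 20-gene coexpressed block (shared
sample pattern plus Gaussian noise of SD σ, giving pairwise correlation
1/(1+σ²)) among 100 noise genes, with a pure-noise second condition, for
end-to-end validation of the detector.

## Worked example

```bash
bmkc simulate --sigma 0.1 --seed 3 --outdir sim/
bmkc run sim/control.tsv sim/disease.tsv --outdir out/ \
     --t1 0.8 --t2 0.4 -k 4 --filter-fraction 0
```

prints one line per detected module, e.g.

```
module 1 (20 genes): G002 G015 G018 G024 G036 G039 G045 G051 G054 G057 G058 G066 G068 G078 G089 G092 G094 G106 G113 G118
```

which is exactly the planted 20-gene block recorded in `sim/truth.txt`:
the block's within-condition correlation (≈ 0.99 at σ = 0.1) clears
T1 = 0.8 in the control group while the pure-noise disease group stays
below T2 = 0.4, so all 190 block pairs become edges and k = 4 percolation
returns the block as one module.  `out/` holds the two bicor matrices,
the edge list, the module table and JSON, and a verbatim config echo.

The same is available from Python:

```python
from bmkc import BenchmarkConfig, PipelineConfig, generate_benchmark, run_pipeline

control, disease, truth = generate_benchmark(BenchmarkConfig(sigma=0.1, seed=3))
result = run_pipeline(control, disease,
                      PipelineConfig(filter_fraction=0.0, n_permutations=100))
print(result.modules.modules[0])          # the recovered 20-gene module
print(result.permutation.p_value)         # 0.0: no permutation null reached it
```

The scripts in `examples/` walk through each capability — bicor's outlier
robustness, the three edge rules, percolation on toy graphs, benchmark
recovery across noise levels, and the permutation test — each printing a
few numbers and what they mean.

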