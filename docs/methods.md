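# Methods

## Model and procedure

`bmkc` detects gene modules whose *coexpression*, not expression level,
changes between two conditions.  The pipeline has five stages, run in this
fixed order.

**1. Biweight midcorrelation.**  For a vector x with median med(x) and
(unscaled) median absolute deviation mad(x), each observation gets

    u_i = (x_i − med(x)) / (9·mad(x)),
    w_i = (1 − u_i²)² · 1[|u_i| < 1],

and for two vectors

    bicor(x, y) = Σ (x_i − med x) w_i^x (y_i − med y) w_i^y
                  / √Σ[(x_j − med x) w_j^x]² / √Σ[(y_k − med y) w_k^y]².

The weight is 1 at the median, falls smoothly, and is exactly 0 beyond
9·mad — points there are outliers by construction, so no separate outlier
detection step exists.  The 9·mad quantity serves as both the soft scale
and the hard cutoff; we implement that literally.  The MAD carries no
1.4826 Gaussian consistency factor: the scale is relative, and any
constant would cancel against the cutoff anyway.

*Degenerate vectors.*  A vector with mad = 0 (constant, or majority-tied)
has no defined weights.  The default policy reports correlation 0 with a
warning, which keeps genome-scale runs total when flat probes occur;
`pearson` and `error` are selectable (`BicorOptions.fallback_on_zero_mad`).

*maxPOutliers.*  `BicorOptions.max_p_outliers` (default 1 = no cap) caps
the proportion of zero-weight points on each side of the median
separately: when a side exceeds the cap, that side's u values are divided
by its (1 − max_p_outliers) quantile of |u|, placing that quantile at the
cutoff.  This matches the parameter's meaning — a bound on the proportion
of low and high outliers separately — while leaving clean vectors
untouched.

**2. Differential-coexpression thresholding.**  Writing C_N and C_D for
the condition correlation matrices, the three edge rules are

| mode    | edge iff                                       | default thresholds |
|---------|------------------------------------------------|--------------------|
| gain    | C_N(i,j) ≥ T1 and C_D(i,j) ≤ T2                | T1 = 0.8, T2 = 0.4 |
| loss    | C_N(i,j) ≤ T1 and C_D(i,j) ≥ T2                | T1 = 0.2, T2 = 0.8 (set per run) |
| absdiff | \|C_N − C_D\| ≥ T3 and \|C_N\| ≥ \|C_D\|       | T3 = 1.3           |

In gain/loss modes correlations are taken as absolute values by default
(`use_absolute_correlation`), since the question is strength of
coexpression, not its sign; signed comparison is selectable.  The absdiff
rule deliberately differences *signed* values — a reversal +0.9 → −0.7 is
a change of 1.6 — while its second condition compares magnitudes, so
pairs whose coexpression *grows* in disease are excluded.  T1/T2 trade
edge count against clique density: too strict loses modules, too lax
produces a blur of overlapping cliques.  The random-graph critical point
d(k) (below) is exposed as a diagnostic for calibrating them.

**3. Pre-filtering.**  Two separate, composable passes: removal of
degree-zero genes, then a single-pass pruning of the lowest-degree
⌊fraction·n⌋ genes (default fraction 0.5 for real-data runs).  Degrees are
computed once before removal; ties break on gene id (stable sort on
(degree, id)) so results are deterministic.  The passes are separate
operations, not fused, for testability.

**4. k-clique percolation.**  A module is the union of all k-cliques
reachable through shared-(k−1)-vertex adjacency; modules may overlap.
The implementation enumerates maximal cliques (Bron–Kerbosch, via
networkx) and takes connected components of the maximal-clique overlap
graph with overlap ≥ k−1 — equivalent to percolating every individual
k-clique, because two k-cliques within one maximal clique already share
k−1 vertices.  The test suite asserts this equivalence against a literal
k-subset percolation oracle on all graphs with ≤ 5 vertices and hundreds
of random 6–8-vertex graphs.  Default k = 4; raising k (or the
thresholds) shrinks and disintegrates modules, a resolution control.
Diagnostics: d(k) = 1/((k−1)·N^{1/(k−1)}), the Erdős–Rényi edge
probability above which giant k-clique clusters emerge; φ = N*/N and
φ′ = L*/L, the vertex and k-clique shares of the largest percolation
cluster (largest by vertex count, ties to the lexicographically smallest
member; φ′ = 0 when the graph has no k-clique); and the analytic estimate
L ≈ C(N,k)·d^{k(k−1)/2} of the k-clique count of a random graph.

**5. Permutation significance.**  The module score is
Σ_modules Σ_{unordered pairs (i,j) in module} |C_N(i,j) − C_D(i,j)|; a
pair belonging to two overlapping modules contributes to both, since each
module is a separate finding.  The summation is over gene *pairs* — the
natural unit of a correlation change — and is the package's only scorer.
The null shuffles each gene's values independently *within each
condition*, preserving all per-gene marginals while destroying all
covariance, and re-runs the entire pipeline per replicate (detection
included), so the null distribution accounts for selection effects; a
replicate that detects nothing scores 0.  Significance is upper-tail,
p = #(null ≥ observed)/n — the score measures magnitude of differential
change, so large values are the alternative — with the add-one estimator
(#+1)/(n+1) reported alongside as the never-zero variant.  When the
observed run detects no modules the score is 0 and the estimator yields
p = 1, with a warning.  Default n = 1000 permutations.

## Synthetic benchmark

The generator emulates a two-condition study with one planted module:
20 signal genes in the control group follow x_gj = a_g + s_j + ε_gj with
a_g ~ N(0,1) per gene, s_j ~ N(0,1) per sample, ε ~ N(0, σ²); the other
100 control genes and the entire 120-gene disease group are i.i.d.
N(0,1); 30 samples per group; gene order is randomised with the planted
ids recorded.  The additive combination of the per-gene and per-sample
vectors is chosen because it yields one analyzable signal level — every
signal pair has population correlation 1/(1+σ²) — consistent with a
clear/medium/high noise narrative at σ = 0.1, 0.25, 1 (≈ 0.99, 0.94,
0.50); a multiplicative variant (a_g·s_j + ε) is available behind
`model=`.  The study protocol runs 50 seeded replicates per σ and
tabulates mean and median recovered size and Jaccard index against the
planted set; the median is the headline statistic, robust to rare total
failures.  The benchmark pipeline uses gain mode T1 = 0.8 / T2 = 0.4 —
separating the ≈ 0.99 signal correlation from the n = 30 null correlation
spread (SD ≈ 0.19) — k = 4, and no low-degree pruning: with one planted
module, pruning half the detected subgraph would only bite into the
target.  What passing shows: the detector recovers a uniformly correlated
block from a noise background at realistic sample sizes.  What it does
not show: robustness to correlated noise backgrounds, multiple or nested
modules, heavy-tailed expression, or batch structure — real data have all
of these, which is what the permutation test (run on the real data
itself) is for.

## Numerical and design choices

- Even-length medians: mean of the two central order statistics.
- bicor results are clipped to [−1, 1] to absorb floating-point overshoot;
  self-correlation is exactly 1 by construction in the matrix path.
- All set-valued outputs (cliques, modules, edge lists) are sorted —
  members lexicographically, collections by (descending size, members) —
  so repeated runs produce byte-identical files.
- Maximal cliques below size k are ignored for community building but can
  be reported for diagnostics (`enumerate_maximal_cliques(min_size=...)`).
- The expression TSV dialect is gene-id column + sample header row;
  parsing errors name the offending line.  Floats are written at 17
  significant digits so read(write(x)) is exact.
- Seeding: one integer seed drives generation, permutation and replicate
  seeds (replicate seeds drawn from a generator seeded by the master
  seed, all below 2³¹).

## Problem sizes

The test suite and acceptance script run the 50-replicate benchmark at
the full 120-gene, 30+30-sample design (sub-second per replicate), the
permutation machinery at 200 planted-signal and 20×60 null permutations,
and a structural pass at 4765 genes × 10+10 samples — sizes chosen to
match the designs the method targets while keeping a laptop run in
minutes.

## Known limitations

- Thresholding is hard (binary); no soft-threshold weighted networks or
  scale-free topology fitting.
- bicor is the only similarity measure; no Spearman or mutual
  information, and no missing-value imputation (inputs must be complete).
- The permutation test evaluates one global score across all detected
  modules, not per-module p-values, and assumes exchangeable samples
  within condition (no covariate structure).
- k-clique percolation is exponential in the worst case; dense graphs at
  lax thresholds can blow up clique enumeration — the threshold-selection
  guidance (graph density, d(k)) exists to keep graphs sparse.
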